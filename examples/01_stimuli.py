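"""Parameterize the two stimulus families and inspect their invariants.

Builds the default ICMS pulse train (320 Hz, 200 us/phase, 650 ms) and the
default training tone (6 kHz, 500 ms, 50 ms ramps), and prints the derived
quantities a rig operator cares about: charge per phase, pulse count,
charge balance, and tone peak amplitude.
"""

import numpy as np

from nosepoke import (
    PulseTrainSpec,
    ToneSpec,
    charge_per_phase,
    make_pulse_train,
    percent_amplitude_to_db_spl,
    synthesize_tone,
)

spec = PulseTrainSpec(current_amplitude_ua=15)
train = make_pulse_train(spec)
print(f"charge per phase: {spec.charge_per_phase_nc:.2f} nC/ph "
      f"(= {spec.current_amplitude_ua} uA x {spec.pulse_width_us} us)")
print(f"pulses in {spec.train_duration_ms:.0f} ms at {spec.frequency_hz:.0f} Hz: "
      f"{len(train)}")
print(f"net charge of first pulse: {train[0].net_charge_nc:+.1f} nC "
      "(charge balanced)")
print(f"full-scale amplitude 25 uA -> {charge_per_phase(25, 200):.1f} nC/ph "
      "(the safety ceiling)")

tone = ToneSpec(amplitude_percent=50)
wave = synthesize_tone(tone)
print(f"\ntone: {len(wave)} samples, peak {np.abs(wave).max():.3f} "
      f"(amplitude {tone.amplitude_percent:.0f}% of the training tone)")
print(f"50% amplitude under the 20*log10 reporting convention: "
      f"~{percent_amplitude_to_db_spl(50):.0f} dB SPL")
# The pulse count and charge balance are what the stimulator must deliver;
# the tone peak shows the linear 0-100% amplitude scale used for thresholds.
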