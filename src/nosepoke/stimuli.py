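"""Stimulus families for the go/no-go task: ICMS pulse trains and pure tones.

Two stimulus modalities are supported. Intracortical microstimulation (ICMS)
is delivered as current-controlled, charge-balanced symmetric biphasic pulse
trains with a cathodal-leading phase; intensity is expressed as charge per
phase in nanocoulombs (nC/ph = current amplitude x pulse width). The auditory
stimulus is an amplitude-scaled pure tone; intensity is expressed as percent
of the training-tone amplitude on a 0-100 scale where 0% is silence.

Defaults reproduce the standard parameterization: 320 Hz pulse rate, 200 us
per phase, 40 us interphase interval, 650 ms train duration, 5 nC/ph charge
limit; 6 kHz carrier, 100 kHz sample rate, 500 ms tone, 50 ms linear ramps.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Modality",
    "PulseTrainSpec",
    "ToneSpec",
    "StimulusIntensity",
    "charge_per_phase",
    "make_pulse_train",
    "synthesize_tone",
    "percent_amplitude_to_db_spl",
    "DEFAULT_CHARGE_LIMIT_NC",
]

#: Maximum charge per phase permitted per simultaneously pulsed electrode (nC/ph).
DEFAULT_CHARGE_LIMIT_NC = 5.0


class Modality(str, enum.Enum):
    """Stimulus modality: microstimulation charge or tone amplitude."""

    ICMS = "icms"
    AUDITORY = "auditory"


def charge_per_phase(current_amplitude_ua: float, pulse_width_us: float) -> float:
    """Charge delivered in one phase of a biphasic pulse, in nC/ph.

    Parameters
    ----------
    current_amplitude_ua : float
        Current amplitude in microamps (>= 0).
    pulse_width_us : float
        Pulse width per phase in microseconds (>= 0).

    Returns
    -------
    float
        Charge per phase in nanocoulombs: ``I * w`` with unit conversion
        (uA * us = pC, /1000 -> nC).

    Examples
    --------
    >>> charge_per_phase(25, 200)
    5.0
    """
    if current_amplitude_ua < 0 or pulse_width_us < 0:
        raise ValueError(
            "current amplitude and pulse width must be non-negative, got "
            f"{current_amplitude_ua} uA, {pulse_width_us} us"
        )
    return current_amplitude_ua * pulse_width_us / 1000.0


@dataclass(frozen=True)
class PulseTrainSpec:
    """Parameterization of a charge-balanced symmetric biphasic ICMS pulse train.

    Attributes
    ----------
    current_amplitude_ua : float
        Current amplitude in microamps.
    pulse_width_us : float
        Width of each phase in microseconds.
    interphase_interval_us : float
        Gap between cathodal and anodal phases, microseconds.
    frequency_hz : float
        Pulse repetition rate.
    train_duration_ms : float
        Total train duration in milliseconds.
    n_channels : int
        Number of electrode sites pulsed simultaneously.
    cathodal_leading : bool
        Polarity of the first phase.
    charge_limit_nc : float
        Safety ceiling on charge per phase per channel (nC/ph).
    """

    current_amplitude_ua: float = 15.0
    pulse_width_us: float = 200.0
    interphase_interval_us: float = 40.0
    frequency_hz: float = 320.0
    train_duration_ms: float = 650.0
    n_channels: int = 10
    cathodal_leading: bool = True
    charge_limit_nc: float = DEFAULT_CHARGE_LIMIT_NC

    def __post_init__(self) -> None:
        if self.current_amplitude_ua < 0:
            raise ValueError("current amplitude must be >= 0")
        if self.pulse_width_us <= 0 or self.frequency_hz <= 0:
            raise ValueError("pulse width and frequency must be > 0")
        if self.train_duration_ms <= 0:
            raise ValueError("train duration must be > 0")
        charge = self.charge_per_phase_nc
        if charge > self.charge_limit_nc:
            raise ValueError(
                f"charge per phase {charge:.3g} nC/ph exceeds limit "
                f"{self.charge_limit_nc:.3g} nC/ph"
            )
        period_us = 1e6 / self.frequency_hz
        if period_us < 2 * self.pulse_width_us + self.interphase_interval_us:
            raise ValueError(
                "biphasic pulse does not fit in the period: "
                f"1/f = {period_us:.1f} us < 2*{self.pulse_width_us} + "
                f"{self.interphase_interval_us} us"
            )

    @property
    def charge_per_phase_nc(self) -> float:
        return charge_per_phase(self.current_amplitude_ua, self.pulse_width_us)

    @property
    def n_pulses(self) -> int:
        """Number of pulses emitted: floor(duration * frequency)."""
        return math.floor(self.train_duration_ms / 1000.0 * self.frequency_hz)


@dataclass(frozen=True)
class Pulse:
    """One biphasic pulse: onset time and its two signed phase charges (nC)."""

    onset_ms: float
    phase_charges_nc: tuple[float, float]
    phase_width_us: float
    interphase_interval_us: float

    @property
    def net_charge_nc(self) -> float:
        return sum(self.phase_charges_nc)


def make_pulse_train(spec: PulseTrainSpec) -> list[Pulse]:
    """Expand a pulse-train spec into per-pulse onset times and phase charges.

    Onsets are uniformly spaced at 1/frequency starting at t = 0; the pulse
    count is ``floor(train_duration * frequency)`` so the whole train fits
    within the stated duration. Each pulse is charge balanced: the cathodal
    and anodal phases carry equal and opposite charge.
    """
    q = spec.charge_per_phase_nc
    first, second = (-q, q) if spec.cathodal_leading else (q, -q)
    period_ms = 1000.0 / spec.frequency_hz
    return [
        Pulse(
            onset_ms=i * period_ms,
            phase_charges_nc=(first, second),
            phase_width_us=spec.pulse_width_us,
            interphase_interval_us=spec.interphase_interval_us,
        )
        for i in range(spec.n_pulses)
    ]


@dataclass(frozen=True)
class ToneSpec:
    """Amplitude-scaled pure tone with linear onset/offset ramps.

    ``amplitude_percent`` is on the normalized 0-100 scale where 100
    reproduces the training tone and 0 is silence.
    """

    carrier_frequency_hz: float = 6000.0
    sample_rate_hz: float = 100_000.0
    duration_ms: float = 500.0
    ramp_duration_ms: float = 50.0
    amplitude_percent: float = 100.0

    def __post_init__(self) -> None:
        if not 0 <= self.amplitude_percent <= 100:
            raise ValueError("amplitude_percent must lie in [0, 100]")
        if 2 * self.ramp_duration_ms > self.duration_ms:
            raise ValueError("ramps may not exceed half the tone duration")
        if self.sample_rate_hz <= 0 or self.carrier_frequency_hz <= 0:
            raise ValueError("carrier and sample rate must be > 0")

    @property
    def n_samples(self) -> int:
        return round(self.duration_ms / 1000.0 * self.sample_rate_hz)


def synthesize_tone(spec: ToneSpec) -> np.ndarray:
    """Render the tone as a sample sequence in [-1, 1] scaled by amplitude.

    The envelope ramps linearly from 0 over ``ramp_duration_ms`` at onset and
    back to 0 at offset; peak absolute value equals ``amplitude_percent/100``
    up to sampling discretization.
    """
    n = spec.n_samples
    t = np.arange(n) / spec.sample_rate_hz
    wave = np.sin(2 * np.pi * spec.carrier_frequency_hz * t)
    env = np.ones(n)
    n_ramp = round(spec.ramp_duration_ms / 1000.0 * spec.sample_rate_hz)
    if n_ramp > 0:
        ramp = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
        env[:n_ramp] = ramp
        env[n - n_ramp:] = ramp[::-1]
    return wave * env * (spec.amplitude_percent / 100.0)


def percent_amplitude_to_db_spl(percent: float, reference_db: float = 90.0) -> float:
    """Convert percent amplitude to dB SPL under a 20*log10 convention.

    Reporting utility only: maps 100% to the training-tone level
    (``reference_db``, nominally ~90 dB SPL) via
    ``reference_db + 20*log10(percent/100)``. This is one conventional
    choice of scaling and is never used in any threshold computation.
    """
    if percent <= 0:
        return float("-inf")
    return reference_db + 20.0 * math.log10(percent / 100.0)


@dataclass(frozen=True)
class StimulusIntensity:
    """A presented stimulus intensity: nC/ph for ICMS, percent for auditory."""

    modality: Modality
    value: float
    charge_limit_nc: float = field(default=DEFAULT_CHARGE_LIMIT_NC, compare=False)

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("intensity must be >= 0")
        if self.modality is Modality.ICMS and self.value > self.charge_limit_nc:
            raise ValueError(
                f"ICMS intensity {self.value} nC/ph exceeds charge limit "
                f"{self.charge_limit_nc} nC/ph"
            )
        if self.modality is Modality.AUDITORY and self.value > 100:
            raise ValueError("auditory intensity may not exceed 100% amplitude")

    @property
    def units(self) -> str:
        return "nC/ph" if self.modality is Modality.ICMS else "% amplitude"
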