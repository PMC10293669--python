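"""Trace the up/down staircase against a deterministic observer.

Drives the staircase controller with an observer that detects exactly when
the intensity is at or above its threshold (1.3 nC/ph here). The dynamic
intensity descends from the 3 nC/ph naive anchor in coarse steps, then
hovers near the threshold as the scheduled step size shrinks from 1.00 to
0.20 nC/ph across the session.
"""

from nosepoke import Outcome, init_staircase, update

TRUE_THRESHOLD = 1.3  # nC/ph

state = init_staircase(naive_intensity=3.0)
minute = 20.0  # the first 20 minutes present only anchor/catch trials
print("minute  intensity  outcome")
while minute < 60.0:
    outcome = (
        Outcome.HIT if state.dynamic_intensity >= TRUE_THRESHOLD else Outcome.MISS
    )
    update(state, outcome, minute, jitter=False)
    if int(minute * 10) % 20 == 0:  # print every ~2 minutes
        print(f"{minute:6.1f}  {state.dynamic_intensity:9.2f}  {outcome.value}")
    minute += 0.3

final = [v for t, v, _ in state.history if t >= 50]
lo, hi = min(final), max(final)
print(f"\nminutes 50-60 intensities span [{lo:.2f}, {hi:.2f}] nC/ph")
print(f"true threshold {TRUE_THRESHOLD} nC/ph lies within one final step "
      f"(0.20 nC/ph) of every late intensity: "
      f"{all(abs(v - TRUE_THRESHOLD) <= 0.2 for v in final)}")
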