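"""Modified up/down staircase controlling the dynamic stimulus intensity.

The threshold-detection task tracks one dynamic intensity per session. It
starts at the animal's naive threshold (the maximum), decreases by the
scheduled step size after a hit on a dynamic trial, and increases by the
same rule after a miss, hovering near the perception threshold. Outcomes of
anchor and catch trials never move the staircase. The intensity is clamped
to [0, naive]; when a drawn step exceeds the available headroom it saturates
at the clamp rather than redrawing. During the first 20 minutes of a session
no dynamic trials occur and the staircase is frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .scheduler import StepSchedule, step_size
from .session_types import Outcome
from .stimuli import Modality

__all__ = ["StaircaseState", "init_staircase", "update"]


@dataclass
class StaircaseState:
    """Current dynamic intensity, its anchor, and the step history."""

    dynamic_intensity: float
    naive_intensity: float
    modality: Modality
    history: list[tuple[float, float, Outcome]] = field(default_factory=list)
    # history rows: (session_time_min, intensity_after_update, outcome)


def init_staircase(
    naive_intensity: float, modality: Modality = Modality.ICMS
) -> StaircaseState:
    """Start a session's staircase at the naive anchor intensity."""
    if naive_intensity <= 0:
        raise ValueError("naive anchor intensity must be > 0")
    return StaircaseState(
        dynamic_intensity=naive_intensity,
        naive_intensity=naive_intensity,
        modality=Modality(modality),
    )


def update(
    state: StaircaseState,
    outcome: Outcome,
    session_time_min: float,
    rng: np.random.Generator | None = None,
    jitter: bool = True,
    schedule: StepSchedule | None = None,
) -> StaircaseState:
    """Step the staircase after a *dynamic* trial's outcome (in place).

    A hit lowers the dynamic intensity by the scheduled step, a miss raises
    it; the result is clamped to [0, naive_intensity]. Only hit/miss
    outcomes are legal here — catch and anchor trials must not be routed
    through the staircase.
    """
    outcome = Outcome(outcome)
    if outcome not in (Outcome.HIT, Outcome.MISS):
        raise ValueError(
            f"staircase updates take dynamic-trial outcomes (hit/miss), got {outcome}"
        )
    step = step_size(session_time_min, state.modality, rng, jitter, schedule)
    delta = -step if outcome is Outcome.HIT else step
    new_val = min(max(state.dynamic_intensity + delta, 0.0), state.naive_intensity)
    state.dynamic_intensity = new_val
    state.history.append((session_time_min, new_val, outcome))
    return state
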