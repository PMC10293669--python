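"""Shared record types for session logs: trials, events, outcomes."""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Any

from .scheduler import Phase, TrialKind

__all__ = ["Outcome", "TrialRecord", "Event", "SessionLog"]


class Outcome(str, enum.Enum):
    """The four signal-detection outcomes of a go/no-go trial."""

    HIT = "hit"
    MISS = "miss"
    FALSE_ALARM = "false_alarm"
    CORRECT_REJECTION = "correct_rejection"


#: Outcomes legal for stimulus-bearing vs catch trials.
STIMULUS_OUTCOMES = frozenset({Outcome.HIT, Outcome.MISS})
CATCH_OUTCOMES = frozenset({Outcome.FALSE_ALARM, Outcome.CORRECT_REJECTION})


@dataclass
class TrialRecord:
    """One completed trial.

    Times are integer milliseconds from session start; ``poke_times_ms`` are
    raw pokes relative to trial start (before the 150 ms lockout is applied).
    ``intensity_value`` is None on catch trials. ``timeout_s`` is the total
    timeout actually served (0 when unpunished); ``distracted`` marks trials
    annotated as disengaged, excluded from all metrics.
    """

    index: int
    phase: Phase
    trial_type: TrialKind
    intensity_value: float | None
    intensity_units: str | None
    trial_start_ms: int
    trial_window_s: float
    hit_window_s: float
    poke_times_ms: list[float]
    outcome: Outcome
    punished: bool
    timeout_s: float
    distracted: bool

    @property
    def minute(self) -> int:
        return self.trial_start_ms // 60_000

    @property
    def first_poke_ms(self) -> float | None:
        return min(self.poke_times_ms) if self.poke_times_ms else None


@dataclass(frozen=True)
class Event:
    """Symbolic session event (poke, pellet, air puff, light change, pause)."""

    time_ms: int
    kind: str
    detail: str = ""


@dataclass
class SessionLog:
    """Everything recorded during one 1-hour session.

    ``config`` is a plain-dict snapshot of the run configuration (including
    the seed and, for simulated animals, the ground-truth observer
    parameters, so parameter-recovery studies can compare against truth).
    """

    config: dict[str, Any]
    seed: int
    trials: list[TrialRecord] = field(default_factory=list)
    events: list[Event] = field(default_factory=list)
    pellets: int = 0
    manual_dispenses: int = 0

    def trials_of_kind(self, kind: TrialKind) -> list[TrialRecord]:
        return [t for t in self.trials if t.trial_type is TrialKind(kind)]
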