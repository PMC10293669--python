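"""Signal-detection performance metrics with the paired zero-count correction.

A session's outcomes form a 2x2 confusion table: stimulus trials yield hits
or misses, catch trials yield false alarms or correct rejections. Rates of
exactly 0 or 1 make d' infinite, so before computing scores a zero cell is
replaced by 0.5 and its paired non-zero counterpart reduced by 0.5 (pair
sums are preserved exactly). Scores follow the standard definitions:

    accuracy  = (H + CR) / (H + M + FA + CR)
    precision = H / (H + FA)
    hit rate  = H / (H + M)
    CR rate   = CR / (CR + FA)
    F1        = 2 * precision * hit_rate / (precision + hit_rate)
    d'        = z(hit rate) - z(false-alarm rate),   z = Phi^-1

with false-alarm rate = FA / (FA + CR) = 1 - CR rate.

Tier-proficiency gates are also evaluated here: Shaping requires >= 100
pellets with no manual dispenses in two consecutive sessions; Shape2Detect
requires accuracy, precision and hit rate >= 75% plus >= 100 pellets in two
consecutive sessions; Detection requires all five fraction metrics >= 75%
and d' >= 1.5 in three total sessions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import norm

from .scheduler import Phase

__all__ = [
    "ConfusionCounts",
    "PerformanceScores",
    "zero_correct",
    "scores",
    "d_prime",
    "counts_from_trials",
    "confusion_matrix",
    "ProficiencyResult",
    "proficiency",
    "SessionSummary",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Hits / misses / false alarms / correct rejections for one session.

    Raw counts are integers; after zero correction half-counts appear.
    """

    hits: float
    misses: float
    false_alarms: float
    correct_rejections: float

    def __post_init__(self) -> None:
        for name in ("hits", "misses", "false_alarms", "correct_rejections"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def n_stimulus(self) -> float:
        return self.hits + self.misses

    @property
    def n_catch(self) -> float:
        return self.false_alarms + self.correct_rejections


def zero_correct(counts: ConfusionCounts) -> ConfusionCounts:
    """Apply the paired 0.5 adjustment to zero cells.

    Within each pair (hits/misses and false_alarms/correct_rejections) a zero
    member becomes 0.5 and its counterpart loses 0.5, so pair sums are
    preserved; pairs without a zero are untouched. A session with 119 hits
    and 0 misses becomes 118.5 hits and 0.5 misses.

    Raises
    ------
    ValueError
        If both members of a pair are zero (no trials of that kind were
        presented, so rates are undefined).
    """

    def adjust(a: float, b: float, pair: str) -> tuple[float, float]:
        if a == 0 and b == 0:
            raise ValueError(f"no {pair} trials in session; rates undefined")
        if a == 0:
            return 0.5, b - 0.5
        if b == 0:
            return a - 0.5, 0.5
        return a, b

    h, m = adjust(counts.hits, counts.misses, "stimulus")
    fa, cr = adjust(counts.false_alarms, counts.correct_rejections, "catch")
    return ConfusionCounts(h, m, fa, cr)


def d_prime(hit_rate: float, false_alarm_rate: float) -> float:
    """Sensitivity index d' = z(hit rate) - z(false-alarm rate)."""
    for name, r in (("hit_rate", hit_rate), ("false_alarm_rate", false_alarm_rate)):
        if not 0 < r < 1:
            raise ValueError(
                f"{name}={r} outside (0, 1); apply zero_correct to the counts first"
            )
    return float(norm.ppf(hit_rate) - norm.ppf(false_alarm_rate))


@dataclass(frozen=True)
class PerformanceScores:
    accuracy: float
    precision: float
    hit_rate: float
    correct_rejection_rate: float
    f1: float
    d_prime: float

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "hit_rate": self.hit_rate,
            "correct_rejection_rate": self.correct_rejection_rate,
            "f1": self.f1,
            "d_prime": self.d_prime,
        }


def scores(counts: ConfusionCounts) -> PerformanceScores:
    """Compute the six performance scores from zero-corrected counts.

    ``counts`` must already be zero-corrected (or contain no zero cells);
    otherwise d' is undefined and a ``ValueError`` is raised.
    """
    h, m = counts.hits, counts.misses
    fa, cr = counts.false_alarms, counts.correct_rejections
    total = h + m + fa + cr
    if h + m == 0 or fa + cr == 0 or h + fa == 0:
        raise ValueError("degenerate counts; apply zero_correct first")
    precision = h / (h + fa)
    hit_rate = h / (h + m)
    cr_rate = cr / (cr + fa)
    return PerformanceScores(
        accuracy=(h + cr) / total,
        precision=precision,
        hit_rate=hit_rate,
        correct_rejection_rate=cr_rate,
        f1=2 * precision * hit_rate / (precision + hit_rate),
        d_prime=d_prime(hit_rate, 1 - cr_rate),
    )


def counts_from_trials(trials: Iterable) -> ConfusionCounts:
    """Tally raw confusion counts from trial records.

    Accepts any iterable of objects (or mapping rows) exposing ``outcome``
    and ``distracted``; distracted trials are excluded before counting.
    """
    tally = {"hit": 0, "miss": 0, "false_alarm": 0, "correct_rejection": 0}
    for t in trials:
        outcome = t["outcome"] if isinstance(t, dict) else t.outcome
        distracted = t["distracted"] if isinstance(t, dict) else t.distracted
        if distracted:
            continue
        key = getattr(outcome, "value", outcome)
        tally[key] += 1
    return ConfusionCounts(
        tally["hit"], tally["miss"], tally["false_alarm"], tally["correct_rejection"]
    )


def confusion_matrix(counts: ConfusionCounts) -> pd.DataFrame:
    """2x2 table, rows = presented trial type, columns = animal response."""
    return pd.DataFrame(
        {
            "poke": [counts.hits, counts.false_alarms],
            "no_poke": [counts.misses, counts.correct_rejections],
        },
        index=pd.Index(["stimulus", "catch"], name="presented"),
    )


@dataclass(frozen=True)
class SessionSummary:
    """Per-session inputs to the proficiency gates."""

    scores: PerformanceScores | None
    pellets: int = 0
    manual_dispenses: int = 0


@dataclass(frozen=True)
class ProficiencyResult:
    passed: bool
    reasons: tuple[str, ...]  # criteria that failed, empty when passed


_FRACTION_METRICS = (
    "accuracy", "precision", "hit_rate", "correct_rejection_rate", "f1",
)


def _session_failures(s: SessionSummary, tier: Phase) -> list[str]:
    fails: list[str] = []
    if tier is Phase.SHAPING:
        if s.pellets < 100:
            fails.append("pellets")
        if s.manual_dispenses > 0:
            fails.append("manual_dispenses")
        return fails
    assert s.scores is not None, "training tiers beyond Shaping require scores"
    metric_names = (
        _FRACTION_METRICS[:3] if tier is Phase.SHAPE2DETECT else _FRACTION_METRICS
    )
    for name in metric_names:
        if getattr(s.scores, name) < 0.75:
            fails.append(name)
    if tier is Phase.SHAPE2DETECT and s.pellets < 100:
        fails.append("pellets")
    if tier is Phase.DETECTION and s.scores.d_prime < 1.5:
        fails.append("d_prime")
    return fails


def proficiency(history: Sequence[SessionSummary], tier: Phase) -> ProficiencyResult:
    """Evaluate a tier's proficiency gate over the session history.

    Shaping and Shape2Detect require their per-session criteria to hold in
    two *consecutive* sessions; Detection requires them in three sessions
    *total* (not necessarily consecutive). ``reasons`` lists the criteria
    that failed in the most recent session (or the consecutiveness /
    session-count shortfall).
    """
    tier = Phase(tier)
    if tier is Phase.THRESHOLD_DETECTION:
        raise ValueError("the threshold-detection task has no proficiency gate")
    per_session = [_session_failures(s, tier) for s in history]
    if tier is Phase.DETECTION:
        n_pass = sum(not f for f in per_session)
        if n_pass >= 3:
            return ProficiencyResult(True, ())
        reasons = tuple(per_session[-1]) if history and per_session[-1] else ()
        return ProficiencyResult(False, reasons or ("sessions",))
    run = 0
    for fails in per_session:
        run = 0 if fails else run + 1
        if run >= 2:
            return ProficiencyResult(True, ())
    reasons = tuple(per_session[-1]) if history and per_session[-1] else ()
    return ProficiencyResult(False, reasons or ("consecutive_sessions",))
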