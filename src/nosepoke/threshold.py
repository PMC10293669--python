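"""Quantal dose-response estimation of perception thresholds (ED50).

Dynamic-trial responses from the threshold-detection task are binned by
presented intensity (0.5 nC/ph increments for ICMS, 1% amplitude for
auditory) into per-bin percent hit rates, and a Hill-type sigmoid

    y = 100 * x^HillSlope / (ED50^HillSlope + x^HillSlope)

is fitted by unweighted least squares jointly over an animal's sessions:
one ED50 per session, one Hill slope shared across all of that animal's
sessions. ED50 — the dose producing a 50% hit rate — is the operational
perception threshold; it is constrained positive via a log-parameter
transform. The animal-level threshold is the mean +/- standard error of
its session ED50s.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .scheduler import TrialKind
from .session_types import Outcome, SessionLog
from .stimuli import Modality

__all__ = [
    "DoseResponsePoint",
    "PsychometricFit",
    "DEFAULT_BIN_WIDTH",
    "bin_responses",
    "fit_quantal",
    "estimate_threshold",
    "hill_percent",
]

#: Default bin widths per modality: 0.5 nC/ph (ICMS), 1% amplitude (auditory).
DEFAULT_BIN_WIDTH = {Modality.ICMS: 0.5, Modality.AUDITORY: 1.0}

SLOPE_BOUNDS = (0.1, 20.0)


def hill_percent(x, ed50: float, slope: float):
    """The fitted curve: 100 * x^s / (ED50^s + x^s), vectorized over x."""
    x = np.asarray(x, dtype=float)
    out = np.zeros_like(x)
    pos = x > 0
    r = (ed50 / x[pos]) ** slope
    out[pos] = 100.0 / (1.0 + r)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class DoseResponsePoint:
    """One bin of the quantal dose-response: center dose, % hit rate, n."""

    dose: float
    hit_rate_percent: float
    n_trials: int

    def __post_init__(self) -> None:
        if self.n_trials < 1:
            raise ValueError("a dose-response point needs at least one trial")
        if not 0 <= self.hit_rate_percent <= 100:
            raise ValueError("hit_rate_percent must lie in [0, 100]")


def bin_responses(
    dynamic_trials: Iterable, bin_width: float = 0.5
) -> list[DoseResponsePoint]:
    """Bin dynamic-trial hit/miss responses into percent hit rate per dose.

    Bins are half-open ``[k*w, (k+1)*w)`` and labeled by their centers;
    empty bins are omitted. ``dynamic_trials`` is any iterable of objects or
    mapping rows exposing ``intensity_value`` and ``outcome`` (hit/miss).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    hits: dict[int, int] = {}
    totals: dict[int, int] = {}
    n_seen = 0
    for t in dynamic_trials:
        x = t["intensity_value"] if isinstance(t, dict) else t.intensity_value
        outcome = t["outcome"] if isinstance(t, dict) else t.outcome
        outcome = Outcome(getattr(outcome, "value", outcome))
        if outcome not in (Outcome.HIT, Outcome.MISS):
            raise ValueError(f"dynamic trials must be hit/miss, got {outcome}")
        k = math.floor(x / bin_width)
        totals[k] = totals.get(k, 0) + 1
        hits[k] = hits.get(k, 0) + (outcome is Outcome.HIT)
        n_seen += 1
    if n_seen == 0:
        raise ValueError("no dynamic trials to bin")
    return [
        DoseResponsePoint(
            dose=(k + 0.5) * bin_width,
            hit_rate_percent=100.0 * hits[k] / totals[k],
            n_trials=totals[k],
        )
        for k in sorted(totals)
    ]


@dataclass(frozen=True)
class PsychometricFit:
    """Joint-fit result: per-session ED50s, shared slope, pooled threshold."""

    ed50_per_session: tuple[float, ...]
    shared_hillslope: float
    threshold_mean: float
    threshold_sem: float
    residual_sumsq: float

    @property
    def n_sessions(self) -> int:
        return len(self.ed50_per_session)


def _session_identifiable(points: Sequence[DoseResponsePoint]) -> bool:
    rates = {p.hit_rate_percent for p in points}
    if len(points) < 2:
        return False
    if all(r == 0.0 for r in rates) or all(r == 100.0 for r in rates):
        return False
    return True


def _objective(theta, sessions):
    log_slope, log_ed50s = theta[0], theta[1:]
    s = math.exp(log_slope)
    res = []
    for log_e, pts in zip(log_ed50s, sessions):
        ed50 = math.exp(log_e)
        x = np.array([p.dose for p in pts])
        y = np.array([p.hit_rate_percent for p in pts])
        res.append(hill_percent(x, ed50, s) - y)
    return np.concatenate(res)


def fit_quantal(
    points_by_session: Sequence[Sequence[DoseResponsePoint]],
) -> PsychometricFit:
    """Fit the shared-slope Hill model across sessions by least squares.

    Minimizes the unweighted squared error of the percent-hit-rate curve
    jointly over all sessions, with one ED50 per session and a single Hill
    slope shared between them. Positivity of ED50 (and the slope bounds
    [0.1, 20]) are enforced by optimizing in log space; several starting
    points guard against local minima. Sessions whose binned data are
    degenerate (fewer than two bins, or all 0% / all 100%) are dropped with
    a warning rather than failing the animal-level estimate.
    """
    sessions = [list(pts) for pts in points_by_session]
    keep = [i for i, pts in enumerate(sessions) if _session_identifiable(pts)]
    dropped = [i for i in range(len(sessions)) if i not in keep]
    if dropped:
        warnings.warn(
            f"dropping non-identifiable session(s) {dropped} from the fit",
            stacklevel=2,
        )
    sessions = [sessions[i] for i in keep]
    if not sessions:
        raise ValueError("no identifiable sessions: all binned data degenerate")
    all_doses = {p.dose for pts in sessions for p in pts}
    if len(all_doses) < 2:
        raise ValueError("need at least two distinct doses to fit")

    def crossing_guess(pts: Sequence[DoseResponsePoint]) -> float:
        best = min(pts, key=lambda p: abs(p.hit_rate_percent - 50.0))
        return max(best.dose, 1e-6)

    ed50_init = [crossing_guess(pts) for pts in sessions]
    lo = np.concatenate(
        ([math.log(SLOPE_BOUNDS[0])], np.full(len(sessions), -30.0))
    )
    hi = np.concatenate(
        ([math.log(SLOPE_BOUNDS[1])], np.full(len(sessions), 30.0))
    )
    best = None
    for s0 in (1.0, 2.0, 5.0):
        theta0 = np.concatenate(([math.log(s0)], np.log(ed50_init)))
        sol = least_squares(
            _objective, theta0, args=(sessions,), bounds=(lo, hi),
            xtol=1e-10, ftol=1e-10, gtol=1e-10,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    slope = math.exp(best.x[0])
    ed50s = tuple(math.exp(v) for v in best.x[1:])
    mean = float(np.mean(ed50s))
    sem = (
        float(np.std(ed50s, ddof=1) / math.sqrt(len(ed50s)))
        if len(ed50s) > 1
        else float("nan")
    )
    return PsychometricFit(
        ed50_per_session=ed50s,
        shared_hillslope=slope,
        threshold_mean=mean,
        threshold_sem=sem,
        residual_sumsq=float(2 * best.cost),
    )


def dynamic_trials_of(log: SessionLog) -> list:
    """The non-distracted dynamic trials of a threshold-detection session."""
    return [
        t for t in log.trials_of_kind(TrialKind.DYNAMIC) if not t.distracted
    ]


def estimate_threshold(
    session_logs: Sequence[SessionLog],
    modality: Modality,
    bin_width: float | None = None,
) -> tuple[PsychometricFit, list[pd.DataFrame]]:
    """Animal-level threshold report from threshold-detection sessions.

    Bins each session's dynamic trials, jointly fits the shared-slope Hill
    model, and returns the fit together with per-session dose-response
    tables (columns: dose, hit_rate_percent, n_trials).
    """
    if not session_logs:
        raise ValueError("at least one session log is required")
    modality = Modality(modality)
    w = bin_width if bin_width is not None else DEFAULT_BIN_WIDTH[modality]
    points = [bin_responses(dynamic_trials_of(log), w) for log in session_logs]
    tables = [
        pd.DataFrame(
            {
                "dose": [p.dose for p in pts],
                "hit_rate_percent": [p.hit_rate_percent for p in pts],
                "n_trials": [p.n_trials for p in pts],
            }
        )
        for pts in points
    ]
    return fit_quantal(points), tables
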