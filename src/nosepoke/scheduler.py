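"""Session-time-dependent task parameters and trial-type sampling.

The go/no-go task runs in 1-hour sessions whose behavioral parameters are
piecewise constant in session time. During the Shape2Detect training tier the
trial window, stimulus probability, hit window and timeout all change across
five printed segments; the Detection tier (and the threshold-detection task
that follows it) uses fixed constants equal to the final Shape2Detect
segment's pacing (6 s trial window, 50% stimulus probability, 3 s hit window,
8 s timeout). The threshold-detection task additionally varies the staircase
step size across session time, with an optional uniform jitter around each
segment's central step ("+/-" variation).

Segment boundaries are half-open ``[start, end)`` in minutes, so minute 10
belongs to the "10-19" row.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .stimuli import Modality

__all__ = [
    "Phase",
    "TrialKind",
    "TrialParams",
    "ScheduleSegment",
    "PhaseSchedule",
    "StepSegment",
    "StepSchedule",
    "NoStepVariationError",
    "SHAPE2DETECT_SCHEDULE",
    "DETECTION_PARAMS",
    "STEP_SCHEDULES",
    "SESSION_MINUTES",
    "lookup_params",
    "sample_trial_type",
    "step_size",
]

SESSION_MINUTES = 60


class Phase(str, enum.Enum):
    """Training tiers and the final threshold-estimation task."""

    SHAPING = "shaping"
    SHAPE2DETECT = "shape2detect"
    DETECTION = "detection"
    THRESHOLD_DETECTION = "threshold_detection"


class TrialKind(str, enum.Enum):
    """What is presented on a trial.

    ``STIMULUS`` covers training-phase stimulus trials; the threshold task
    distinguishes ``NAIVE_ANCHOR`` (fixed naive-threshold intensity) from
    ``DYNAMIC`` (staircase-controlled intensity). ``CATCH`` presents nothing.
    """

    STIMULUS = "stimulus"
    NAIVE_ANCHOR = "naive_anchor"
    DYNAMIC = "dynamic"
    CATCH = "catch"


@dataclass(frozen=True)
class TrialParams:
    """Behavioral parameters in force for one trial."""

    trial_window_s: float
    stimulus_probability: float
    hit_window_s: float
    timeout_s: float

    def __post_init__(self) -> None:
        if not 0 <= self.stimulus_probability <= 1:
            raise ValueError("stimulus_probability must lie in [0, 1]")
        if self.hit_window_s > self.trial_window_s:
            raise ValueError("hit window may not exceed trial window")


@dataclass(frozen=True)
class ScheduleSegment:
    start_min: int
    end_min: int  # exclusive
    params: TrialParams


@dataclass(frozen=True)
class PhaseSchedule:
    """Ordered segments tiling [0, 60) minutes with behavioral parameters."""

    segments: tuple[ScheduleSegment, ...]

    def __post_init__(self) -> None:
        edge = 0
        for seg in self.segments:
            if seg.start_min != edge:
                raise ValueError("segments must tile the session without gaps")
            if seg.end_min <= seg.start_min:
                raise ValueError("segment end must exceed start")
            edge = seg.end_min
        if edge != SESSION_MINUTES:
            raise ValueError(f"segments must cover [0, {SESSION_MINUTES}) minutes")

    def at(self, session_time_min: float) -> TrialParams:
        if not 0 <= session_time_min < SESSION_MINUTES:
            raise ValueError(
                f"session time {session_time_min} min outside [0, {SESSION_MINUTES})"
            )
        for seg in self.segments:
            if seg.start_min <= session_time_min < seg.end_min:
                return seg.params
        raise AssertionError("unreachable: segments tile the session")


def _const_schedule(params: TrialParams) -> PhaseSchedule:
    return PhaseSchedule((ScheduleSegment(0, SESSION_MINUTES, params),))


#: Shape2Detect tier: probabilities stored as the printed percentages / 100.
SHAPE2DETECT_SCHEDULE = PhaseSchedule(
    (
        ScheduleSegment(0, 10, TrialParams(3, 0.833, 3, 2)),
        ScheduleSegment(10, 20, TrialParams(3, 0.714, 3, 3)),
        ScheduleSegment(20, 30, TrialParams(4, 0.667, 4, 3)),
        ScheduleSegment(30, 40, TrialParams(5, 0.600, 5, 5)),
        ScheduleSegment(40, 60, TrialParams(6, 0.500, 3, 8)),
    )
)

#: Detection tier (also inherited by the threshold-detection task).
DETECTION_PARAMS = TrialParams(6, 0.500, 3, 8)

_DEFAULT_SCHEDULES: dict[Phase, PhaseSchedule] = {
    Phase.SHAPE2DETECT: SHAPE2DETECT_SCHEDULE,
    Phase.DETECTION: _const_schedule(DETECTION_PARAMS),
    Phase.THRESHOLD_DETECTION: _const_schedule(DETECTION_PARAMS),
    # Shaping has an indefinite trial window; the stored window is unused by
    # the engine, which rewards the first effective poke whenever it comes.
    Phase.SHAPING: _const_schedule(TrialParams(6, 1.0, 6, 8)),
}


def lookup_params(
    phase: Phase,
    session_time_min: float,
    schedule: PhaseSchedule | None = None,
) -> TrialParams:
    """Behavioral parameters in force at ``session_time_min`` for a phase.

    Returns the covering Shape2Detect segment for that tier and the fixed
    Detection constants for the Detection and ThresholdDetection phases.
    Raises ``ValueError`` for times outside [0, 60) minutes.
    """
    sched = schedule if schedule is not None else _DEFAULT_SCHEDULES[Phase(phase)]
    return sched.at(session_time_min)


#: Minutes before which the threshold task presents only anchor/catch trials
#: and the staircase is frozen.
ANCHOR_ONLY_MINUTES = 20


def sample_trial_type(
    phase: Phase,
    session_time_min: float,
    rng: np.random.Generator,
    schedule: PhaseSchedule | None = None,
) -> TrialKind:
    """Draw the trial type presented at this point in the session.

    Training phases present a stimulus trial with the scheduled probability
    and a catch trial otherwise. The threshold-detection task presents the
    naive anchor with 50% probability (catch otherwise) for the first 20
    minutes, then anchor / dynamic / catch each with probability 1/3.
    """
    phase = Phase(phase)
    if phase is Phase.THRESHOLD_DETECTION:
        # Validate the session time against the schedule either way.
        lookup_params(phase, session_time_min, schedule)
        if session_time_min < ANCHOR_ONLY_MINUTES:
            return TrialKind.NAIVE_ANCHOR if rng.random() < 0.5 else TrialKind.CATCH
        u = rng.random()
        if u < 1 / 3:
            return TrialKind.NAIVE_ANCHOR
        if u < 2 / 3:
            return TrialKind.DYNAMIC
        return TrialKind.CATCH
    p = lookup_params(phase, session_time_min, schedule).stimulus_probability
    return TrialKind.STIMULUS if rng.random() < p else TrialKind.CATCH


@dataclass(frozen=True)
class StepSegment:
    start_min: int
    end_min: int  # exclusive
    central_step: float
    jitter_halfwidth: float

    def __post_init__(self) -> None:
        if self.central_step <= 0:
            raise ValueError("central step must be > 0")
        if not 0 <= self.jitter_halfwidth < self.central_step:
            raise ValueError("jitter halfwidth must lie in [0, central step)")


@dataclass(frozen=True)
class StepSchedule:
    """Staircase step magnitudes per session-time segment for one modality.

    The first ``ANCHOR_ONLY_MINUTES`` of the session carry no variation:
    requesting a step there raises :class:`NoStepVariationError`.
    """

    segments: tuple[StepSegment, ...]

    def segment_at(self, session_time_min: float) -> StepSegment:
        if session_time_min < ANCHOR_ONLY_MINUTES:
            raise NoStepVariationError(
                f"no step variation before minute {ANCHOR_ONLY_MINUTES} "
                f"(got {session_time_min})"
            )
        for seg in self.segments:
            if seg.start_min <= session_time_min < seg.end_min:
                return seg
        raise ValueError(f"session time {session_time_min} min outside the schedule")


class NoStepVariationError(Exception):
    """The staircase is frozen at this session time (first 20 minutes)."""


#: Step-size variation across the session: central step +/- uniform jitter.
STEP_SCHEDULES: dict[Modality, StepSchedule] = {
    Modality.ICMS: StepSchedule(
        (
            StepSegment(20, 30, 1.00, 0.40),
            StepSegment(30, 40, 0.60, 0.20),
            StepSegment(40, 50, 0.40, 0.10),
            StepSegment(50, 60, 0.20, 0.05),
        )
    ),
    Modality.AUDITORY: StepSchedule(
        (
            StepSegment(20, 30, 20.00, 5.00),
            StepSegment(30, 40, 10.00, 3.00),
            StepSegment(40, 50, 1.00, 0.30),
            StepSegment(50, 60, 0.10, 0.03),
        )
    ),
}


def step_size(
    session_time_min: float,
    modality: Modality,
    rng: np.random.Generator | None = None,
    jitter: bool = True,
    schedule: StepSchedule | None = None,
) -> float:
    """Staircase step magnitude at this session time.

    With ``jitter`` off the central step of the covering segment is returned;
    with jitter on, a value is drawn uniformly from
    ``[central - halfwidth, central + halfwidth]``. Times before minute 20
    raise :class:`NoStepVariationError` (the staircase is frozen there).
    """
    sched = schedule if schedule is not None else STEP_SCHEDULES[Modality(modality)]
    seg = sched.segment_at(session_time_min)
    if not jitter or seg.jitter_halfwidth == 0:
        return seg.central_step
    if rng is None:
        raise ValueError("rng required when jitter is enabled")
    return rng.uniform(
        seg.central_step - seg.jitter_halfwidth,
        seg.central_step + seg.jitter_halfwidth,
    )
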