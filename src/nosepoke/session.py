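"""Trial-by-trial state machine of the go/no-go nose-poke task.

A session is a sequence of trials separated by 3 s white-light inter-trial
periods. A green light marks the trial window; pokes in the first 150 ms are
ignored (sensor lockout against accidental pokes at trial start). On a
stimulus trial the first effective poke inside the hit window earns a sugar
pellet (hit); a poke after the hit window but inside the trial window is a
miss punished with an air puff and a red-light timeout; silence is an
unpunished miss. On a catch trial any effective poke is a false alarm
(punished) and silence a correct rejection. Pokes during an active timeout
draw an additional air puff and reset the remaining timeout to its base
duration. If the animal fails to poke for 10 stimulus trials in a row the
session pauses (white light) and resumes on the next poke. Shaping, the
first training tier, instead rewards any effective poke during an
indefinite green-light period.

In the threshold-detection phase the engine routes dynamic-trial outcomes
through the up/down staircase and presents anchor trials at the naive
threshold; all of this runs against a supplied observer (simulated rat or a
replay source) under a single seeded RNG stream, so a (config, seed) pair
reproduces a session bit-exactly.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from . import staircase as _staircase
from .config import RunConfig
from .observer import ObserverModel, respond
from .scheduler import (
    SESSION_MINUTES,
    Phase,
    TrialKind,
    lookup_params,
    sample_trial_type,
)
from .session_types import Event, Outcome, SessionLog, TrialRecord

__all__ = [
    "apply_lockout",
    "classify_response",
    "run_timeout",
    "run_session",
    "LOCKOUT_S",
    "PAUSE_AFTER_CONSECUTIVE_SILENT",
]

LOCKOUT_S = 0.150
PAUSE_AFTER_CONSECUTIVE_SILENT = 10


def apply_lockout(
    poke_times_s: Sequence[float], lockout_s: float = LOCKOUT_S
) -> list[float]:
    """Drop pokes at or before the lockout (t <= 150 ms from trial start).

    The boundary is closed: a poke at exactly 150 ms is voided.
    """
    return [t for t in poke_times_s if t > lockout_s]


def classify_response(
    trial_kind: TrialKind,
    poke_times_s: Sequence[float],
    hit_window_s: float,
    trial_window_s: float,
    lockout_s: float = LOCKOUT_S,
) -> tuple[Outcome, bool]:
    """Classify one trial's pokes into its outcome and punishment flag.

    Stimulus-bearing trials: first effective poke within the hit window is a
    hit; an effective poke only in the trial remainder is a punished miss;
    no effective poke is an unpunished miss. Catch trials: any effective
    poke in the trial window is a punished false alarm, otherwise a correct
    rejection. The 150 ms lockout is applied before classification.
    """
    effective = apply_lockout(poke_times_s, lockout_s)
    in_window = [t for t in effective if t <= trial_window_s]
    if TrialKind(trial_kind) is TrialKind.CATCH:
        return (Outcome.FALSE_ALARM, True) if in_window else (
            Outcome.CORRECT_REJECTION, False)
    if not in_window:
        return Outcome.MISS, False
    first = min(in_window)
    if first <= hit_window_s:
        return Outcome.HIT, False
    return Outcome.MISS, True


def run_timeout(
    base_timeout_s: float, poke_times_s: Sequence[float] = ()
) -> tuple[float, int]:
    """Total timeout served and air puffs delivered.

    The triggering response itself draws one air puff and starts a timeout
    of ``base_timeout_s``. Each poke while the timeout is active draws a
    further puff and resets the remaining time to the full base duration
    (poke times are seconds from timeout start). Pokes after the timeout
    has elapsed are ignored.
    """
    if base_timeout_s <= 0:
        raise ValueError("base timeout must be > 0")
    end = base_timeout_s
    puffs = 1
    for t in sorted(poke_times_s):
        if t < end:
            end = t + base_timeout_s
            puffs += 1
    return end, puffs


def _simulate_timeout(
    base_timeout_s: float, observer: ObserverModel, rng: np.random.Generator
) -> tuple[float, int, list[float]]:
    """Draw the animal's pokes during a timeout and apply the reset rule.

    Each active stretch of timeout tempts one spontaneous poke with the
    observer's guess probability; the geometric escalation terminates with
    probability one since guess_rate < 1.
    """
    pokes: list[float] = []
    pos, end = 0.0, base_timeout_s
    while rng.random() < observer.guess_rate:
        pk = rng.uniform(pos, end)
        pokes.append(pk)
        pos, end = pk, pk + base_timeout_s
    total, puffs = run_timeout(base_timeout_s, pokes)
    return total, puffs, pokes


def run_session(config: RunConfig, rng: np.random.Generator | None = None) -> SessionLog:
    """Simulate one full session of the configured phase.

    Returns a :class:`SessionLog` with per-trial records and the symbolic
    event stream (pokes, pellets, air puffs, light changes, pauses). The
    RNG defaults to ``numpy.random.default_rng(config.seed)``; passing an
    explicit generator lets callers run several sessions off one stream.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    phase = Phase(config.phase)
    log = SessionLog(config=config.to_dict(), seed=config.seed)
    if phase is Phase.SHAPING:
        _run_shaping(config, rng, log)
    else:
        _run_discrimination(config, rng, log, phase)
    return log


def _run_shaping(
    config: RunConfig, rng: np.random.Generator, log: SessionLog
) -> None:
    session_end_ms = config.session_minutes * 60_000
    obs = config.observer
    t = 0
    log.events.append(Event(t, "light", "white"))
    index = 0
    while True:
        t += int(config.inter_trial_s * 1000)
        if t >= session_end_ms:
            break
        trial_start = t
        log.events.append(Event(t, "light", "green"))
        # Exponential wait for the first poke after the lockout; pokes
        # within the lockout do not trigger and the green light persists.
        latency_ms = config.lockout_s * 1000
        latency_ms += rng.exponential(obs.shaping_poke_mean_s * 1000)
        poke_abs = trial_start + latency_ms
        if poke_abs >= session_end_ms:
            log.events.append(Event(session_end_ms, "light", "off"))
            break
        t = int(poke_abs)
        log.events.append(Event(t, "poke"))
        log.events.append(Event(t, "pellet"))
        log.pellets += 1
        log.trials.append(
            TrialRecord(
                index=index, phase=Phase.SHAPING, trial_type=TrialKind.STIMULUS,
                intensity_value=None, intensity_units=None,
                trial_start_ms=trial_start,
                trial_window_s=(t - trial_start) / 1000.0,
                hit_window_s=(t - trial_start) / 1000.0,
                poke_times_ms=[latency_ms], outcome=Outcome.HIT,
                punished=False, timeout_s=0.0, distracted=False,
            )
        )
        log.events.append(Event(t, "light", "white"))
        index += 1


def _run_discrimination(
    config: RunConfig, rng: np.random.Generator, log: SessionLog, phase: Phase
) -> None:
    session_end_ms = config.session_minutes * 60_000
    obs = config.observer
    units = "nC/ph" if config.modality.value == "icms" else "% amplitude"
    stair = (
        _staircase.init_staircase(config.naive_intensity, config.modality)
        if phase is Phase.THRESHOLD_DETECTION
        else None
    )
    t = 0
    index = 0
    silent_streak = 0
    log.events.append(Event(t, "light", "white"))
    while True:
        t += int(config.inter_trial_s * 1000)
        if t >= session_end_ms:
            break
        minute = t / 60_000.0
        if minute >= SESSION_MINUTES:
            break
        params = lookup_params(phase, minute)
        kind = sample_trial_type(phase, minute, rng)
        if kind is TrialKind.CATCH:
            intensity = None
        elif kind is TrialKind.DYNAMIC:
            assert stair is not None
            intensity = stair.dynamic_intensity
        else:
            intensity = config.naive_intensity
        trial_start = t
        log.events.append(Event(t, "light", "green"))
        poke_times_ms, distracted = respond(
            kind, intensity if intensity is not None else 0.0,
            params.trial_window_s, params.hit_window_s, obs, rng,
        )
        outcome, punished = classify_response(
            kind, [p / 1000.0 for p in poke_times_ms],
            params.hit_window_s, params.trial_window_s, config.lockout_s,
        )
        for p in poke_times_ms:
            log.events.append(Event(int(trial_start + p), "poke"))
        # The trial ends at the decisive poke (reward or punishment) or at
        # the end of the trial window.
        effective = apply_lockout(
            [p / 1000.0 for p in poke_times_ms], config.lockout_s
        )
        decisive_s = min(effective) if effective else params.trial_window_s
        t = trial_start + int(decisive_s * 1000)
        timeout_s = 0.0
        if outcome is Outcome.HIT:
            log.pellets += 1
            log.events.append(Event(t, "pellet"))
        elif punished:
            total, puffs, to_pokes = _simulate_timeout(params.timeout_s, obs, rng)
            timeout_s = total
            log.events.append(Event(t, "light", "red"))
            for i, pk in enumerate(sorted(to_pokes)):
                log.events.append(Event(t + int(pk * 1000), "poke", "during_timeout"))
            for _ in range(puffs):
                log.events.append(Event(t, "air_puff"))
            t += int(total * 1000)
        log.trials.append(
            TrialRecord(
                index=index, phase=phase, trial_type=kind,
                intensity_value=intensity, intensity_units=(
                    units if intensity is not None else None),
                trial_start_ms=trial_start,
                trial_window_s=params.trial_window_s,
                hit_window_s=params.hit_window_s,
                poke_times_ms=list(poke_times_ms),
                outcome=outcome, punished=punished,
                timeout_s=timeout_s, distracted=distracted,
            )
        )
        index += 1
        log.events.append(Event(t, "light", "white"))
        # Staircase moves on dynamic-trial outcomes only (the rig steps in
        # real time, so distracted dynamic trials still move it).
        if kind is TrialKind.DYNAMIC and stair is not None:
            _staircase.update(stair, outcome, minute, rng, jitter=config.jitter)
        # 10-in-a-row silent stimulus trials pause the session until a poke.
        if kind is not TrialKind.CATCH:
            if poke_times_ms:
                silent_streak = 0
            else:
                silent_streak += 1
                if silent_streak >= PAUSE_AFTER_CONSECUTIVE_SILENT:
                    log.events.append(Event(t, "pause"))
                    wait_ms = rng.exponential(obs.pause_poke_mean_s * 1000)
                    t += int(wait_ms)
                    t = min(t, session_end_ms)
                    log.events.append(Event(t, "poke", "resume"))
                    log.events.append(Event(t, "resume"))
                    silent_streak = 0
    if stair is not None:
        log.config["staircase_history"] = [
            (tm, val, oc.value) for tm, val, oc in stair.history
        ]
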