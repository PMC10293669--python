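"""Simulated rat observer with a known ground-truth psychometric function.

The simulated animal detects a stimulus of intensity ``x`` with probability
governed by a Hill-type sigmoid,

    F(x) = x^s / (ED50^s + x^s),

mixed with a lapse rate (probability of ignoring a detected stimulus) and a
guess rate (probability of a spontaneous nose-poke in a trial window). The
marginal psychometric function reported by :func:`detection_probability` is

    p(x) = guess + (1 - guess - lapse) * F(x),

so an observer with guess = lapse = 0 pokes on exactly half of trials at its
true ED50. Because the ground truth is known, full closed-loop sessions can
be simulated and the threshold-estimation pipeline checked for parameter
recovery.

Behavioral mechanics: on a stimulus trial the animal detects with
probability (1 - lapse) * F(x) and, if it does, pokes once at stimulus onset
plus a reaction-time latency drawn from a normal distribution truncated to
(0, hit_window]. On catch trials and on undetected stimulus trials it may
emit one spontaneous poke, with probability ``guess_rate``, at a uniform
time in the trial window. The two mechanisms compose to a marginal poke
probability of guess + (1 - guess)(1 - lapse) F(x), which agrees with
``detection_probability`` to within guess*lapse (< 0.3% at default rates).
Each trial is independently flagged "distracted" with a small probability,
emulating experimenter annotation of disengaged trials; distracted trials
are excluded from performance metrics downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .scheduler import TrialKind

__all__ = ["ObserverModel", "detection_probability", "respond", "hill"]


def hill(intensity: float, ed50: float, slope: float) -> float:
    """Hill sigmoid x^s / (ED50^s + x^s), the quantal dose-response curve."""
    if intensity < 0:
        raise ValueError("intensity must be >= 0")
    if intensity == 0:
        return 0.0
    # Compute in log-ratio form so extreme slopes or tiny intensities
    # saturate instead of overflowing.
    t = slope * math.log(ed50 / intensity)
    if t > 700:
        return 0.0
    if t < -700:
        return 1.0
    return 1.0 / (1.0 + math.exp(t))


@dataclass(frozen=True)
class ObserverModel:
    """Ground-truth parameters of the simulated animal.

    Attributes
    ----------
    true_ed50 : float
        Intensity at which the underlying detection curve crosses 50%
        (nC/ph for ICMS, % amplitude for auditory).
    slope : float
        Hill exponent (steepness) of the detection curve.
    lapse_rate : float
        Probability of failing to act on a detected stimulus.
    guess_rate : float
        Probability of one spontaneous poke per trial window.
    latency_loc_ms, latency_scale_ms : float
        Location and scale of the reaction-time distribution (normal
        truncated to the hit window).
    distraction_rate : float
        Per-trial probability the animal is disengaged (trial annotated
        distracted and excluded from metrics).
    """

    true_ed50: float = 1.6
    slope: float = 5.0
    lapse_rate: float = 0.05
    guess_rate: float = 0.05
    latency_loc_ms: float = 800.0
    latency_scale_ms: float = 300.0
    distraction_rate: float = 0.0
    # Mean waits (exponential) for behaviors the task leaves open-ended:
    # poking during a Shaping green light, and resuming from a pause.
    shaping_poke_mean_s: float = 5.0
    pause_poke_mean_s: float = 30.0

    def __post_init__(self) -> None:
        if self.true_ed50 <= 0:
            raise ValueError("true_ed50 must be > 0")
        if self.slope <= 0:
            raise ValueError("slope must be > 0")
        for name in ("lapse_rate", "guess_rate", "distraction_rate"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.lapse_rate + self.guess_rate >= 1:
            raise ValueError("guess_rate + lapse_rate must be < 1")


def detection_probability(intensity: float, observer: ObserverModel) -> float:
    """Marginal probability of a poke on a stimulus trial at ``intensity``.

    ``p = guess + (1 - guess - lapse) * x^s / (ED50^s + x^s)``; monotonically
    non-decreasing in intensity, with floor ``guess`` and ceiling
    ``1 - lapse``.
    """
    f = hill(intensity, observer.true_ed50, observer.slope)
    return observer.guess_rate + (1 - observer.guess_rate - observer.lapse_rate) * f


def _truncated_normal_ms(
    loc: float, scale: float, upper_ms: float, rng: np.random.Generator
) -> float:
    """Draw from N(loc, scale) truncated to (0, upper_ms] by rejection."""
    if scale <= 0:
        return min(max(loc, 1e-6), upper_ms)
    for _ in range(1000):
        x = rng.normal(loc, scale)
        if 0 < x <= upper_ms:
            return x
    # Pathological parameterization: fall back to a uniform draw.
    return rng.uniform(0, upper_ms)


def respond(
    trial_kind: TrialKind,
    intensity: float,
    trial_window_s: float,
    hit_window_s: float,
    observer: ObserverModel,
    rng: np.random.Generator,
) -> tuple[list[float], bool]:
    """Simulate the animal's pokes for one trial.

    Parameters
    ----------
    trial_kind : TrialKind
        Catch trials present nothing (intensity ignored); all other kinds
        present a stimulus at ``intensity``.
    intensity : float
        Presented stimulus intensity in the modality's units.
    trial_window_s, hit_window_s : float
        Trial parameters in force (seconds).
    observer : ObserverModel
    rng : numpy.random.Generator

    Returns
    -------
    (poke_times_ms, distracted)
        Poke times in milliseconds from trial start (at most one), and the
        per-trial distraction flag. A distracted animal emits no pokes.
    """
    kind = TrialKind(trial_kind)
    distracted = rng.random() < observer.distraction_rate
    if distracted:
        return [], True
    detected = False
    if kind is not TrialKind.CATCH:
        p_detect = (1 - observer.lapse_rate) * hill(
            intensity, observer.true_ed50, observer.slope
        )
        detected = rng.random() < p_detect
    if detected:
        latency = _truncated_normal_ms(
            observer.latency_loc_ms, observer.latency_scale_ms,
            hit_window_s * 1000.0, rng,
        )
        return [latency], False
    if rng.random() < observer.guess_rate:
        return [rng.uniform(0.0, trial_window_s * 1000.0)], False
    return [], False
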