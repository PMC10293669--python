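# Methods

## The task

The paradigm is a tiered go/no-go operant task run in 1-hour sessions. A
green light marks a trial window during which either a stimulus (ICMS pulse
train or pure tone) or nothing (catch trial) is presented; the animal
nose-pokes to report detection. Stimulus trials resolve to a hit (poke
inside the hit window, rewarded with a sugar pellet) or a miss; catch
trials resolve to a false alarm (poke, punished with an air puff and a
red-light timeout) or a correct rejection. Pokes in the first 150 ms of a
trial are ignored (sensor lockout against accidental pokes); the boundary
is closed, so a poke at exactly 150 ms is voided. A poke after the hit
window but inside the trial window is a punished miss. Pokes during an
active timeout draw an extra air puff and reset the remaining timeout to
its base duration — the simplest rule consistent with "more time added"
escalation. Ten consecutive stimulus trials without any poke pause the
session until the next poke; catch trials neither advance nor reset this
counter. A punished poke ends the trial immediately.

Training tiers: **Shaping** (indefinite green-light periods, any effective
poke rewarded; proficiency = ≥100 pellets with no manual dispenses in two
consecutive sessions), **Shape2Detect** (time-varying trial windows 3→6 s,
stimulus probability 83.3→50%, hit windows and timeouts per the built-in
five-segment schedule; proficiency = accuracy, precision, hit rate ≥75%
plus ≥100 pellets in two consecutive sessions), and **Detection** (fixed
6 s window / 50% / 3 s hit window / 8 s timeout; proficiency = all five
fraction metrics ≥75% and d′ ≥ 1.5 in three sessions total). Schedule
segments are half-open `[start, end)` in minutes, so minute 10 takes the
10–19 row. The threshold-detection task inherits the Detection constants,
which immediately precede it in training.

## Stimuli

ICMS intensity is charge per phase, `Q = I · w` (µA × µs → nC/ph), capped
at 5 nC/ph per simultaneously pulsed channel. Pulse trains are
charge-balanced symmetric biphasic, cathodal-leading, 320 Hz, 200 µs/phase,
40 µs interphase gap, 650 ms trains; the pulse count is
`floor(duration × frequency)` so the whole train fits the stated duration.
Tones are 6 kHz sinusoids at 100 kHz sampling, 500 ms, with 50 ms linear
onset/offset ramps (linear is the simplest ramp consistent with a stated
"ramp duration"), amplitude-normalized to 0–100% of the training tone.
A percent→dB SPL helper uses `90 + 20·log10(pct/100)`; it is one
documented convention, provided for reporting only and never used in any
computation.

## The staircase

The threshold-detection task presents, for the first 20 minutes, only
naive-anchor trials (50%) and catch trials (50%); thereafter anchor,
dynamic, and catch trials each with probability 1/3. One staircase per
session tracks the dynamic intensity: it starts at the naive anchor (its
stated maximum), steps down after a dynamic-trial hit and up after a
dynamic-trial miss, and is clamped to [0, naive]. Anchor- and catch-trial
outcomes never move it — anchors serve as engagement probes. Step
magnitudes follow the four-segment schedule (ICMS: 1.00, 0.60, 0.40,
0.20 nC/ph central steps for minutes 20–29, 30–39, 40–49, 50–60); the
printed "±" variation is interpreted as uniform jitter around the central
step, togglable off for deterministic tests. A drawn step larger than the
remaining headroom saturates at the clamp rather than redrawing. The rig
steps in real time, so dynamic trials later annotated distracted still
move the staircase (they are excluded from analysis, not from the task).

## Metrics

Scores are computed per session from the confusion counts with distracted
trials excluded first. The zero-count correction operates pairwise
(hits/misses, false alarms/correct rejections): a zero cell becomes 0.5
and its counterpart loses 0.5, preserving pair sums exactly; a pair with
both cells zero is an undefined session and raises. d′ is the standard
signal-detection form z(hit rate) − z(FA/(FA+CR)) using the inverse normal
quantile; the false-alarm rate is 1 − correct-rejection rate.

## The simulated observer

The synthetic rat detects intensity *x* with probability
`(1 − lapse) · F(x)` where `F(x) = x^s/(ED50^s + x^s)`, and poking is
composed with a spontaneous-guess process: on catch trials and undetected
stimulus trials one spontaneous poke occurs with probability `guess`,
uniformly placed in the trial window. The marginal poke probability on a
stimulus trial is therefore `g + (1−g)(1−l)F(x)`, which matches the
package's reported psychometric function `g + (1−g−l)F(x)` to within
`g·l·F ≤ 0.25%` at the default rates; the decomposition keeps the 50%
crossing at the true ED50 while still producing false alarms at rate `g`.
Detected pokes occur at stimulus onset plus a reaction-time latency drawn
from a normal distribution truncated to (0, hit window] (defaults 800 ±
300 ms), so nearly all detections are hits while the tails produce
occasional lockout-voided or late pokes. Distraction is a per-trial
Bernoulli flag consumed by the metrics-exclusion path.

Defaults emulate a proficient implanted animal: true ED50 1.6 nC/ph with a
3 nC/ph naive anchor, Hill slope 5 (steep enough that the anchor is
detected ~96% of the time, reproducing the ≥90% hit-rate / d′ ≈ 3 regime a
trained animal shows while its threshold sits near half its anchor), guess
and lapse rates 0.05. Open-ended behaviors the task does not specify —
the wait to poke during a Shaping green light, and the wait to resume from
a pause — are modeled as exponential delays (means 5 s and 30 s). The
generator does not model learning across sessions, satiety/motivation
drift, serial dependence between trials, or reaction times that vary with
intensity; passing recovery tests therefore demonstrates correctness of
the estimation pipeline under a stationary observer, not robustness to
every behavior of a real rat.

## Threshold estimation

Dynamic trials (only; anchors are engagement probes and are excluded) are
binned into half-open dose bins labeled by their centers — 0.5 nC/ph for
ICMS, 1% amplitude for auditory — giving percent hit rate and trial count
per bin; empty bins are omitted. The Hill curve is fitted by *unweighted*
least squares on the binned percentages (matching the described
normalized-response regression procedure; per-bin n is retained in outputs
so users can re-fit weighted), jointly over sessions with one shared slope.
Positivity of ED50 and the slope bounds [0.1, 20] are enforced by
optimizing in log space with `scipy.optimize.least_squares` (TRF,
xtol/ftol/gtol 1e-10) from three slope starting points (1, 2, 5), with
per-session 50%-crossing initial ED50s. Sessions whose binned data are
degenerate (fewer than two bins, all 0% or all 100%) are dropped with a
warning rather than failing the animal-level report; if all sessions are
degenerate the fit raises.

A note on estimator bias: fitting the pure 0–100% curve to responses that
have a guess floor and a lapse ceiling (and a lockout that voids ~1.5% of
detected pokes at the default latency parameters) biases the recovered
ED50 upward by roughly 2% under the default observer. This mirrors the
estimation procedure as practiced; the package reports what that procedure
measures rather than correcting for the observer's nuisance parameters.

## Problem sizes and numerical choices

Simulated sessions run the full 60 minutes (roughly 350–550 trials
depending on phase and observer); recovery studies in the test suite use 5
sessions per replicate and up to 50 replicates, sizes at which the session
ED50 dispersion (SD ≈ 0.05–0.15 nC/ph) is comparable to the
between-session spread reported for trained animals. Scheduler-frequency
checks use 10^4–10^5 draws with 3-standard-error tolerances. All session
time is integer milliseconds from session start; a single
`numpy.random.Generator` stream per session, seeded from the config,
makes every output byte reproducible from (config, seed).
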