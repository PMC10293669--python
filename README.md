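# nosepoke

Hardware-free simulation and analysis of a **go/no-go nose-poke behavioral
paradigm** for estimating stimulation-evoked perception thresholds in rats.

Intracortical microstimulation (ICMS) of somatosensory cortex evokes
percepts whose detectability must be measured behaviorally: the animal
nose-pokes when it feels the stimulus ("go") and withholds otherwise
("no-go"). This package reimplements the complete behavioral pipeline as
software — the tiered session engine (Shaping → Shape2Detect → Detection),
a modified up/down staircase for the threshold-detection task,
signal-detection performance metrics, and quantal dose–response (ED50)
threshold estimation — driven end-to-end by a simulated rat observer with a
known ground-truth psychometric function. It is intended for behavioral
neuroscientists and neuroprosthetics engineers who want to prototype task
schedules, validate analysis code against known ground truth, or analyze
trial logs exported from a real rig.

## The model

The animal's detection of a stimulus of intensity *x* (charge per phase in
nC/ph for ICMS, percent amplitude for tones) follows a Hill-type sigmoid

```
y = 100 · x^h / (ED50^h + x^h)
```

where *h* is the Hill slope and ED50 — the dose producing a 50% hit rate —
is the operational perception threshold. Dynamic-trial responses from the
staircase task are binned by dose (0.5 nC/ph or 1% amplitude increments)
and the curve is fitted by unweighted least squares jointly over an
animal's sessions, with one ED50 per session and a single Hill slope shared
across sessions; ED50 is constrained positive. The animal-level threshold
is the mean ± SEM of its session ED50s.

Session performance uses standard signal-detection scores — accuracy,
precision, hit rate, correct-rejection rate, F1, and
d′ = z(hit rate) − z(false-alarm rate) — computed after a paired zero-count
correction (a zero cell becomes 0.5 and its paired counterpart loses 0.5,
so no rate is exactly 0 or 1).

## Worked example

Simulate one animal's five 1-hour threshold-detection sessions and estimate
its threshold (`examples/04_threshold_estimation.py`):

```python
from nosepoke import Modality, Phase, RunConfig, estimate_threshold, run_session

logs = [run_session(RunConfig(phase=Phase.THRESHOLD_DETECTION, seed=300 + i))
        for i in range(5)]
fit, tables = estimate_threshold(logs, Modality.ICMS)
```

Output:

```
session ED50s (nC/ph): 1.46 1.61 1.54 1.63 1.81
shared Hill slope: 3.88
estimated perception threshold: 1.61 +/- 0.06 nC/ph
```

The default simulated rat has a true ED50 of 1.60 nC/ph with 5% guess and
lapse rates; the pipeline recovers it from the staircase-sampled hit/miss
data to within a few hundredths of a nC/ph. The other scripts in
`examples/` cover stimulus parameterization (`01`), a scored Detection
session with its proficiency gate (`02`), and a staircase trace against a
deterministic observer (`03`).

A thin CLI wraps the same functions for shell use:

```bash
nosepoke simulate --phase threshold_detection --seed 1 --sessions 5 --out-dir runs/
nosepoke metrics runs/*_trials.csv
nosepoke fit runs/*_trials.csv --out fit.json
nosepoke report runs/*.jsonl
```

## File formats

* **Session log** (`.jsonl`): one JSON object per line — a `header` record
  (config snapshot, seed, pellet counts) followed by `trial` and `event`
  records. Round-trips exactly through `write_session_log` /
  `read_session_log`.
* **Trial CSV**: columns `trial_index, phase, minute, trial_type,
  intensity_value, intensity_units, outcome, first_poke_ms, punished,
  timeout_s, distracted`. Intensity units are `nC/ph` (ICMS) or
  `% amplitude` (auditory); times are milliseconds from session start.
  External rigs can write this format to use the analysis path alone.
* **Fit report** (JSON): per-session ED50s, shared Hill slope, pooled
  mean ± SEM, bin width, modality.

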