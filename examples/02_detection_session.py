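"""Simulate a Detection-tier session and score it.

Runs a 1-hour go/no-go Detection session (fixed 6 s trial window, 50%
stimulus probability, 3 s hit window, 8 s timeouts) with the default
simulated rat, then computes the signal-detection scores after the paired
zero-count correction and checks the tier's proficiency gate.
"""

from nosepoke import (
    Phase,
    RunConfig,
    SessionSummary,
    confusion_matrix,
    counts_from_trials,
    proficiency,
    run_session,
    scores,
    zero_correct,
)

cfg = RunConfig(phase=Phase.DETECTION, seed=42)
log = run_session(cfg)
counts = counts_from_trials(log.trials)
print(f"{len(log.trials)} trials, {log.pellets} pellets")
print(confusion_matrix(counts), "\n")

s = scores(zero_correct(counts))
for name, value in s.as_dict().items():
    print(f"{name:>24}: {value:.3f}")
# Hit and correct-rejection rates near 0.9-0.95 with d' around 3 are the
# proficient-animal regime; d' > 1.5 and all five fraction scores >= 0.75
# pass the Detection gate when sustained over three sessions.

summary = SessionSummary(s, pellets=log.pellets)
gate = proficiency([summary] * 3, Phase.DETECTION)
print(f"\nDetection proficiency over 3 such sessions: "
      f"{'PASS' if gate.passed else 'FAIL ' + str(gate.reasons)}")
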