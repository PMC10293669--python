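import dataclasses

import numpy as np
import pytest

from nosepoke import (
    ObserverModel,
    Outcome,
    Phase,
    RunConfig,
    TrialKind,
    apply_lockout,
    classify_response,
    run_session,
    run_timeout,
)
from nosepoke.io import write_session_log
from nosepoke.session import PAUSE_AFTER_CONSECUTIVE_SILENT


class TestApplyLockout:
    def test_early_poke_removed(self):
        assert apply_lockout([0.05, 0.40]) == [0.40]

    def test_empty(self):
        assert apply_lockout([]) == []

    def test_boundary_poke_at_150ms_voided(self):
        assert apply_lockout([0.150]) == []
        assert apply_lockout([0.1500001]) == [0.1500001]


class TestClassifyResponse:
    def test_poke_in_hit_window_is_hit(self):
        outcome, punished = classify_response(TrialKind.STIMULUS, [1.0], 3, 6)
        assert outcome is Outcome.HIT and not punished

    def test_silence_is_unpunished_miss(self):
        outcome, punished = classify_response(TrialKind.STIMULUS, [], 3, 6)
        assert outcome is Outcome.MISS and not punished

    def test_lockout_voided_poke_then_late_poke_is_punished_miss(self):
        # first poke falls in the 150 ms lockout, second in the trial
        # remainder: classified as a miss with punishment
        outcome, punished = classify_response(
            TrialKind.STIMULUS, [0.10, 4.5], 3, 6
        )
        assert outcome is Outcome.MISS and punished

    def test_catch_trial_outcomes(self):
        assert classify_response(TrialKind.CATCH, [], 3, 6) == (
            Outcome.CORRECT_REJECTION, False)
        assert classify_response(TrialKind.CATCH, [2.0], 3, 6) == (
            Outcome.FALSE_ALARM, True)

    def test_catch_poke_inside_lockout_only_is_correct_rejection(self):
        outcome, punished = classify_response(TrialKind.CATCH, [0.05], 3, 6)
        assert outcome is Outcome.CORRECT_REJECTION and not punished

    @pytest.mark.parametrize(
        "kind", [TrialKind.STIMULUS, TrialKind.NAIVE_ANCHOR, TrialKind.DYNAMIC]
    )
    def test_stimulus_bearing_kinds_share_rules(self, kind):
        outcome, _ = classify_response(kind, [0.5], 3, 6)
        assert outcome is Outcome.HIT


class TestRunTimeout:
    def test_clean_timeout_serves_base_with_entry_puff(self):
        assert run_timeout(8.0) == (8.0, 1)

    def test_poke_resets_remaining_to_base(self):
        assert run_timeout(8.0, [4.0]) == (12.0, 2)

    def test_cascading_pokes_hand_trace(self):
        # end=2; poke@1 -> end=3; poke@2.5 -> end=4.5; 3 puffs total
        assert run_timeout(2.0, [1.0, 2.5]) == (4.5, 3)

    def test_poke_after_timeout_elapsed_ignored(self):
        assert run_timeout(2.0, [5.0]) == (2.0, 1)

    def test_nonpositive_base_rejected(self):
        with pytest.raises(ValueError):
            run_timeout(0.0)


def _ideal_observer(**kw):
    """Detects everything, never guesses, fixed 500 ms latency."""
    return ObserverModel(
        true_ed50=1e-6, slope=5, lapse_rate=0.0, guess_rate=0.0,
        latency_loc_ms=500, latency_scale_ms=0.0, distraction_rate=0.0, **kw
    )


def _deaf_observer():
    """Never detects, never pokes."""
    return ObserverModel(
        true_ed50=1e9, slope=5, lapse_rate=0.0, guess_rate=0.0,
        latency_scale_ms=0.0,
    )


class TestRunSession:
    def test_ideal_observer_hits_everything(self):
        cfg = RunConfig(
            phase=Phase.DETECTION, seed=11, observer=_ideal_observer()
        )
        log = run_session(cfg)
        stim = [t for t in log.trials if t.trial_type is TrialKind.STIMULUS]
        catch = [t for t in log.trials if t.trial_type is TrialKind.CATCH]
        assert stim and catch
        assert all(t.outcome is Outcome.HIT for t in stim)
        assert all(t.outcome is Outcome.CORRECT_REJECTION for t in catch)
        assert log.pellets == len(stim)

    def test_never_poking_observer_pauses_after_ten_silent_trials(self):
        cfg = RunConfig(phase=Phase.DETECTION, seed=12, observer=_deaf_observer())
        log = run_session(cfg)
        assert all(
            t.outcome in (Outcome.MISS, Outcome.CORRECT_REJECTION)
            for t in log.trials
        )
        pauses = [e for e in log.events if e.kind == "pause"]
        assert pauses, "pause rule never engaged"
        # the first pause comes exactly after the 10th consecutive silent
        # stimulus trial
        silent = 0
        first_pause_start = None
        for t in log.trials:
            if t.trial_type is not TrialKind.CATCH:
                silent += 1
                if silent == PAUSE_AFTER_CONSECUTIVE_SILENT:
                    first_pause_start = t
                    break
        assert first_pause_start is not None
        assert pauses[0].time_ms >= first_pause_start.trial_start_ms

    def test_fixed_seed_reproduces_log_exactly(self, tmp_path):
        cfg = RunConfig(phase=Phase.THRESHOLD_DETECTION, seed=13)
        a, b = run_session(cfg), run_session(cfg)
        assert [dataclasses.asdict(t) for t in a.trials] == [
            dataclasses.asdict(t) for t in b.trials
        ]
        assert a.events == b.events
        pa, pb = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
        write_session_log(a, pa)
        write_session_log(b, pb)
        assert pa.read_bytes() == pb.read_bytes()

    def test_outcome_partition_and_trial_spacing(self, detection_log):
        log = detection_log
        stim = [t for t in log.trials if t.trial_type is not TrialKind.CATCH]
        catch = [t for t in log.trials if t.trial_type is TrialKind.CATCH]
        assert all(
            t.outcome in (Outcome.HIT, Outcome.MISS) for t in stim
        )
        assert all(
            t.outcome in (Outcome.FALSE_ALARM, Outcome.CORRECT_REJECTION)
            for t in catch
        )
        hits = sum(t.outcome is Outcome.HIT for t in log.trials)
        assert log.pellets == hits
        starts = [t.trial_start_ms for t in log.trials]
        assert all(b - a >= 3000 for a, b in zip(starts, starts[1:]))

    def test_replaying_pokes_reproduces_recorded_outcomes(self, detection_log):
        for t in detection_log.trials:
            outcome, punished = classify_response(
                t.trial_type,
                [p / 1000.0 for p in t.poke_times_ms],
                t.hit_window_s,
                t.trial_window_s,
            )
            assert outcome is t.outcome
            assert punished == t.punished

    def test_session_ends_within_the_hour(self, detection_log):
        assert detection_log.trials[-1].trial_start_ms < 60 * 60_000

    def test_shaping_rewards_every_poke(self):
        cfg = RunConfig(phase=Phase.SHAPING, seed=14)
        log = run_session(cfg)
        assert log.pellets == len(log.trials) > 100
        assert all(t.outcome is Outcome.HIT for t in log.trials)
        # every poke comes after the lockout
        assert all(t.poke_times_ms[0] > 150 for t in log.trials)

    def test_threshold_session_staircase_monotone_segments(self):
        cfg = RunConfig(phase=Phase.THRESHOLD_DETECTION, seed=15)
        log = run_session(cfg)
        hist = log.config["staircase_history"]
        assert hist, "no dynamic trials stepped the staircase"
        assert all(0.0 <= v <= cfg.naive_intensity for _, v, _ in hist)
        dyn = log.trials_of_kind(TrialKind.DYNAMIC)
        assert dyn and all(t.minute >= 20 for t in dyn)
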