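"""Influence statistic, trial alignment, shuffle null, exclusion, success."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import perturbmap as pm
from perturbmap.influence import (EmptyTrialsError, InsufficientTrialsError,
                                  TrialWindows, align_trials,
                                  classify_influence, compute_influence,
                                  event_window_means, influence_statistic,
                                  proximity_exclusion, shuffle_null)


class TestAlignTrials:
    def test_constant_trace(self):
        tw = align_trials(np.full(200, 3.0), [50, 100, 150])
        assert np.allclose(tw.pre, 3.0) and np.allclose(tw.post, 3.0)

    def test_step_at_onset(self):
        activity = np.zeros(300)
        onsets = [50, 120, 200]
        for o in onsets:
            activity[o:] += 1.0
        tw = align_trials(activity, onsets)
        assert np.allclose(tw.post - tw.pre, 1.0)

    def test_matches_bruteforce_loop(self, rng):
        activity = rng.normal(size=400)
        onsets = np.array([30, 95, 170, 260, 350])
        tw = align_trials(activity, onsets, pre_len=10, post_len=10)
        for i, o in enumerate(onsets):
            assert tw.pre[i] == pytest.approx(
                np.mean([activity[t] for t in range(o - 10, o)]), abs=1e-12)
            assert tw.post[i] == pytest.approx(
                np.mean([activity[t] for t in range(o + 1, o + 11)]), abs=1e-12)

    def test_edge_trials_dropped(self):
        tw = align_trials(np.zeros(100), [5, 50, 95])
        assert tw.pre.size == 1

    def test_all_trials_unusable_raises(self):
        with pytest.raises(EmptyTrialsError):
            align_trials(np.zeros(30), [2])

    def test_vectorized_matches_scalar_path(self, rng):
        activity = rng.normal(size=(4, 300))
        onsets = np.array([40, 120, 210])
        pre, post, valid = event_window_means(activity, onsets)
        assert valid.all()
        for j in range(4):
            tw = align_trials(activity[j], onsets)
            assert np.allclose(pre[:, j], tw.pre, atol=1e-12)
            assert np.allclose(post[:, j], tw.post, atol=1e-12)


class TestInfluenceStatistic:
    def test_zero_differences(self):
        tw = TrialWindows(pre=np.zeros(4), post=np.zeros(4))
        assert compute_influence(tw) == 0.0

    def test_hand_computed_example(self):
        # d = [2, 0, 1, 1]: mean 1, sample SD sqrt(2/3)
        tw = TrialWindows(pre=np.zeros(4), post=np.array([2.0, 0.0, 1.0, 1.0]))
        assert compute_influence(tw) == pytest.approx(1.0 / np.sqrt(2.0 / 3.0))
        assert compute_influence(tw) == pytest.approx(1.224745, abs=1e-6)

    def test_too_few_trials(self):
        with pytest.raises(InsufficientTrialsError):
            influence_statistic(np.array([1.0]))

    def test_degenerate_flagged(self):
        value, degenerate = influence_statistic(np.array([2.0, 2.0, 2.0]))
        assert degenerate and np.isnan(value)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-50.0, 50.0))
    def test_invariant_to_additive_offset(self, c):
        rng = np.random.default_rng(7)
        activity = rng.normal(size=500)
        onsets = [50, 150, 250, 350, 450]
        a = compute_influence(align_trials(activity, onsets))
        b = compute_influence(align_trials(activity + c, onsets))
        assert a == pytest.approx(b, abs=1e-8)

    def test_sign_flip_equivariance(self, rng):
        d = rng.normal(size=30)
        v1, _ = influence_statistic(d)
        v2, _ = influence_statistic(-d)
        assert v1 == pytest.approx(-v2)


class TestClassify:
    def test_tie_is_none(self):
        assert classify_influence(1.0, -1.0, 1.0) == "none"

    def test_far_above_is_positive(self):
        assert classify_influence(10.0, -1.0, 1.0) == "positive"
        assert classify_influence(-10.0, -1.0, 1.0) == "negative"

    def test_identical_nulls_strictly_exceeded(self, rng):
        # all shuffle influences identical -> thresholds equal; observed
        # strictly greater is positive
        activity = np.zeros((2, 1300))
        onsets = np.arange(20, 1280, 30)
        targets = np.tile([0, 1], len(onsets) // 2 + 1)[:len(onsets)]
        stim = pd.DataFrame({"target_id": targets, "onset_frame": onsets,
                             "trial_index": np.arange(len(onsets))})
        lo, hi = shuffle_null(activity, stim, 0, n_shuffles=50, seed=1)
        assert np.allclose(lo, 0.0) and np.allclose(hi, 0.0)
        assert classify_influence(0.5, lo[0], hi[0]) == "positive"

    def test_shuffle_determinism(self, rng):
        activity = rng.normal(size=(3, 2000))
        onsets = np.arange(30, 1950, 30)
        targets = np.tile([0, 1, 2], len(onsets) // 3 + 1)[:len(onsets)]
        stim = pd.DataFrame({"target_id": targets, "onset_frame": onsets,
                             "trial_index": np.arange(len(onsets))})
        a = shuffle_null(activity, stim, 0, n_shuffles=100, seed=5)
        b = shuffle_null(activity, stim, 0, n_shuffles=100, seed=5)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestProximityExclusion:
    def test_examples(self):
        positions = np.array([[0.0, 0.0], [3.0, 4.0], [30.0, 40.0]])
        rec = pd.DataFrame({"target_id": [0, 0], "neuron_id": [1, 2],
                            "sig_class": ["positive", "positive"]})
        out = proximity_exclusion(rec, positions, radius=25.0)
        assert out["distance_um"].tolist() == [5.0, 50.0]
        assert out["excluded"].tolist() == [True, False]
        assert out["sig_class"].tolist()[0] is None

    def test_counts_match_bruteforce(self, rng):
        positions = rng.uniform(0, 300, size=(40, 2))
        pairs = [(t, n) for t in range(5) for n in range(40) if n != t]
        rec = pd.DataFrame(pairs, columns=["target_id", "neuron_id"])
        out = proximity_exclusion(rec, positions, radius=25.0)
        brute = sum(np.hypot(*(positions[t] - positions[n])) < 25.0
                    for t, n in pairs)
        assert out["excluded"].sum() == brute

    def test_missing_position_rejected(self):
        rec = pd.DataFrame({"target_id": [0], "neuron_id": [5]})
        with pytest.raises(ValueError):
            proximity_exclusion(rec, np.zeros((3, 2)))


class TestNullCalibration:
    def test_null_session_statistic_and_call_rates(self, null_mid):
        """On a no-effect session the influence statistic is centered on
        zero with SD ~ 1/sqrt(n_trials), and both 1%-tail call rates stay
        near their nominal level."""
        rec = pm.map_influence(null_mid, n_shuffles=500, seed=21)
        ret = rec.loc[~rec["excluded"]]
        assert len(ret) > 500
        n_trials = null_mid.params.n_repeats
        assert abs(ret["influence"].mean()) < 0.1
        assert 0.5 / np.sqrt(n_trials) < ret["influence"].std() \
            < 2.0 / np.sqrt(n_trials)
        pos = (ret["sig_class"] == "positive").mean()
        neg = (ret["sig_class"] == "negative").mean()
        assert 0.0 <= pos < 0.03
        assert 0.0 <= neg < 0.035

    def test_observed_inside_null_interval_for_most_pairs(self, rng):
        """Activity independent of stimulation falls inside the [1st, 99th]
        null interval for ~98% of pairs."""
        activity = rng.normal(size=(30, 3000))
        onsets = np.arange(20, 2980, 15)
        targets = np.tile(np.arange(10), len(onsets) // 10 + 1)[:len(onsets)]
        stim = pd.DataFrame({"target_id": targets, "onset_frame": onsets,
                             "trial_index": np.arange(len(onsets))})
        pre, post, _ = event_window_means(activity, onsets)
        inside = 0
        total = 0
        for tid in range(10):
            own = targets == tid
            d = post[own] - pre[own]
            obs = d.mean(axis=0) / d.std(axis=0, ddof=1)
            lo, hi = shuffle_null(activity, stim, tid, n_shuffles=400, seed=tid)
            inside += int(((obs >= lo) & (obs <= hi)).sum())
            total += obs.size
        assert inside / total > 0.93


class TestTargetSuccess:
    def test_opsin_targets_succeed_controls_fail(self, small_ac):
        success = small_ac.processed["target_success"]
        opsin = [t for t in small_ac.target_ids
                 if not small_ac.control_target[t]]
        ctrl = [t for t in small_ac.target_ids if small_ac.control_target[t]]
        assert np.mean([success[int(t)] for t in opsin]) >= 0.8
        assert sum(success[int(t)] for t in ctrl) <= 1

    def test_records_only_from_successful_noncontrol_targets(self, small_ac):
        rec = small_ac.processed["influence_records"]
        success = small_ac.processed["target_success"]
        for tid in rec["target_id"].unique():
            assert success[int(tid)]
            assert not small_ac.control_target[tid]
        # the target itself never appears as a measured neuron
        assert not np.any(rec["target_id"].to_numpy()
                          == rec["neuron_id"].to_numpy())


class TestGroundTruthRecovery:
    def test_influence_tracks_true_effect(self, strong_session):
        """Measured influence correlates with the generator's ground-truth
        rate change across pairs (Spearman > 0.5 at high SNR)."""
        from scipy.stats import spearmanr
        s = strong_session
        rec = s.processed["influence_records"].loc[
            lambda df: ~df["excluded"]]
        row_of = {int(t): k for k, t in enumerate(s.target_ids)}
        true = np.array([s.true_effect[row_of[int(t)], int(n)]
                         for t, n in zip(rec["target_id"], rec["neuron_id"])])
        rho = spearmanr(true, rec["influence"]).statistic
        assert rho > 0.5

    def test_positive_calls_concentrate_near_target(self, strong_session):
        rec = strong_session.processed["influence_records"]
        ret = rec.loc[~rec["excluded"]]
        near = ret.loc[ret["distance_um"] < 50.0]
        far = ret.loc[ret["distance_um"] > 200.0]
        frac_near = (near["sig_class"] == "positive").mean()
        frac_far = (far["sig_class"] == "positive").mean()
        assert frac_near > frac_far
        assert frac_near > 0.2
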