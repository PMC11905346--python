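"""Generator: kernel shape, protocol geometry, determinism, null sessions."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom

import perturbmap as pm
from perturbmap.params import GroundTruthParams
from perturbmap.syndata import ProtocolError, influence_kernel

TINY = dict(n_neurons=40, som_fraction=0.1, n_targets=4, n_control_targets=1,
            n_repeats=5, n_tone_repeats=0)


def _params(**over):
    d = dict(TINY)
    d.update(over)
    return GroundTruthParams(**d)


class TestInfluenceKernel:
    def test_value_at_zero_distance(self):
        p = _params(center_amp=1.0, surround_amp=0.2)
        assert influence_kernel(0.0, p) == pytest.approx(0.8)

    def test_pure_gaussian_is_monotone(self):
        p = _params(center_amp=1.0, surround_amp=0.0)
        d = np.linspace(0, 400, 100)
        k = influence_kernel(d, p)
        assert np.all(np.diff(k) <= 0)

    def test_matches_scalar_formula(self):
        p = _params(center_amp=1.0, center_sigma=50.0,
                    surround_amp=0.3, surround_sigma=150.0)
        expected = math.exp(-100.0 ** 2 / (2 * 50.0 ** 2)) \
            - 0.3 * math.exp(-100.0 ** 2 / (2 * 150.0 ** 2))
        assert influence_kernel(100.0, p) == pytest.approx(expected, rel=1e-12)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            influence_kernel(-1.0, _params())

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.0, 500.0))
    def test_depends_only_on_magnitude(self, d):
        p = _params()
        assert influence_kernel(d, p) == influence_kernel(abs(-d), p)

    def test_bounded_by_center_amp(self):
        p = _params(center_amp=2.0, surround_amp=0.5)
        d = np.linspace(0, 1000, 200)
        k = influence_kernel(d, p)
        assert np.all(k <= 2.0) and np.all(k >= -0.5)


class TestParamsInvariants:
    def test_surround_must_be_wider(self):
        with pytest.raises(ValueError):
            _params(center_sigma=100.0, surround_sigma=50.0)

    @pytest.mark.parametrize("field,value", [
        ("som_fraction", 1.5), ("n_repeats", 0), ("center_sigma", -1.0),
        ("surround_amp", -0.1), ("neuropil_mix", 2.0)])
    def test_invalid_values_rejected(self, field, value):
        with pytest.raises(ValueError):
            _params(**{field: value})

    def test_json_round_trip(self):
        p = _params(seed=42)
        assert GroundTruthParams.from_json(p.to_json()) == p


class TestGenerateSession:
    def test_seed_determinism(self):
        a = pm.generate_session(_params(seed=3))
        b = pm.generate_session(_params(seed=3))
        assert np.array_equal(a.f_raw, b.f_raw)
        assert np.array_equal(a.positions, b.positions)
        assert a.stim_table.equals(b.stim_table)
        assert np.array_equal(a.true_effect, b.true_effect)

    def test_different_seeds_differ(self):
        a = pm.generate_session(_params(seed=3))
        b = pm.generate_session(_params(seed=4))
        assert not np.array_equal(a.f_raw, b.f_raw)

    def test_protocol_error_when_too_short(self):
        with pytest.raises(ProtocolError):
            pm.generate_session(_params(n_frames=100))

    def test_som_fraction_within_binomial_ci(self):
        p = GroundTruthParams(n_neurons=400, som_fraction=0.07, n_targets=4,
                              n_control_targets=0, n_repeats=3, seed=1)
        s = pm.generate_session(p)
        n_som = int((s.cell_type == "SOM").sum())
        lo, hi = binom.interval(0.99, 400, 0.07)
        assert lo <= n_som <= hi

    def test_onsets_respect_isi_and_cover_targets(self):
        p = _params(seed=6)
        s = pm.generate_session(p)
        onsets = np.sort(s.stim_table["onset_frame"].to_numpy())
        assert np.min(np.diff(onsets)) >= p.isi_frames
        # each repeat block stimulates every target exactly once
        n_tot = p.n_targets + p.n_control_targets
        order = s.stim_table.sort_values("onset_frame")["target_id"].to_numpy()
        for r in range(p.n_repeats):
            block = order[r * n_tot:(r + 1) * n_tot]
            assert sorted(block) == sorted(s.target_ids)
        for tid in s.target_ids:
            o = s.onsets_for(tid)
            assert np.all(np.diff(o) > 0)

    def test_positions_inside_fov_and_speed_nonnegative(self):
        p = _params(seed=2)
        s = pm.generate_session(p)
        assert np.all(s.positions >= 0) and np.all(s.positions <= p.fov_size)
        assert np.all(s.run_speed >= 0)

    def test_running_has_stationary_and_moving_bouts(self):
        s = pm.generate_session(_params(seed=8, n_repeats=20))
        frac_stationary = np.mean(s.run_speed == 0.0)
        assert 0.05 < frac_stationary < 0.95
        assert s.run_speed.max() > 1.0

    def test_zero_amp_params_give_null_true_effect(self):
        p = _params(center_amp=0.0, surround_amp=0.0, seed=1)
        s = pm.generate_session(p)
        off_target = s.true_effect.copy()
        for k, tid in enumerate(s.target_ids):
            off_target[k, tid] = 0.0
            near = np.linalg.norm(s.positions - s.positions[tid], axis=1) \
                <= p.direct_radius
            off_target[k, near] = 0.0
        assert np.allclose(off_target, 0.0)

    def test_true_effect_matches_kernel_for_plain_params(self):
        p = _params(like_to_like_strength=0.0, corr_influence_strength=0.0,
                    run_influence_gain=1.0, seed=12)
        s = pm.generate_session(p)
        k = 0
        tid = s.target_ids[0]
        d = np.linalg.norm(s.positions - s.positions[tid], axis=1)
        far = d > p.direct_radius
        assert np.allclose(s.true_effect[k, far],
                           influence_kernel(d[far], p), atol=1e-12)


class TestNullSession:
    def test_off_target_effect_is_zero(self):
        s = pm.generate_null_session(_params(seed=4))
        p = s.params
        for k, tid in enumerate(s.target_ids):
            d = np.linalg.norm(s.positions - s.positions[tid], axis=1)
            assert np.allclose(s.true_effect[k, d > p.direct_radius], 0.0)

    def test_direct_effect_only_on_target(self):
        s = pm.generate_null_session(_params(seed=4), direct_effect=True)
        for k, tid in enumerate(s.target_ids):
            if not s.control_target[tid]:
                assert s.true_effect[k, tid] > 0
        s0 = pm.generate_null_session(_params(seed=4), direct_effect=False)
        assert np.allclose(s0.true_effect, 0.0)
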