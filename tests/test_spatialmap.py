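"""Centered maps, distance distributions/profiles, center/surround fit."""

import numpy as np
import pandas as pd
import pytest

from perturbmap.spatialmap import (DistanceProfile, centered_influence_map,
                                   distance_binned_influence,
                                   distance_distributions, distance_table,
                                   fit_center_surround)


def _records(target_ids, neuron_ids, sig, dist, cell_type="NonSOM",
             influence=None):
    n = len(target_ids)
    return pd.DataFrame({
        "target_id": target_ids, "neuron_id": neuron_ids,
        "neuron_type": [cell_type] * n if isinstance(cell_type, str) else cell_type,
        "influence": influence if influence is not None else np.zeros(n),
        "sig_class": sig, "excluded": [False] * n, "distance_um": dist})


class TestCenteredMap:
    def test_two_targets_identical_offset(self):
        positions = np.array([[100.0, 100.0], [300.0, 300.0],
                              [130.0, 140.0], [330.0, 340.0]])
        rec = _records([0, 1], [2, 3], ["positive", "positive"], [50.0, 50.0])
        cmap = centered_influence_map(rec, positions, bin_size=20.0)
        assert cmap.grid.max() == pytest.approx(1.0)  # 2 neurons / 2 targets
        assert cmap.total() == pytest.approx(1.0)

    def test_no_influenced_neurons_all_zero(self):
        positions = np.zeros((3, 2))
        rec = _records([0, 1], [2, 2], ["none", "none"], [0.0, 0.0])
        cmap = centered_influence_map(rec, positions)
        assert np.all(cmap.grid == 0.0)

    def test_normalization_contract(self, rng):
        """Total map mass equals influenced count / target count exactly
        when the extent covers every offset."""
        n = 60
        positions = rng.uniform(0, 400, size=(n, 2))
        targets = [0, 1, 2]
        rows = []
        for t in targets:
            for j in range(3, n):
                sig = "positive" if rng.random() < 0.3 else "none"
                rows.append((t, j, sig,
                             float(np.linalg.norm(positions[t] - positions[j]))))
        rec = _records(*zip(*rows))
        cmap = centered_influence_map(rec, positions, bin_size=20.0, extent=700.0)
        count = (rec["sig_class"] == "positive").sum()
        assert cmap.total() == pytest.approx(count / len(targets), abs=1e-12)

    def test_mirrored_positions_give_mirrored_map(self):
        positions = np.array([[200.0, 200.0], [265.0, 222.0]])
        rec = _records([0], [1], ["positive"], [68.6])
        m1 = centered_influence_map(rec, positions, bin_size=20.0)
        mirrored = positions.copy()
        mirrored[:, 0] = 400.0 - mirrored[:, 0]
        m2 = centered_influence_map(rec, mirrored, bin_size=20.0)
        assert np.allclose(m1.grid, m2.grid[::-1, :])

    def test_zero_targets_rejected(self):
        rec = _records([], [], [], [])
        with pytest.raises(ValueError):
            centered_influence_map(rec, np.zeros((1, 2)))


class TestDistanceDistributions:
    def test_single_distance_step_cdf(self):
        rec = _records([0, 0], [1, 2], ["positive", "positive"], [80.0, 80.0])
        out = distance_distributions(rec)
        assert np.allclose(out[("positive", "NonSOM")], 80.0)
        assert out[("negative", "NonSOM")].size == 0  # n=0, no CDF

    def test_group_means_match_bruteforce(self, rng):
        n = 200
        sig = rng.choice(["positive", "negative", "none"], n, p=[0.2, 0.1, 0.7])
        ct = rng.choice(["NonSOM", "SOM"], n, p=[0.9, 0.1])
        dist = rng.uniform(25, 400, n)
        rec = _records(np.zeros(n, int), np.arange(1, n + 1), sig, dist, ct)
        tab = distance_table(rec)
        for _, row in tab.iterrows():
            if row["group"] == "all":
                sel = dist[ct == row["cell_type"]]
            else:
                cls = {"positively influenced": "positive",
                       "negatively influenced": "negative",
                       "un-influenced": "none"}[row["group"]]
                sel = dist[(ct == row["cell_type"]) & (sig == cls)]
            if sel.size:
                assert row["mean_distance_um"] == pytest.approx(sel.mean())
                assert row["n"] == sel.size

    def test_excluded_records_do_not_contribute(self):
        rec = _records([0, 0], [1, 2], ["positive", "positive"], [10.0, 100.0])
        rec.loc[0, "excluded"] = True
        tab = distance_table(rec)
        row = tab.loc[(tab["cell_type"] == "NonSOM") & (tab["group"] == "all")]
        assert row["n"].item() == 1


class TestDistanceBinnedInfluence:
    def test_zero_influence_flat_profile(self):
        rec = _records([0] * 10, np.arange(1, 11), ["none"] * 10,
                       np.linspace(30, 390, 10))
        prof = distance_binned_influence(rec)
        assert np.allclose(prof.mean_influence[prof.counts > 0], 0.0)

    def test_bin_means_match_bruteforce(self, rng):
        n = 300
        dist = rng.uniform(25, 425, n)
        infl = rng.normal(size=n)
        rec = _records(np.zeros(n, int), np.arange(1, n + 1), ["none"] * n,
                       dist, influence=infl)
        prof = distance_binned_influence(rec, bin_width=50.0, max_dist=400.0)
        edges = np.arange(25.0, 450.0, 50.0)
        for b in range(len(prof.bin_centers)):
            sel = (dist >= edges[b]) & (dist < edges[b + 1])
            if sel.any():
                assert prof.mean_influence[b] == pytest.approx(
                    infl[sel].mean(), abs=1e-12)
                assert prof.counts[b] == sel.sum()

    def test_bin_edges_start_at_exclusion_radius(self):
        prof = distance_binned_influence(
            _records([0], [1], ["none"], [30.0]), bin_width=50.0)
        assert prof.bin_centers[0] == pytest.approx(50.0)


class TestCenterSurroundFit:
    @staticmethod
    def _dog_profile(a_c, s_c, a_s, s_s, bw=25.0):
        d = np.arange(25.0 + bw / 2, 400.0, bw)
        y = a_c * np.exp(-d ** 2 / (2 * s_c ** 2)) \
            - a_s * np.exp(-d ** 2 / (2 * s_s ** 2))
        return DistanceProfile(bin_centers=d, mean_influence=y,
                               counts=np.full(d.size, 100),
                               cell_type="NonSOM", bin_width=bw)

    def test_exact_profile_recovered(self):
        prof = self._dog_profile(0.5, 50.0, 0.1, 180.0)
        fit = fit_center_surround(prof)
        assert fit.converged
        assert fit.residual < 0.01 * 0.5
        assert fit.center_sigma == pytest.approx(50.0, rel=0.01)
        assert fit.surround_sigma == pytest.approx(180.0, rel=0.05)

    def test_flat_profile_gives_zero_amplitudes(self):
        prof = self._dog_profile(0.0, 50.0, 0.0, 180.0)
        fit = fit_center_surround(prof)
        assert abs(fit.center_amp) < 1e-6 and abs(fit.surround_amp) < 1e-6

    def test_too_few_bins_rejected(self):
        prof = self._dog_profile(0.5, 50.0, 0.1, 180.0, bw=100.0)
        with pytest.raises(ValueError):
            fit_center_surround(prof)

    def test_generator_session_center_surround_shape(self, strong_session):
        """Radial structure from a high-SNR synthetic session: positive
        influence near the target, negative beyond the zero crossing."""
        rec = strong_session.processed["influence_records"]
        prof = distance_binned_influence(rec, bin_width=50.0)
        assert prof.mean_influence[0] > 0
        assert prof.mean_influence[3:6][prof.counts[3:6] > 0].mean() < 0
        # positive map is tighter than the negative map
        pos = distance_distributions(rec)[("positive", "NonSOM")]
        neg = distance_distributions(rec)[("negative", "NonSOM")]
        if pos.size > 10 and neg.size > 10:
            assert pos.mean() < neg.mean()
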