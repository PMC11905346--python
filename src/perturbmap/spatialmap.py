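"""Spatial structure of influence: target-centered maps, distance
distributions, distance-binned influence curves, and a center/surround
(difference-of-Gaussians) fit for parameter recovery.

Distance bins are 50 µm wide with edges [25, 75), [75, 125), ... so the
first bin starts at the 25 µm exclusion radius; intersomatic distance is
2-D Euclidean within the imaging plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CenteredMap",
    "DistanceProfile",
    "CenterSurroundFit",
    "centered_influence_map",
    "distance_distributions",
    "distance_table",
    "distance_binned_influence",
    "fit_center_surround",
]


def _retained(records: pd.DataFrame) -> pd.DataFrame:
    return records.loc[~records["excluded"].astype(bool)]


@dataclass
class CenteredMap:
    """Counts of significantly influenced neurons per target, accumulated
    on a grid of offsets relative to the (centered) target position."""

    grid: np.ndarray
    bin_size: float
    extent: float
    sign: str
    cell_type: str
    n_targets: int

    def total(self) -> float:
        """Equals (number of influenced neurons of this class) / n_targets."""
        return float(self.grid.sum())


@dataclass
class DistanceProfile:
    """Mean influence over all retained pairs, binned by distance."""

    bin_centers: np.ndarray
    mean_influence: np.ndarray
    counts: np.ndarray
    cell_type: str
    bin_width: float = 50.0


@dataclass
class CenterSurroundFit:
    """DoG fit A_c exp(-d²/2σc²) − A_s exp(-d²/2σs²) to a distance profile."""

    center_amp: float
    center_sigma: float
    surround_amp: float
    surround_sigma: float
    residual: float
    converged: bool
    stderr: np.ndarray | None = None
    message: str = ""

    def predict(self, d: np.ndarray) -> np.ndarray:
        return _dog(np.asarray(d, dtype=float), self.center_amp,
                    self.center_sigma, self.surround_amp, self.surround_sigma)


def centered_influence_map(records: pd.DataFrame, positions: np.ndarray,
                           sign: str = "positive", cell_type: str = "NonSOM",
                           bin_size: float = 20.0, extent: float = 400.0
                           ) -> CenteredMap:
    """Accumulate relative offsets (neuron − target) of significantly
    influenced neurons into bins, summed over targets and divided by the
    number of targets."""
    rec = _retained(records)
    target_ids = rec["target_id"].unique()
    n_targets = len(target_ids)
    if n_targets == 0:
        raise ValueError("no targets in records")
    sel = rec.loc[(rec["sig_class"] == sign) & (rec["neuron_type"] == cell_type)]
    nbins = int(np.ceil(2 * extent / bin_size))
    edges = -extent + bin_size * np.arange(nbins + 1)
    grid = np.zeros((nbins, nbins))
    if len(sel):
        off = positions[sel["neuron_id"].to_numpy()] - \
            positions[sel["target_id"].to_numpy()]
        inside = np.all(np.abs(off) < extent, axis=1)
        h, _, _ = np.histogram2d(off[inside, 0], off[inside, 1], bins=[edges, edges])
        grid = h
    return CenteredMap(grid=grid / n_targets, bin_size=bin_size, extent=extent,
                       sign=sign, cell_type=cell_type, n_targets=n_targets)


def distance_distributions(records: pd.DataFrame) -> dict[tuple[str, str], np.ndarray]:
    """Sorted intersomatic distances (empirical CDF support) per
    (sign, cell_type) class plus the all-neuron reference per cell type.

    Keys are (sign, cell_type) with sign in {'positive', 'negative', 'all'};
    empty classes are present with an empty array (n = 0, no CDF).
    """
    rec = _retained(records)
    out: dict[tuple[str, str], np.ndarray] = {}
    for ct in ("NonSOM", "SOM"):
        sub = rec.loc[rec["neuron_type"] == ct]
        out[("all", ct)] = np.sort(sub["distance_um"].to_numpy())
        for sign in ("positive", "negative"):
            d = sub.loc[sub["sig_class"] == sign, "distance_um"].to_numpy()
            out[(sign, ct)] = np.sort(d)
    return out


def distance_table(records: pd.DataFrame, area_tag: str = "") -> pd.DataFrame:
    """Group mean/SD/count of distance-to-target per influence class and
    cell type (the layout of the distance-statistics table)."""
    rec = _retained(records)
    rows = []
    for ct in ("NonSOM", "SOM"):
        sub = rec.loc[rec["neuron_type"] == ct]
        classes = {
            "all": sub,
            "positively influenced": sub.loc[sub["sig_class"] == "positive"],
            "negatively influenced": sub.loc[sub["sig_class"] == "negative"],
            "un-influenced": sub.loc[sub["sig_class"] == "none"],
        }
        for name, grp in classes.items():
            d = grp["distance_um"].to_numpy()
            rows.append({
                "area": area_tag, "cell_type": ct, "group": name,
                "mean_distance_um": d.mean() if d.size else np.nan,
                "sd_um": d.std(ddof=1) if d.size > 1 else np.nan,
                "n": int(d.size)})
    return pd.DataFrame(rows)


def distance_binned_influence(records: pd.DataFrame, bin_width: float = 50.0,
                              max_dist: float = 400.0, min_dist: float = 25.0,
                              cell_type: str | None = "NonSOM") -> DistanceProfile:
    """Mean influence of *all* retained pairs (not only significant ones)
    per distance bin; bin edges [25, 75), [75, 125), ..."""
    rec = _retained(records)
    if cell_type is not None:
        rec = rec.loc[rec["neuron_type"] == cell_type]
    edges = np.arange(min_dist, max_dist + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    d = rec["distance_um"].to_numpy()
    v = rec["influence"].to_numpy()
    ok = np.isfinite(v)
    d, v = d[ok], v[ok]
    idx = np.digitize(d, edges) - 1
    inside = (idx >= 0) & (idx < len(centers))
    counts = np.bincount(idx[inside], minlength=len(centers))
    sums = np.bincount(idx[inside], weights=v[inside], minlength=len(centers))
    with np.errstate(invalid="ignore"):
        means = sums / counts
    return DistanceProfile(bin_centers=centers, mean_influence=means,
                           counts=counts,
                           cell_type=cell_type or "all", bin_width=bin_width)


def _dog(d, a_c, s_c, a_s, s_s):
    return a_c * np.exp(-d ** 2 / (2 * s_c ** 2)) - a_s * np.exp(-d ** 2 / (2 * s_s ** 2))


def fit_center_surround(profile: DistanceProfile,
                        weighted: bool = True) -> CenterSurroundFit:
    """Least-squares DoG fit to a distance-binned influence profile.

    Bins are weighted by pair counts by default (the far bins hold many
    more pairs).  Amplitudes are bounded nonnegative and the surround is
    constrained wider than the center via its lower bound.
    """
    ok = np.isfinite(profile.mean_influence) & (profile.counts > 0)
    d = profile.bin_centers[ok]
    y = profile.mean_influence[ok]
    if d.size < 6:
        raise ValueError("need >= 6 usable bins for a 4-parameter DoG fit")
    scale = max(np.abs(y).max(), 1e-12)
    p0 = [max(y[0], 0.1 * scale), 50.0, max(-y.min(), 0.1 * scale), 180.0]
    sigma = None
    if weighted:
        sigma = 1.0 / np.sqrt(np.maximum(profile.counts[ok], 1))
    try:
        popt, pcov = curve_fit(
            _dog, d, y, p0=p0, sigma=sigma,
            bounds=([0.0, 5.0, 0.0, 20.0], [np.inf, 400.0, np.inf, 1000.0]),
            maxfev=20000)
        resid = float(np.sqrt(np.mean((_dog(d, *popt) - y) ** 2)))
        err = np.sqrt(np.diag(pcov))
        return CenterSurroundFit(*popt, residual=resid, converged=True, stderr=err)
    except RuntimeError as exc:  # pragma: no cover - non-convergence path
        return CenterSurroundFit(np.nan, np.nan, np.nan, np.nan,
                                 residual=np.nan, converged=False,
                                 message=str(exc))
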