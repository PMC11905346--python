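"""Pairwise noise correlations with stimulation-trial exclusion.

For every stimulation event, the neuron's response is its mean activity in
the 10-frame (333 ms) window after the onset; the trial-averaged response
to that event's target is subtracted, leaving residuals that capture
trial-to-trial co-fluctuations.  The noise correlation of a (target,
neuron) pair is the Pearson correlation of their residuals across all
events in which that target was *not* stimulated, so the target's own
evoked response never contributes.  Pairs are split at 125 µm into near
and far distance classes when related to influence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .influence import event_window_means

__all__ = [
    "stim_aligned_residuals",
    "pairwise_noise_correlation",
    "session_noise_correlations",
    "correlation_influence_relation",
]


def stim_aligned_residuals(activity: np.ndarray, stim_table: pd.DataFrame,
                           post_len: int = 10
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Per-event residual responses (events x neurons) and event target ids.

    residual = post-window mean − trial-averaged post-window mean of that
    event's target.  Targets with a single usable event are dropped (their
    residual is identically zero and uninformative).
    """
    onsets = stim_table["onset_frame"].to_numpy()
    _pre, post, valid = event_window_means(activity, onsets, post_len, post_len)
    targets = stim_table["target_id"].to_numpy()[valid]
    keep = np.ones(targets.size, dtype=bool)
    resid = np.empty_like(post)
    for t in np.unique(targets):
        rows = targets == t
        if rows.sum() < 2:
            keep[rows] = False
            continue
        resid[rows] = post[rows] - post[rows].mean(axis=0)
    return resid[keep], targets[keep]


def pairwise_noise_correlation(resid: np.ndarray, event_targets: np.ndarray,
                               target_id: int, neuron_id: int) -> tuple[float, int]:
    """Pearson r between two neurons' residuals over events in which
    ``target_id`` was not stimulated.  Returns (r, n_trials_used); r is
    NaN when either series has zero variance."""
    mask = event_targets != target_id
    n = int(mask.sum())
    if n < 3:
        raise ValueError("need >= 3 usable trials after exclusion")
    x = resid[mask, target_id]
    y = resid[mask, neuron_id]
    if x.std() == 0.0 or y.std() == 0.0:
        return np.nan, n
    return float(np.corrcoef(x, y)[0, 1]), n


def session_noise_correlations(session, activity: np.ndarray | None = None, *,
                               post_len: int = 10,
                               near_split_um: float = 125.0) -> pd.DataFrame:
    """Noise-correlation records for every (target, neuron) pair of a
    session's successful non-control targets.

    Columns: target_id, neuron_id, neuron_type, r, n_trials_used,
    distance_um, distance_class ('near' < 125 µm, 'far' otherwise).
    """
    if activity is None:
        activity = session.processed["bundle"].dff
    resid, ev_targets = stim_aligned_residuals(activity, session.stim_table, post_len)
    success = session.processed.get("target_success", {})
    rows = []
    nids = np.arange(session.n_neurons)
    for tid in session.target_ids:
        if session.control_target[tid] or not success.get(int(tid), True):
            continue
        mask = ev_targets != tid
        if mask.sum() < 3:
            continue
        sub = resid[mask]
        x = sub[:, tid]
        sx = x.std()
        xc = x - x.mean()
        yc = sub - sub.mean(axis=0)
        sy = sub.std(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (xc @ yc) / (mask.sum() * sx * sy)
        dist = np.linalg.norm(session.positions - session.positions[tid], axis=1)
        keep = nids != tid
        rows.append(pd.DataFrame({
            "target_id": int(tid), "neuron_id": nids[keep],
            "neuron_type": session.cell_type[keep], "r": r[keep],
            "n_trials_used": int(mask.sum()), "distance_um": dist[keep]}))
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["target_id", "neuron_id", "neuron_type", "r",
                 "n_trials_used", "distance_um"])
    if len(out):
        out["distance_class"] = np.where(out["distance_um"] < near_split_um,
                                         "near", "far")
    else:
        out["distance_class"] = pd.Series(dtype=object)
    session.processed["noise_corr_records"] = out
    return out


def correlation_influence_relation(noise_records: pd.DataFrame,
                                   influence_records: pd.DataFrame,
                                   split_um: float = 125.0) -> pd.DataFrame:
    """Pearson r (and p, n) between noise correlation and influence per
    (cell_type, distance_class) — the layout of the correlation table."""
    inf = influence_records.loc[~influence_records["excluded"].astype(bool),
                                ["target_id", "neuron_id", "influence"]]
    merged = noise_records.merge(inf, on=["target_id", "neuron_id"])
    merged = merged.dropna(subset=["r", "influence"])
    merged["distance_class"] = np.where(merged["distance_um"] < split_um,
                                        "near", "far")
    rows = []
    for ct in ("NonSOM", "SOM"):
        for dc in ("near", "far"):
            sub = merged.loc[(merged["neuron_type"] == ct)
                             & (merged["distance_class"] == dc)]
            if len(sub) < 3 or sub["r"].nunique() < 2 \
                    or sub["influence"].nunique() < 2:
                rows.append({"cell_type": ct, "distance_class": dc,
                             "r": np.nan, "p": np.nan, "n_pairs": int(len(sub))})
                continue
            r, p = sps.pearsonr(sub["r"], sub["influence"])
            rows.append({"cell_type": ct, "distance_class": dc,
                         "r": float(r), "p": float(p), "n_pairs": int(len(sub))})
    return pd.DataFrame(rows)
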