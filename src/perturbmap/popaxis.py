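"""Population "stimulus axis" analysis.

For each target, the stimulus axis is the unit vector in population
activity space (one axis per included neuron) pointing from the
population's mean prestimulus activity to its mean stimulation response.
Projections of activity onto this axis summarize the population-level
impact of the stimulation; the signed axis weights, binned by distance to
the target, expose the center/surround structure at the population level.

Included neurons are all SOM and Non-SOM cells at least 25 µm from the
target (and not the target itself); weights are the trial-averaged
post − pre window means normalized to unit Euclidean length.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .influence import event_window_means

__all__ = [
    "StimulusAxisRecord",
    "stimulus_axis",
    "project",
    "weights_by_distance",
    "session_stimulus_axes",
    "UndefinedAxisError",
]


class UndefinedAxisError(ValueError):
    """Pre and post population activity coincide; the axis is undefined."""


@dataclass
class StimulusAxisRecord:
    """Unit-norm weight vector over included neurons for one target."""

    target_id: int
    included_ids: np.ndarray
    weights: np.ndarray
    pre_mean: np.ndarray
    response_norm: float
    projection: np.ndarray | None = None  # per-trial projection

    def __post_init__(self) -> None:
        if self.weights.shape != self.included_ids.shape:
            raise ValueError("weights and included_ids must align")


def stimulus_axis(pre_mean: np.ndarray, post_mean: np.ndarray) -> np.ndarray:
    """Unit vector (post_mean − pre_mean) / ‖post_mean − pre_mean‖."""
    pre_mean = np.asarray(pre_mean, dtype=np.float64)
    post_mean = np.asarray(post_mean, dtype=np.float64)
    diff = post_mean - pre_mean
    norm = np.linalg.norm(diff)
    if norm == 0.0:
        raise UndefinedAxisError("post_mean equals pre_mean")
    return diff / norm


def project(activity: np.ndarray, weights: np.ndarray,
            pre_mean: np.ndarray) -> float | np.ndarray:
    """Project population activity onto the axis after subtracting the
    prestimulus mean: (activity − pre_mean) · weights."""
    activity = np.asarray(activity, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if activity.shape[-1] != weights.shape[0]:
        raise ValueError("activity/weights dimension mismatch")
    return (activity - pre_mean) @ weights


def weights_by_distance(weights: np.ndarray, distances: np.ndarray,
                        bin_width: float = 50.0, max_dist: float = 400.0,
                        min_dist: float = 25.0) -> pd.DataFrame:
    """Mean |weight| per distance bin, separately for positively and
    negatively weighted neurons, with counts (n = 0 for empty subsets)."""
    weights = np.asarray(weights, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if weights.shape != distances.shape:
        raise ValueError("weights and distances must align")
    edges = np.arange(min_dist, max_dist + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    rows = []
    for sign, mask in (("positive", weights > 0), ("negative", weights < 0)):
        idx = np.digitize(distances[mask], edges) - 1
        mag = np.abs(weights[mask])
        for b, c in enumerate(centers):
            sel = idx == b
            rows.append({
                "sign": sign, "bin_center_um": c,
                "mean_abs_weight": mag[sel].mean() if sel.any() else np.nan,
                "n": int(sel.sum())})
    return pd.DataFrame(rows)


def session_stimulus_axes(session, activity: np.ndarray | None = None, *,
                          pre_len: int = 10, post_len: int = 10,
                          exclusion_radius: float = 25.0,
                          only_successful: bool = True
                          ) -> tuple[list[StimulusAxisRecord], pd.DataFrame]:
    """Stimulus axis for every (successful, non-control) target of a session.

    Returns the per-target axis records (with per-trial projections of the
    defining trials) and a tidy weights table (target_id, neuron_id,
    weight, distance_um).
    """
    if activity is None:
        activity = session.processed["bundle"].dff
    stim = session.stim_table
    pre, post, valid = event_window_means(
        activity, stim["onset_frame"].to_numpy(), pre_len, post_len)
    targets = stim["target_id"].to_numpy()[valid]
    success = session.processed.get("target_success", {})
    axes: list[StimulusAxisRecord] = []
    rows = []
    for tid in session.target_ids:
        if session.control_target[tid]:
            continue
        if only_successful and not success.get(int(tid), True):
            continue
        own = targets == tid
        if own.sum() < 2:
            continue
        dist = np.linalg.norm(session.positions - session.positions[tid], axis=1)
        included = np.flatnonzero((dist >= exclusion_radius) &
                                  (np.arange(session.n_neurons) != tid))
        pre_mean = pre[own][:, included].mean(axis=0)
        post_mean = post[own][:, included].mean(axis=0)
        try:
            w = stimulus_axis(pre_mean, post_mean)
        except UndefinedAxisError:
            continue
        proj = project(post[own][:, included], w, pre_mean)
        axes.append(StimulusAxisRecord(
            target_id=int(tid), included_ids=included, weights=w,
            pre_mean=pre_mean,
            response_norm=float(np.linalg.norm(post_mean - pre_mean)),
            projection=np.asarray(proj)))
        rows.append(pd.DataFrame({
            "target_id": int(tid), "neuron_id": included, "weight": w,
            "neuron_type": session.cell_type[included],
            "distance_um": dist[included]}))
    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["target_id", "neuron_id", "weight", "neuron_type", "distance_um"])
    return axes, table
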