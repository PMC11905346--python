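"""Trial-normalized influence of each stimulated target on each neuron.

The influence of a target on a neuron is the mean over trials of
(post-window − pre-window activity) divided by the sample SD of that
difference across trials — a unitless, z-like statistic.  Windows are
10 imaging frames (333 ms at 30 Hz) before the onset and after it (the
onset frame itself, which contains the 100 ms stimulation artifact, is
excluded).  Significance is assessed per pair against a trial-shuffle
null: the target's onsets are replaced by equal-size draws from the other
targets' onsets, and a pair is called positively (negatively) influenced
when the observed influence exceeds the 99th (falls below the 1st)
percentile of the shuffled values.  Neurons within 25 µm of the target
are excluded (possible direct activation), and only targets whose own
response is classified positive ("successfully stimulated") contribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "TrialWindows",
    "align_trials",
    "event_window_means",
    "compute_influence",
    "influence_statistic",
    "shuffle_null",
    "classify_influence",
    "proximity_exclusion",
    "map_influence",
    "InsufficientTrialsError",
    "EmptyTrialsError",
    "ShufflePoolError",
]


class EmptyTrialsError(ValueError):
    """No usable trials after window validation."""


class InsufficientTrialsError(ValueError):
    """Fewer than two trials; the influence SD is undefined."""


class ShufflePoolError(ValueError):
    """Shuffle pool smaller than the trial count."""


@dataclass
class TrialWindows:
    """Per-trial pre/post window means for one (target, neuron) pair."""

    pre: np.ndarray
    post: np.ndarray
    target_id: int = -1
    neuron_id: int = -1

    def __post_init__(self) -> None:
        if self.pre.shape != self.post.shape:
            raise ValueError("pre and post must have equal trial counts")


def align_trials(activity: np.ndarray, onsets: np.ndarray,
                 pre_len: int = 10, post_len: int = 10,
                 target_id: int = -1, neuron_id: int = -1) -> TrialWindows:
    """Mean activity in the ``pre_len`` frames before and ``post_len``
    frames after each onset (the onset frame is in neither window).

    Onsets without a full window on both sides are dropped with a log entry.
    """
    activity = np.asarray(activity, dtype=np.float64)
    onsets = np.asarray(onsets, dtype=int)
    t = activity.shape[-1]
    valid = (onsets >= pre_len) & (onsets + post_len < t)
    if np.any(~valid):
        logger.info("align_trials: dropped %d/%d trials without full windows",
                    int((~valid).sum()), onsets.size)
    onsets = onsets[valid]
    if onsets.size == 0:
        raise EmptyTrialsError("no usable trials")
    pre = np.empty(onsets.size)
    post = np.empty(onsets.size)
    for i, o in enumerate(onsets):
        pre[i] = activity[o - pre_len:o].mean()
        post[i] = activity[o + 1:o + post_len + 1].mean()
    return TrialWindows(pre=pre, post=post, target_id=target_id, neuron_id=neuron_id)


def event_window_means(activity: np.ndarray, onsets: np.ndarray,
                       pre_len: int = 10, post_len: int = 10
                       ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized pre/post window means for all events and all neurons.

    ``activity`` is (neurons, frames); returns (pre, post, valid) where pre
    and post are (n_valid_events, neurons) and ``valid`` marks the onsets
    with full windows.  Accumulation is float64 via cumulative sums.
    """
    activity = np.asarray(activity)
    onsets = np.asarray(onsets, dtype=int)
    t = activity.shape[1]
    valid = (onsets >= pre_len) & (onsets + post_len < t)
    o = onsets[valid]
    cs = np.concatenate(
        [np.zeros((activity.shape[0], 1)),
         np.cumsum(activity, axis=1, dtype=np.float64)], axis=1)
    pre = (cs[:, o] - cs[:, o - pre_len]).T / pre_len
    post = (cs[:, o + post_len + 1] - cs[:, o + 1]).T / post_len
    return pre, post, valid


def influence_statistic(d: np.ndarray) -> tuple[float, bool]:
    """mean(d)/sd(d) with sample SD (n−1).  Returns (value, degenerate):
    sd = 0 with zero mean gives 0; sd = 0 with nonzero mean is degenerate."""
    d = np.asarray(d, dtype=np.float64)
    if d.size < 2:
        raise InsufficientTrialsError("need >= 2 trials")
    m = d.mean()
    s = d.std(ddof=1)
    if s == 0.0:
        return (0.0, False) if m == 0.0 else (np.nan, True)
    return float(m / s), False


def compute_influence(tw: TrialWindows) -> float:
    """Influence value for one pair; raises on degenerate (sd=0, mean≠0)."""
    value, degenerate = influence_statistic(tw.post - tw.pre)
    if degenerate:
        raise ValueError("degenerate pair: zero SD with nonzero mean")
    return value


def _influence_matrix(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Influence per neuron from per-trial differences d (trials, neurons).
    Returns (values, degenerate mask)."""
    m = d.mean(axis=0)
    s = d.std(axis=0, ddof=1)
    degenerate = (s == 0.0) & (m != 0.0)
    zero = (s == 0.0) & (m == 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = m / s
    vals[zero] = 0.0
    vals[degenerate] = np.nan
    return vals, degenerate


def _null_percentiles(d_pool: np.ndarray, n_trials: int, n_shuffles: int,
                      rng: np.random.Generator,
                      percentiles: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    """Shuffle-null thresholds of the influence statistic: each shuffle
    draws ``n_trials`` rows from ``d_pool`` without replacement.

    Thresholds are order statistics implementing the rank rule "greater
    (less) than q% of the shuffled values": with M shuffles and
    k = ceil(q/100 * M), hi is the k-th smallest null value and lo the
    (M−k+1)-th, so 'observed > hi' means the observed statistic strictly
    exceeds at least q% of the shuffled values.
    """
    n_neurons = d_pool.shape[1] if d_pool.ndim == 2 else 1
    d_pool = d_pool.reshape(d_pool.shape[0], n_neurons)
    idx = _draw_indices(rng, n_shuffles, np.ones(d_pool.shape[0], bool),
                        None, None, n_trials)
    return _null_from_indices(d_pool, idx, percentiles)


def _draw_indices(rng: np.random.Generator, n_shuffles: int,
                  pool_mask: np.ndarray, strata: np.ndarray | None,
                  own_strata: np.ndarray | None, n_trials: int) -> np.ndarray:
    """Pseudo-onset index draws, (n_shuffles, n_trials).

    When repeat-block strata are available, each shuffle draws one event
    per stratum the target participates in — the same sampling design that
    produced the observed onset set, which makes the observed statistic
    exchangeable with the shuffled ones.  Without usable strata, draws are
    plain subsets without replacement.
    """
    pool_idx = np.flatnonzero(pool_mask)
    if strata is not None and own_strata is not None:
        cands = []
        deficient = 0
        for b in own_strata:
            cand = pool_idx[strata[pool_idx] == b]
            if cand.size < 2:  # stratum holds at most the target's own event
                deficient += 1
                cand = pool_idx
            cands.append(cand)
        if deficient <= len(own_strata) // 2:
            cols = [cand[rng.integers(0, cand.size, size=n_shuffles)]
                    for cand in cands]
            return np.stack(cols, axis=1)
    return pool_idx[np.argpartition(
        rng.random((n_shuffles, pool_idx.size)),
        n_trials - 1, axis=1)[:, :n_trials]]


def _null_from_indices(d_all: np.ndarray, idx: np.ndarray,
                       percentiles: tuple[float, float]
                       ) -> tuple[np.ndarray, np.ndarray]:
    n_shuffles, n_trials = idx.shape
    n_neurons = d_all.shape[1]
    null_vals = np.empty((n_shuffles, n_neurons))
    chunk = max(1, int(4e7 // max(1, n_trials * n_neurons)))
    for s0 in range(0, n_shuffles, chunk):
        sel = d_all[idx[s0:s0 + chunk]]         # (c, n_trials, neurons)
        m = sel.mean(axis=1)
        s = sel.std(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            null_vals[s0:s0 + sel.shape[0]] = m / s
        null_vals[s0:s0 + sel.shape[0]][s == 0.0] = 0.0
    null_vals.sort(axis=0)
    k = int(np.ceil(percentiles[1] / 100.0 * n_shuffles))
    return null_vals[n_shuffles - k], null_vals[k - 1]


def shuffle_null(activity: np.ndarray, stim_table: pd.DataFrame, target_id: int,
                 n_shuffles: int = 1000, seed: int | np.random.Generator = 0,
                 pre_len: int = 10, post_len: int = 10,
                 percentiles: tuple[float, float] = (1.0, 99.0),
                 neuron_target_ids: np.ndarray | None = None,
                 _windows: tuple[np.ndarray, np.ndarray] | None = None
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Trial-shuffle null thresholds for one target, per neuron.

    Each shuffle replaces the target's onset set with an equal-size random
    draw (without replacement) from the pooled onsets of *all* targets and
    recomputes the influence statistic; under no effect, the observed
    statistic is then one member of an approximately exchangeable family,
    which calibrates the q%-rank rule.  Returns (lo, hi) order-statistic
    thresholds per neuron.

    When the measured neuron is itself a stimulation target
    (``neuron_target_ids``), its *own* onsets are removed from that
    neuron's shuffle pool — otherwise the neuron's direct responses leak
    into its null and bias the thresholds upward.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    targets = stim_table["target_id"].to_numpy()
    strata = stim_table["trial_index"].to_numpy() \
        if "trial_index" in stim_table else None
    if _windows is None:
        pre, post, valid = event_window_means(
            activity, stim_table["onset_frame"].to_numpy(), pre_len, post_len)
        targets = targets[valid]
        if strata is not None:
            strata = strata[valid]
        d_all = post - pre
    else:
        d_all = _windows[1] - _windows[0]
    own = targets == target_id
    n_trials = int(own.sum())
    if targets.size - n_trials < n_trials:
        raise ShufflePoolError(
            f"other targets' onsets ({targets.size - n_trials}) fewer than "
            f"the trial count ({n_trials})")
    own_strata = strata[own] if strata is not None else None
    idx = _draw_indices(rng, n_shuffles, np.ones(targets.size, bool),
                        strata, own_strata, n_trials)
    lo, hi = _null_from_indices(d_all, idx, percentiles)
    if neuron_target_ids is not None:
        for j in np.asarray(neuron_target_ids, dtype=int):
            if j == target_id or j >= d_all.shape[1]:
                continue
            pool_mask = targets != j
            if pool_mask.sum() < n_trials:
                continue
            idx_j = _draw_indices(rng, n_shuffles, pool_mask, strata,
                                  own_strata, n_trials)
            lo_j, hi_j = _null_from_indices(d_all[:, j][:, None], idx_j,
                                            percentiles)
            lo[j], hi[j] = lo_j[0], hi_j[0]
    return lo, hi


def classify_influence(observed, lo, hi):
    """'positive' if observed > hi, 'negative' if observed < lo, else 'none'.
    Ties (observed exactly at a threshold) are 'none'."""
    observed = np.asarray(observed, dtype=float)
    out = np.full(observed.shape, "none", dtype=object)
    out[observed > hi] = "positive"
    out[observed < lo] = "negative"
    out[~np.isfinite(observed)] = "none"
    return out if observed.ndim else str(out[()])


def proximity_exclusion(records: pd.DataFrame, positions: np.ndarray,
                        radius: float = 25.0) -> pd.DataFrame:
    """Flag pairs with intersomatic distance < ``radius`` µm as excluded.

    Adds/overwrites ``distance_um`` and ``excluded``; excluded records lose
    their significance class.
    """
    tid = records["target_id"].to_numpy()
    nid = records["neuron_id"].to_numpy()
    if np.any(tid >= len(positions)) or np.any(nid >= len(positions)):
        raise ValueError("record references a neuron with no known position")
    dist = np.linalg.norm(positions[tid] - positions[nid], axis=1)
    rec = records.copy()
    rec["distance_um"] = dist
    rec["excluded"] = rec.get("excluded", False) | (dist < radius)
    if "sig_class" in rec:
        rec.loc[rec["excluded"], "sig_class"] = None
    return rec


def map_influence(session, activity: np.ndarray | None = None, *,
                  n_shuffles: int = 1000, seed: int = 0,
                  pre_len: int = 10, post_len: int = 10,
                  exclusion_radius: float = 25.0) -> pd.DataFrame:
    """Full influence mapping for one session.

    Returns a tidy table with one row per (target, neuron) pair for every
    *successfully stimulated*, non-control target: columns target_id,
    neuron_id, neuron_type, distance_um, influence, sig_class, excluded.
    Per-target success flags (including control targets) are stored in
    ``session.processed['target_success']``.

    ``activity`` defaults to the preprocessed ΔF/F matrix.
    """
    if activity is None:
        activity = session.processed["bundle"].dff
    rng = np.random.default_rng(seed)
    stim = session.stim_table
    onsets = stim["onset_frame"].to_numpy()
    pre, post, valid = event_window_means(activity, onsets, pre_len, post_len)
    targets = stim["target_id"].to_numpy()[valid]
    d_all = post - pre
    tab = stim.loc[valid].reset_index(drop=True).assign(
        target_id=targets, onset_frame=stim["onset_frame"].to_numpy()[valid])

    n_neurons = activity.shape[0]
    rows = []
    success: dict[int, bool] = {}
    for tid in session.target_ids:
        own = targets == tid
        if own.sum() < 2:
            logger.warning("target %d: <2 usable trials, skipped", tid)
            success[int(tid)] = False
            continue
        obs, degenerate = _influence_matrix(d_all[own])
        lo, hi = shuffle_null(activity, tab, tid, n_shuffles=n_shuffles,
                              seed=rng, pre_len=pre_len, post_len=post_len,
                              neuron_target_ids=session.target_ids,
                              _windows=(pre, post))
        cls = classify_influence(obs, lo, hi)
        ok = bool(cls[tid] == "positive")
        success[int(tid)] = ok
        if not ok or session.control_target[tid]:
            continue
        neuron_ids = np.arange(n_neurons)
        keep = neuron_ids != tid
        rows.append(pd.DataFrame({
            "target_id": tid,
            "neuron_id": neuron_ids[keep],
            "neuron_type": session.cell_type[keep],
            "influence": obs[keep],
            "sig_class": cls[keep],
            "excluded": degenerate[keep],
        }))
    if rows:
        records = pd.concat(rows, ignore_index=True)
    else:
        records = pd.DataFrame(columns=["target_id", "neuron_id", "neuron_type",
                                        "influence", "sig_class", "excluded"])
    records = proximity_exclusion(records, session.positions, exclusion_radius) \
        if len(records) else records.assign(distance_um=pd.Series(dtype=float))
    session.processed["target_success"] = success
    session.processed["influence_records"] = records
    return records
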