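"""Behavioral-state (locomotion) analyses.

Prestimulus running speed is the mean treadmill speed in the 20 imaging
frames (660 ms at 30 Hz) before each stimulation onset; the within-session
distribution of these speeds is split into quartiles (Q1 typically
corresponds to the animal being stationary).  Influence and activity are
then re-measured per quartile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .influence import event_window_means, _influence_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "QuartileAssignment",
    "prestim_speed",
    "assign_quartiles",
    "influence_by_quartile",
    "activity_by_quartile",
]


@dataclass
class QuartileAssignment:
    """Per-trial running-speed quartile labels (1..4) for one session."""

    boundaries: np.ndarray        # 25/50/75 percentile cut points, cm/s
    trial_quartile: np.ndarray    # label per usable trial
    valid: np.ndarray             # mask over the input trials
    degenerate: bool = False      # all speeds equal -> everything in Q1
    session_id: str = ""


def prestim_speed(run_speed: np.ndarray, onsets: np.ndarray,
                  window: int = 20) -> tuple[np.ndarray, np.ndarray]:
    """Mean running speed over frames [onset−window, onset−1] per trial.

    Returns (speeds, valid mask); onsets closer than ``window`` frames to
    the trace start are dropped with a log entry.
    """
    run_speed = np.asarray(run_speed, dtype=np.float64)
    onsets = np.asarray(onsets, dtype=int)
    valid = (onsets >= window) & (onsets <= run_speed.size)
    if np.any(~valid):
        logger.info("prestim_speed: dropped %d/%d trials",
                    int((~valid).sum()), onsets.size)
    if not np.any(valid):
        raise ValueError("no usable trials for prestimulus speed")
    cs = np.concatenate([[0.0], np.cumsum(run_speed)])
    o = onsets[valid]
    speeds = (cs[o] - cs[o - window]) / window
    return speeds, valid


def assign_quartiles(speeds: np.ndarray, session_id: str = "") -> QuartileAssignment:
    """Quartile labels from the within-session speed distribution.

    Cut points are the 25/50/75th percentiles; a trial whose speed ties a
    boundary goes to the lower quartile.  All-equal speeds are degenerate:
    every trial lands in Q1 and the assignment is flagged.
    """
    speeds = np.asarray(speeds, dtype=np.float64)
    if speeds.size < 4:
        raise ValueError("need >= 4 trials to form quartiles")
    bounds = np.percentile(speeds, [25.0, 50.0, 75.0])
    labels = 1 + np.searchsorted(bounds, speeds, side="left")
    degenerate = bool(np.all(speeds == speeds[0]))
    return QuartileAssignment(boundaries=bounds,
                              trial_quartile=labels.astype(int),
                              valid=np.ones(speeds.size, dtype=bool),
                              degenerate=degenerate, session_id=session_id)


def _quartiles_for_session(session, window: int = 20) -> tuple[QuartileAssignment, np.ndarray]:
    onsets = session.stim_table["onset_frame"].to_numpy()
    speeds, valid = prestim_speed(session.run_speed, onsets, window)
    qa = assign_quartiles(speeds, session_id=session.area_tag)
    return qa, valid


def influence_by_quartile(session, activity: np.ndarray | None = None, *,
                          records: pd.DataFrame | None = None,
                          restrict_to: str = "positive",
                          pre_len: int = 10, post_len: int = 10,
                          speed_window: int = 20) -> pd.DataFrame:
    """Per-quartile influence of each pair, restricted to pairs that were
    significantly influenced (``restrict_to`` class) over all trials.

    Influence is recomputed with the same mean/SD statistic on each
    quartile's trial subset; pairs whose target has <2 trials in a
    quartile are skipped for that quartile.  Returns a tidy table
    (target_id, neuron_id, neuron_type, quartile, influence) plus the
    per-(quartile, cell_type) summary in ``.attrs['summary']``.
    """
    if activity is None:
        activity = session.processed["bundle"].dff
    if records is None:
        records = session.processed["influence_records"]
    qa, valid_speed = _quartiles_for_session(session, speed_window)
    stim = session.stim_table
    pre, post, valid_win = event_window_means(
        activity, stim["onset_frame"].to_numpy(), pre_len, post_len)
    # align: quartile labels on speed-valid trials, windows on window-valid
    usable = valid_speed & valid_win
    q = np.full(len(stim), 0)
    q[valid_speed] = qa.trial_quartile
    d_all = post - pre
    row_of = np.cumsum(valid_win) - 1        # stim row -> d_all row
    targets = stim["target_id"].to_numpy()

    sel = records.loc[(records["sig_class"] == restrict_to)
                      & ~records["excluded"].astype(bool)]
    rows = []
    for tid, grp in sel.groupby("target_id"):
        own = usable & (targets == tid)
        nids = grp["neuron_id"].to_numpy()
        ntypes = grp["neuron_type"].to_numpy()
        for quart in (1, 2, 3, 4):
            mask = own & (q == quart)
            if mask.sum() < 2:
                logger.info("target %s quartile %d: <2 trials, skipped",
                            tid, quart)
                continue
            d = d_all[row_of[mask]][:, nids]
            vals, _ = _influence_matrix(d)
            rows.append(pd.DataFrame({
                "target_id": tid, "neuron_id": nids, "neuron_type": ntypes,
                "quartile": quart, "influence": vals}))
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["target_id", "neuron_id", "neuron_type", "quartile", "influence"])
    summary = (out.dropna(subset=["influence"])
               .groupby(["quartile", "neuron_type"])["influence"]
               .agg(["mean", "count"]).reset_index()) if len(out) else pd.DataFrame()
    out.attrs["summary"] = summary
    out.attrs["boundaries"] = qa.boundaries
    return out


def activity_by_quartile(session, activity: np.ndarray | None = None, *,
                         pre_len: int = 10, speed_window: int = 20) -> pd.DataFrame:
    """Mean prestimulus-window activity per neuron per running quartile.

    Returns a tidy table (neuron_id, neuron_type, quartile, mean_activity).
    """
    if activity is None:
        activity = session.processed["bundle"].dff
    qa, valid_speed = _quartiles_for_session(session, speed_window)
    stim = session.stim_table
    pre, _post, valid_win = event_window_means(
        activity, stim["onset_frame"].to_numpy(), pre_len, pre_len)
    usable = valid_speed & valid_win
    q = np.full(len(stim), 0)
    q[valid_speed] = qa.trial_quartile
    row_of = np.cumsum(valid_win) - 1
    rows = []
    nids = np.arange(session.n_neurons)
    for quart in (1, 2, 3, 4):
        mask = usable & (q == quart)
        if not mask.any():
            continue
        m = pre[row_of[mask]].mean(axis=0)
        rows.append(pd.DataFrame({
            "neuron_id": nids, "neuron_type": session.cell_type,
            "quartile": quart, "mean_activity": m}))
    return pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(
        columns=["neuron_id", "neuron_type", "quartile", "mean_activity"])
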