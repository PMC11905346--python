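"""Sound-frequency tuning and the like-to-like (tuning-similarity) test.

Tone-evoked responses are measured on z-scored activity aligned on tone
onset (1 s tone window minus a prestimulus baseline), trial-averaged per
frequency over the six tested tones (4, 8, 12, 16, 24, 32 kHz).  Sound-
responsive neurons get a best frequency (BF) from a Gaussian fit in log2
frequency, and the dependence of influence on |ΔBF| (octaves) is tested
against a within-field-of-view shuffle of frequency preferences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "TuningRecord",
    "tone_aligned_response",
    "tone_responsiveness",
    "fit_best_frequency",
    "delta_bf",
    "tuning_shuffle_test",
    "session_tuning",
]

TONE_FREQS_KHZ = np.array([4.0, 8.0, 12.0, 16.0, 24.0, 32.0])


@dataclass
class TuningRecord:
    """Per-neuron sound responsiveness and Gaussian tuning fit."""

    neuron_id: int
    responsive: bool
    best_frequency: float | None      # kHz; None if unresponsive/non-selective
    fit_amplitude: float = np.nan
    fit_center: float = np.nan        # log2 kHz
    fit_width: float = np.nan         # octaves
    fit_r2: float = np.nan

    @property
    def bf_log2(self) -> float:
        return np.log2(self.best_frequency) if self.best_frequency else np.nan


def _tone_windows(activity_z, tone_table, frame_rate, baseline_len=10):
    onsets = tone_table["onset_frame"].to_numpy()
    dur = int(round(frame_rate))
    t = activity_z.shape[1]
    valid = (onsets >= baseline_len) & (onsets + dur <= t)
    o = onsets[valid]
    cs = np.concatenate([np.zeros((activity_z.shape[0], 1)),
                         np.cumsum(activity_z, axis=1, dtype=np.float64)], axis=1)
    tone = (cs[:, o + dur] - cs[:, o]).T / dur              # (trials, neurons)
    base = (cs[:, o] - cs[:, o - baseline_len]).T / baseline_len
    return tone - base, valid


def tone_aligned_response(activity: np.ndarray, tone_table: pd.DataFrame,
                          frame_rate: float, baseline_len: int = 10
                          ) -> pd.DataFrame:
    """Trial-averaged z-scored tone response per neuron per frequency.

    Response = mean z-scored activity over the 1 s tone window minus the
    prestimulus baseline; returned as a (neurons x frequencies) frame with
    NaN columns for missing frequencies.
    """
    activity = np.asarray(activity, dtype=np.float64)
    sd = activity.std(axis=1, keepdims=True)
    sd[sd == 0.0] = 1.0
    z = (activity - activity.mean(axis=1, keepdims=True)) / sd
    diffs, valid = _tone_windows(z, tone_table, frame_rate, baseline_len)
    freqs = tone_table["frequency_khz"].to_numpy()[valid]
    out = np.full((activity.shape[0], len(TONE_FREQS_KHZ)), np.nan)
    for j, f in enumerate(TONE_FREQS_KHZ):
        rows = freqs == f
        if rows.sum() >= 2:
            out[:, j] = diffs[rows].mean(axis=0)
    return pd.DataFrame(out, columns=[f"{f:g}" for f in TONE_FREQS_KHZ])


def tone_responsiveness(activity: np.ndarray, tone_table: pd.DataFrame,
                        frame_rate: float, baseline_len: int = 10,
                        n_iterations: int = 1000, alpha: float = 0.05,
                        seed: int = 0) -> np.ndarray:
    """Permutation test (random sign flips across trials) of tone-window
    vs baseline activity per neuron; True where p < alpha."""
    activity = np.asarray(activity, dtype=np.float64)
    sd = activity.std(axis=1, keepdims=True)
    sd[sd == 0.0] = 1.0
    z = (activity - activity.mean(axis=1, keepdims=True)) / sd
    diffs, _ = _tone_windows(z, tone_table, frame_rate, baseline_len)
    rng = np.random.default_rng(seed)
    obs = np.abs(diffs.mean(axis=0))
    n_trials = diffs.shape[0]
    count = np.ones(diffs.shape[1])
    chunk = 200
    for s0 in range(0, n_iterations, chunk):
        c = min(chunk, n_iterations - s0)
        signs = rng.choice([-1.0, 1.0], size=(c, n_trials))
        null = np.abs(np.tensordot(signs, diffs, axes=(1, 0))) / n_trials
        count += (null >= obs[None, :]).sum(axis=0)
    p = count / (n_iterations + 1)
    return p < alpha


def _gauss(x, a, c, w, b):
    return a * np.exp(-(x - c) ** 2 / (2 * w ** 2)) + b


def fit_best_frequency(responses: np.ndarray, responsive: bool = True,
                       neuron_id: int = -1) -> TuningRecord:
    """Gaussian fit in log2 frequency over the six tested tones.

    The center is bounded to the tested range [2, 5] log2 kHz and the
    width to [0.1, 4] octaves; flat response profiles are non-selective.
    """
    responses = np.asarray(responses, dtype=float)
    if not responsive:
        return TuningRecord(neuron_id, False, None)
    ok = np.isfinite(responses)
    x = np.log2(TONE_FREQS_KHZ[ok])
    y = responses[ok]
    if y.size < 5 or np.ptp(y) < 1e-12:
        return TuningRecord(neuron_id, responsive, None)
    x0 = float(x[np.argmax(y)])
    p0 = [max(np.ptp(y), 1e-3), x0, 1.0, float(y.min())]
    try:
        popt, _ = curve_fit(
            _gauss, x, y, p0=p0,
            bounds=([0.0, 2.0, 0.1, -np.inf], [np.inf, 5.0, 4.0, np.inf]),
            maxfev=5000)
    except RuntimeError:
        return TuningRecord(neuron_id, responsive, None)
    pred = _gauss(x, *popt)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    center = float(np.clip(popt[1], 2.0, 5.0))
    return TuningRecord(neuron_id, responsive, float(2.0 ** center),
                        fit_amplitude=float(popt[0]), fit_center=center,
                        fit_width=float(popt[2]), fit_r2=r2)


def delta_bf(bf_a_khz: float, bf_b_khz: float) -> float:
    """|log2(BF_a) − log2(BF_b)| in octaves."""
    if bf_a_khz is None or bf_b_khz is None:
        raise ValueError("both neurons need a best frequency")
    return abs(float(np.log2(bf_a_khz) - np.log2(bf_b_khz)))


def session_tuning(session, activity: np.ndarray | None = None, *,
                   baseline_len: int = 10, alpha: float = 0.05,
                   seed: int = 0) -> pd.DataFrame:
    """Tuning table for one session: neuron_id, responsive, bf_khz,
    bf_log2, fit_r2.  Uses deconvolved events when available, else ΔF/F."""
    if activity is None:
        bundle = session.processed["bundle"]
        activity = bundle.events if bundle.events is not None else bundle.dff
    if len(session.tone_table) == 0:
        raise ValueError("session has no tone trials")
    resp = tone_aligned_response(activity, session.tone_table,
                                 session.frame_rate, baseline_len)
    responsive = tone_responsiveness(activity, session.tone_table,
                                     session.frame_rate, baseline_len,
                                     seed=seed)
    rows = []
    for i in range(activity.shape[0]):
        rec = fit_best_frequency(resp.iloc[i].to_numpy(), bool(responsive[i]), i)
        rows.append({"neuron_id": i, "responsive": rec.responsive,
                     "bf_khz": rec.best_frequency,
                     "bf_log2": rec.bf_log2 if rec.best_frequency else np.nan,
                     "fit_r2": rec.fit_r2})
    out = pd.DataFrame(rows)
    session.processed["tuning_records"] = out
    return out


def tuning_shuffle_test(influence_records: pd.DataFrame,
                        tuning_records: pd.DataFrame,
                        n_shuffles: int = 500, seed: int = 0
                        ) -> dict:
    """Is influence more negative for larger |ΔBF| than chance?

    Pearson r between influence and |ΔBF| over all retained pairs whose
    target and neuron both have a BF, compared with a null in which BFs are
    permuted across the field of view's tuned neurons.  One-sided
    p = max(#{r_shuffle <= r_observed}, 1) / n_shuffles (more negative =
    like-to-like organization).
    """
    tuned = tuning_records.dropna(subset=["bf_log2"]).set_index("neuron_id")
    rec = influence_records.loc[~influence_records["excluded"].astype(bool)]
    rec = rec.loc[rec["target_id"].isin(tuned.index)
                  & rec["neuron_id"].isin(tuned.index)]
    rec = rec.dropna(subset=["influence"])
    if len(rec) < 3:
        raise ValueError("too few tuned pairs for the shuffle test")
    bf = tuned["bf_log2"]
    if bf.nunique() < 2:
        raise ValueError("all best frequencies identical; test undefined")
    tgt_bf = bf.loc[rec["target_id"]].to_numpy()
    nrn_bf = bf.loc[rec["neuron_id"]].to_numpy()
    infl = rec["influence"].to_numpy()
    obs_r = float(np.corrcoef(infl, np.abs(tgt_bf - nrn_bf))[0, 1])

    rng = np.random.default_rng(seed)
    neuron_index = bf.index.to_numpy()
    pos_t = np.searchsorted(neuron_index, rec["target_id"].to_numpy())
    pos_n = np.searchsorted(neuron_index, rec["neuron_id"].to_numpy())
    bf_vals = bf.to_numpy()
    infl_c = infl - infl.mean()
    infl_ss = float(np.sqrt((infl_c ** 2).sum()))
    null = np.empty(n_shuffles)
    for s in range(n_shuffles):
        perm = rng.permutation(bf_vals)
        dbf = np.abs(perm[pos_t] - perm[pos_n])
        dc = dbf - dbf.mean()
        denom = infl_ss * np.sqrt((dc ** 2).sum())
        null[s] = float(infl_c @ dc) / denom if denom > 0 else 0.0
    p = max(int((null <= obs_r).sum()), 1) / n_shuffles
    return {"observed_r": obs_r, "p": float(p), "n_shuffles": int(n_shuffles),
            "n_pairs": int(len(rec)), "null_r": null, "seed": seed}
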