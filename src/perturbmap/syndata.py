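"""Synthetic photostimulation sessions with known ground-truth influence.

A session emulates one field of view: Poisson spiking whose rate is shaped
by a running-state gain, a slow shared latent per cell type, and — on
stimulation trials — a difference-of-Gaussians (DoG) influence kernel
around the stimulated target plus a direct drive on neurons within the
spiral's direct-activation radius.  Spikes are convolved with an AR1
calcium kernel, scaled into fluorescence, mixed with a neuropil trace and
Gaussian noise.  The applied trial-averaged rate change for every
(target, neuron) pair is stored as ``true_effect`` so downstream stages
can be validated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .params import GroundTruthParams

__all__ = [
    "Session",
    "influence_kernel",
    "generate_session",
    "generate_null_session",
    "ProtocolError",
]

TONE_FREQS_KHZ = np.array([4.0, 8.0, 12.0, 16.0, 24.0, 32.0])


class ProtocolError(ValueError):
    """Requested protocol does not fit in the session (e.g. too few frames)."""


@dataclass
class Session:
    """One synthetic field-of-view recording.

    Arrays are neurons x frames; positions are µm within the square FOV.
    ``stim_table`` has columns (target_id, onset_frame, trial_index) where
    target_id is the neuron index of the stimulated cell.  ``true_effect``
    is (n_all_targets x n_neurons): the trial-averaged added firing rate
    (events/s, during the stimulation frames) each target imposed on each
    neuron, including the direct drive on the target itself.
    """

    positions: np.ndarray
    cell_type: np.ndarray           # "SOM" / "NonSOM" per neuron
    opsin_target: np.ndarray        # bool per neuron
    control_target: np.ndarray      # bool per neuron
    f_raw: np.ndarray
    f_neu: np.ndarray
    stim_table: pd.DataFrame
    run_speed: np.ndarray
    tone_table: pd.DataFrame
    true_effect: np.ndarray
    target_ids: np.ndarray          # stimulated neuron indices, opsin + control
    best_frequency: np.ndarray      # ground-truth BF, log2 kHz (NaN if untuned)
    area_tag: str = "generic"
    frame_rate: float = 30.0
    params: GroundTruthParams | None = None
    processed: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return self.f_raw.shape[0]

    @property
    def n_frames(self) -> int:
        return self.f_raw.shape[1]

    def onsets_for(self, target_id: int) -> np.ndarray:
        tab = self.stim_table
        return tab.loc[tab["target_id"] == target_id, "onset_frame"].to_numpy()


def influence_kernel(distance, params: GroundTruthParams):
    """Ground-truth DoG influence at intersomatic distance ``distance`` (µm).

    k(d) = center_amp exp(-d²/2σc²) − surround_amp exp(-d²/2σs²);
    a narrow positive center with a more diffuse suppressive surround.
    """
    d = np.asarray(distance, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be >= 0")
    center = params.center_amp * np.exp(-(d ** 2) / (2.0 * params.center_sigma ** 2))
    surround = params.surround_amp * np.exp(-(d ** 2) / (2.0 * params.surround_sigma ** 2))
    out = center - surround
    return float(out) if np.isscalar(distance) else out


def _running_trace(rng: np.random.Generator, n_frames: int, frame_rate: float):
    """Two-state (stationary/running) Markov chain with log-normal bout speeds.

    Returns (speed cm/s per frame, running bool per frame).  Mean dwell time
    ~8 s in each state, so roughly half the session is stationary — the
    within-session speed quartiles then put stationary trials in Q1.
    """
    p_switch = 1.0 / (8.0 * frame_rate)
    state = np.empty(n_frames, dtype=bool)
    speed = np.zeros(n_frames)
    s = bool(rng.random() < 0.5)
    bout_speed = float(rng.lognormal(np.log(8.0), 0.5))
    for t in range(n_frames):
        if rng.random() < p_switch:
            s = not s
            if s:
                bout_speed = float(rng.lognormal(np.log(8.0), 0.5))
        state[t] = s
        if s:
            speed[t] = bout_speed
    if np.any(state):
        jitter = 1.0 + 0.1 * rng.standard_normal(n_frames)
        speed = np.clip(speed * jitter, 0.0, None)
        speed[~state] = 0.0
    return speed, state


def _shared_latent(rng: np.random.Generator, n_frames: int, frame_rate: float,
                   sd: float, tau_s: float = 1.0) -> np.ndarray:
    """AR1 latent with stationary SD ``sd`` and timescale ``tau_s``."""
    if sd == 0:
        return np.zeros(n_frames)
    rho = np.exp(-1.0 / (frame_rate * tau_s))
    eps = rng.standard_normal(n_frames) * sd * np.sqrt(1.0 - rho ** 2)
    z = lfilter([1.0], [1.0, -rho], eps)
    z[0] = rng.normal(0.0, sd)
    return z


def _stim_schedule(rng: np.random.Generator, params: GroundTruthParams,
                   target_ids: np.ndarray) -> pd.DataFrame:
    """Pseudorandom target order: every target once per repeat block, one
    onset every ``isi_frames`` frames."""
    isi_f = params.isi_frames
    order = np.concatenate([rng.permutation(target_ids)
                            for _ in range(params.n_repeats)])
    onsets = params.stim_pad + isi_f * np.arange(order.size)
    trial_index = np.empty(order.size, dtype=int)
    seen: dict[int, int] = {}
    for i, t in enumerate(order):
        seen[t] = seen.get(t, -1) + 1
        trial_index[i] = seen[t]
    return pd.DataFrame({"target_id": order.astype(int),
                         "onset_frame": onsets.astype(int),
                         "trial_index": trial_index})


def generate_session(params: GroundTruthParams, *,
                     null_network: bool = False,
                     null_direct: bool = False) -> Session:
    """Generate one synthetic session.

    ``null_network`` zeroes all off-target stimulation effects;
    ``null_direct`` additionally removes the direct drive on the target.
    Identical ``params`` (including ``seed``) give a bit-identical session.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_neurons
    fr = params.frame_rate
    n_frames = params.total_frames()
    if n_frames < params.required_frames():
        raise ProtocolError(
            f"n_frames={n_frames} cannot hold "
            f"{params.n_stim_events} stimulations at isi={params.isi}s "
            f"plus the tone block ({params.required_frames()} frames needed)")

    # --- cells -------------------------------------------------------------
    positions = rng.uniform(0.0, params.fov_size, size=(n, 2))
    is_som = rng.random(n) < params.som_fraction
    cell_type = np.where(is_som, "SOM", "NonSOM")
    nonsom_idx = np.flatnonzero(~is_som)
    n_tot_targets = params.n_targets + params.n_control_targets
    if nonsom_idx.size < n_tot_targets:
        raise ProtocolError("not enough Non-SOM neurons to assign targets")
    chosen = rng.choice(nonsom_idx, size=n_tot_targets, replace=False)
    opsin_ids = chosen[: params.n_targets]
    control_ids = chosen[params.n_targets:]
    opsin_target = np.zeros(n, dtype=bool)
    opsin_target[opsin_ids] = True
    control_target = np.zeros(n, dtype=bool)
    control_target[control_ids] = True
    target_ids = chosen

    # ground-truth tuning (log2 kHz, uniform over the tested 4-32 kHz range)
    best_frequency = rng.uniform(2.0, 5.0, size=n)
    latent_loading = rng.uniform(0.5, 1.5, size=n)

    # --- behavior and shared variability ------------------------------------
    run_speed, running = _running_trace(rng, n_frames, fr)
    z_som = _shared_latent(rng, n_frames, fr, params.shared_latent_sd)
    z_nonsom = _shared_latent(rng, n_frames, fr, params.shared_latent_sd)

    rate = np.empty((n, n_frames))
    gain_run = np.where(running, params.run_gain_som, 1.0)
    rate[is_som] = params.baseline_rate * gain_run * \
        (1.0 + latent_loading[is_som, None] * z_som[None, :])
    gain_run = np.where(running, params.run_gain_nonsom, 1.0)
    rate[~is_som] = params.baseline_rate * gain_run * \
        (1.0 + latent_loading[~is_som, None] * z_nonsom[None, :])

    # --- stimulation schedule and effects -----------------------------------
    stim_table = _stim_schedule(rng, params, target_ids)

    # per-target static effect vector over neurons (events/s added while on)
    dist = np.linalg.norm(positions[target_ids][:, None, :] -
                          positions[None, :, :], axis=2)  # (targets, neurons)
    effect = np.zeros_like(dist)
    for k, tid in enumerate(target_ids):
        if tid in control_ids:
            continue  # spiral on a non-opsin cell: no effect at all
        if not null_network:
            d = dist[k]
            center = params.center_amp * np.exp(-(d ** 2) / (2 * params.center_sigma ** 2))
            if params.like_to_like_strength > 0:
                dbf = np.abs(best_frequency - best_frequency[tid])
                sim = np.exp(-(dbf ** 2) / (2 * params.tuning_sigma ** 2))
                center = center * ((1.0 - params.like_to_like_strength)
                                   + params.like_to_like_strength * sim)
            if params.corr_influence_strength > 0:
                # near pairs sharing more of the latent (higher loading
                # product) receive a stronger positive center
                near = d < 125.0
                factor = 1.0 + params.corr_influence_strength * \
                    (latent_loading[tid] * latent_loading - 1.0)
                center = np.where(near, center * np.clip(factor, 0.2, None),
                                  center)
            surround = params.surround_amp * np.exp(-(d ** 2) / (2 * params.surround_sigma ** 2))
            eff = center - surround
            # the spiral dominates within the direct-activation radius
            eff[dist[k] <= params.direct_radius] = 0.0
            effect[k] = eff
        if not null_direct:
            effect[k, dist[k] <= params.direct_radius] += params.direct_amp

    # apply per event, scaled on running trials by run_influence_gain
    sf = params.stim_frames
    tid_to_row = {int(t): k for k, t in enumerate(target_ids)}
    applied_sum = np.zeros_like(effect)
    n_events_per_target = np.zeros(len(target_ids))
    for tgt, onset in zip(stim_table["target_id"].to_numpy(),
                          stim_table["onset_frame"].to_numpy()):
        k = tid_to_row[int(tgt)]
        scale = params.run_influence_gain if running[onset] else 1.0
        rate[:, onset:onset + sf] += scale * effect[k][:, None]
        applied_sum[k] += scale * effect[k]
        n_events_per_target[k] += 1
    true_effect = applied_sum / np.maximum(n_events_per_target, 1)[:, None]

    # --- tone block (after the stimulation block) ---------------------------
    tone_rows = []
    if params.n_tone_repeats > 0:
        tone_start = params.stim_pad * 2 + params.n_stim_events * params.isi_frames
        fr_i = int(round(fr))
        tone_order = np.concatenate([rng.permutation(TONE_FREQS_KHZ)
                                     for _ in range(params.n_tone_repeats)])
        tone_gain = rng.lognormal(0.0, 0.5, size=n)  # per-neuron responsiveness
        for j, f_khz in enumerate(tone_order):
            onset = tone_start + j * 2 * fr_i
            tone_rows.append((float(f_khz), int(onset)))
            dbf = np.log2(f_khz) - best_frequency
            resp = params.tone_amp * tone_gain * \
                np.exp(-(dbf ** 2) / (2 * params.tuning_sigma ** 2))
            rate[:, onset:onset + fr_i] += resp[:, None]
    tone_table = pd.DataFrame(tone_rows, columns=["frequency_khz", "onset_frame"])

    # --- spikes -> calcium -> fluorescence ----------------------------------
    np.clip(rate, 0.0, None, out=rate)
    spikes = rng.poisson(rate / fr).astype(np.float64)
    del rate
    g = np.exp(-1.0 / (fr * params.calcium_tau))
    calcium = lfilter([1.0], [1.0, -g], spikes * params.event_amp, axis=1)
    del spikes

    f0 = rng.uniform(80.0, 120.0, size=n)
    z_neu = _shared_latent(rng, n_frames, fr, 0.1, tau_s=5.0)
    f_neu = (30.0 * (1.0 + z_neu)[None, :]
             + 2.0 * rng.standard_normal((n, n_frames))).astype(np.float32)
    f_cell = f0[:, None] * (1.0 + calcium) \
        + f0[:, None] * params.noise_sd * rng.standard_normal((n, n_frames))
    f_raw = (f_cell + params.neuropil_mix * f_neu).astype(np.float32)
    del f_cell, calcium

    return Session(
        positions=positions, cell_type=cell_type, opsin_target=opsin_target,
        control_target=control_target, f_raw=f_raw, f_neu=f_neu,
        stim_table=stim_table, run_speed=run_speed, tone_table=tone_table,
        true_effect=true_effect, target_ids=target_ids,
        best_frequency=best_frequency, area_tag=params.area,
        frame_rate=fr, params=params)


def generate_null_session(params: GroundTruthParams, *,
                          direct_effect: bool = True) -> Session:
    """Session in which stimulation has no effect on any non-target neuron.

    With ``direct_effect`` the targets themselves are still driven (so they
    register as successfully stimulated); without it stimulation does
    nothing at all.  Used to calibrate the shuffle-null specificity.
    """
    return generate_session(params, null_network=True,
                            null_direct=not direct_effect)
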