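"""Ground-truth parameters for synthetic photostimulation sessions.

The defaults emulate the recording conditions of a single field of view:
~200 Non-SOM and ~15 SOM neurons imaged at 30 Hz, ~30 single-cell
photostimulation targets plus a handful of non-opsin control targets,
100 pseudorandom repeats per target at a 1 s interstimulus interval,
voluntary running bouts, and (auditory-cortex-like sessions) pure-tone
trials at six frequencies.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass

__all__ = ["GroundTruthParams", "ac_like_params", "ppc_like_params"]


@dataclass
class GroundTruthParams:
    """Parameters of the synthetic-session generator.

    The influence ground truth is a difference-of-Gaussians (DoG) kernel in
    intersomatic distance d:

        k(d) = center_amp * exp(-d^2 / (2 center_sigma^2))
             - surround_amp * exp(-d^2 / (2 surround_sigma^2))

    in units of added firing rate (events/s) during the ``stim_frames``
    frames following a stimulation onset.

    Attributes
    ----------
    n_neurons : total imaged neurons in the field of view.
    som_fraction : fraction of neurons labeled SOM.
    fov_size : side of the square field of view, µm.
    frame_rate : imaging rate, Hz.
    n_frames : total frames; ``None`` auto-sizes to fit the protocol.
    n_targets : opsin-expressing stimulation targets.
    n_control_targets : non-opsin control targets (no direct effect).
    n_repeats : stimulation repeats per target.
    isi : interstimulus interval, s.
    center_amp, center_sigma : positive-center amplitude (events/s) and
        width (µm) of the DoG influence kernel.
    surround_amp, surround_sigma : suppressive-surround amplitude (>=0,
        applied negatively) and width; surround_sigma > center_sigma.
    direct_radius : radius (µm) within which the photostimulation spiral
        directly drives a neuron.
    direct_amp : direct drive on the target, events/s.
    stim_frames : frames over which the stimulation rate change applies
        (3 frames ~ 100 ms at 30 Hz).
    baseline_rate : spontaneous rate, events/s.
    calcium_tau : indicator decay constant, s (AR1 kernel exp(-dt/tau)).
    event_amp : ΔF/F amplitude of a single event.
    noise_sd : additive fluorescence noise, ΔF/F units.
    neuropil_mix : fraction of the neuropil trace mixed into f_raw.
    run_gain_som, run_gain_nonsom : multiplicative rate gain while running.
    run_influence_gain : multiplicative scaling of stimulation effects on
        trials delivered while the animal is running (1 = state
        independent; <1 = influence strongest when stationary).
    shared_latent_sd : SD of the slow shared latent that induces noise
        correlations within each cell type.
    corr_influence_strength : couples each near pair's (<125 µm) influence
        amplitude to the product of the two neurons' latent loadings, so
        that noise correlation and influence become related for near pairs.
    tuning_sigma : width (octaves) of Gaussian frequency tuning.
    like_to_like_strength : 0..1; scales the positive-center influence by
        tuning similarity (0 = tuning independent).
    tone_amp : peak tone-evoked rate at a neuron's best frequency, events/s.
    n_tone_repeats : tone trials per frequency (0 = no tone block).
    area : free label, e.g. "AC-like" or "PPC-like".
    seed : generator seed; identical params + seed give identical sessions.
    """

    n_neurons: int = 215
    som_fraction: float = 0.07
    fov_size: float = 500.0
    frame_rate: float = 30.0
    n_frames: int | None = None
    n_targets: int = 30
    n_control_targets: int = 5
    n_repeats: int = 100
    isi: float = 1.0
    center_amp: float = 8.0
    center_sigma: float = 50.0
    surround_amp: float = 0.8
    surround_sigma: float = 150.0
    direct_radius: float = 12.5
    direct_amp: float = 30.0
    stim_frames: int = 3
    baseline_rate: float = 1.0
    calcium_tau: float = 0.35
    event_amp: float = 0.2
    noise_sd: float = 0.05
    neuropil_mix: float = 0.7
    run_gain_som: float = 1.0
    run_gain_nonsom: float = 1.0
    run_influence_gain: float = 1.0
    shared_latent_sd: float = 0.3
    corr_influence_strength: float = 0.0
    tuning_sigma: float = 1.0
    like_to_like_strength: float = 0.0
    tone_amp: float = 4.0
    n_tone_repeats: int = 0
    area: str = "generic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.som_fraction <= 1.0:
            raise ValueError("som_fraction must be in [0, 1]")
        for name in ("center_sigma", "surround_sigma", "tuning_sigma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.surround_sigma <= self.center_sigma:
            raise ValueError("surround_sigma must exceed center_sigma "
                             "(the surround is the more diffuse zone)")
        if self.surround_amp < 0:
            raise ValueError("surround_amp must be >= 0 (applied negatively)")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.n_targets < 1:
            raise ValueError("n_targets must be >= 1")
        if not 0.0 <= self.neuropil_mix <= 1.0:
            raise ValueError("neuropil_mix must be in [0, 1]")
        if self.frame_rate <= 0 or self.isi <= 0:
            raise ValueError("frame_rate and isi must be positive")

    # --- protocol geometry -------------------------------------------------

    @property
    def isi_frames(self) -> int:
        return int(round(self.isi * self.frame_rate))

    @property
    def n_stim_events(self) -> int:
        return (self.n_targets + self.n_control_targets) * self.n_repeats

    @property
    def stim_pad(self) -> int:
        """Frames of padding before the first / after the last onset."""
        return 60

    @property
    def tone_frames(self) -> int:
        if self.n_tone_repeats == 0:
            return 0
        n_tones = 6 * self.n_tone_repeats
        return n_tones * 2 * int(round(self.frame_rate)) + self.stim_pad

    def required_frames(self) -> int:
        stim = self.stim_pad * 2 + self.n_stim_events * self.isi_frames
        return stim + self.tone_frames

    def total_frames(self) -> int:
        return self.required_frames() if self.n_frames is None else self.n_frames

    def replace(self, **overrides) -> "GroundTruthParams":
        return dataclasses.replace(self, **overrides)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruthParams":
        return cls(**json.loads(text))


def ac_like_params(**overrides) -> GroundTruthParams:
    """Sensory-cortex-like regime: narrow positive center, wide and strong
    suppressive surround, weak/mixed running modulation, tone trials, and
    like-to-like (tuning-similarity) coupling of the positive center."""
    base = dict(
        area="AC-like",
        center_sigma=45.0,
        surround_amp=0.7,
        surround_sigma=180.0,
        run_gain_som=1.1,
        run_gain_nonsom=1.0,
        run_influence_gain=1.0,
        corr_influence_strength=1.0,
        like_to_like_strength=1.0,
        n_tone_repeats=20,
    )
    base.update(overrides)
    return GroundTruthParams(**base)


def ppc_like_params(**overrides) -> GroundTruthParams:
    """Association-cortex-like regime: wider positive center, weaker and
    narrower surround, strong positive running modulation of activity
    (especially SOM), influence strongest when stationary, no tones."""
    base = dict(
        area="PPC-like",
        center_sigma=80.0,
        surround_amp=0.35,
        surround_sigma=120.0,
        run_gain_som=2.0,
        run_gain_nonsom=1.3,
        run_influence_gain=0.3,
        corr_influence_strength=1.0,
        like_to_like_strength=0.0,
        n_tone_repeats=0,
    )
    base.update(overrides)
    return GroundTruthParams(**base)
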