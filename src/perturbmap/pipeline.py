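"""Pipeline orchestration: simulate → preprocess → influence → analyses.

A :class:`RunConfig` carries the seed and every stage parameter; it is
serialized into each report for provenance.  All randomness flows from the
root seed through named substreams so stages are independently
reproducible; identical config + seed gives identical reports.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import influence as infl
from . import noisecorr, popaxis, spatialmap, state, tuning
from .preprocess import preprocess_session
from .syndata import Session

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "validate_session", "run_pipeline",
            "SchemaError"]

_KNOWN_KEYS = {
    "seed", "n_shuffles", "pre_len", "post_len", "exclusion_radius",
    "neuropil_r", "dff_half_window", "dff_percentile", "deconv_tau",
    "deconv_event_floor", "use_events", "bin_width", "max_dist",
    "near_split_um", "speed_window", "tuning_shuffles", "run_tuning",
    "run_state", "run_noisecorr", "run_popaxis", "out_dir",
}


@dataclass
class RunConfig:
    """All pipeline parameters; unknown keys are rejected at construction."""

    seed: int = 0
    n_shuffles: int = 1000
    pre_len: int = 10
    post_len: int = 10
    exclusion_radius: float = 25.0
    neuropil_r: float = 0.7
    dff_half_window: int = 450
    dff_percentile: float = 8.0
    deconv_tau: float | None = None
    deconv_event_floor: float = 0.05
    use_events: bool = False
    bin_width: float = 50.0
    max_dist: float = 400.0
    near_split_um: float = 125.0
    speed_window: int = 20
    tuning_shuffles: int = 500
    run_tuning: bool = True
    run_state: bool = True
    run_noisecorr: bool = True
    run_popaxis: bool = True
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def substream(self, name: str) -> np.random.Generator:
        """Named substream of the root seed (shuffles, permutation tests...)."""
        import zlib
        ss = np.random.SeedSequence([self.seed, zlib.crc32(name.encode())])
        return np.random.default_rng(ss)


@dataclass
class RunReport:
    """Per-session outputs, plus config/seed provenance and warnings."""

    config: dict
    summary: dict = dc_field(default_factory=dict)
    tables: dict = dc_field(default_factory=dict)
    warnings: list = dc_field(default_factory=list)


class SchemaError(ValueError):
    """Session file/object fails the mandatory schema."""


def validate_session(session: Session) -> dict:
    """Schema and consistency check; returns {'errors': [...], 'warnings': [...]}.

    Hard failures: shape mismatches, missing positions, non-monotone onset
    frames per target, onsets closer than the interstimulus interval.
    """
    errors: list[str] = []
    warnings: list[str] = []
    n, t = session.f_raw.shape
    if session.f_neu.shape != (n, t):
        errors.append("f_neu shape differs from f_raw")
    if session.positions.shape != (n, 2):
        errors.append(f"positions shape {session.positions.shape} != ({n}, 2)")
    if not np.all(np.isfinite(session.positions)):
        bad = np.unique(np.nonzero(~np.isfinite(session.positions))[0])
        errors.append(f"neuron(s) {bad.tolist()[:5]} lack a finite position")
    if session.run_speed.shape[0] != t:
        errors.append("run_speed length differs from frame count")
    if np.any(session.run_speed < 0):
        errors.append("negative running speeds")
    fov = session.params.fov_size if session.params else None
    if fov is not None and (np.any(session.positions < 0)
                            or np.any(session.positions > fov)):
        errors.append("positions outside the field of view")
    stim = session.stim_table
    for tid, grp in stim.groupby("target_id"):
        o = grp["onset_frame"].to_numpy()
        if np.any(np.diff(o) <= 0):
            errors.append(f"target {tid}: onset frames not strictly increasing")
            break
    all_onsets = np.sort(stim["onset_frame"].to_numpy())
    if session.params is not None and all_onsets.size > 1:
        if np.min(np.diff(all_onsets)) < session.params.isi_frames:
            errors.append("consecutive onsets closer than the interstimulus interval")
    if np.any(all_onsets >= t):
        errors.append("stimulation onset beyond the end of the recording")
    if len(session.tone_table):
        if np.any(session.tone_table["onset_frame"].to_numpy() >= t):
            errors.append("tone onset beyond the end of the recording")
    return {"errors": errors, "warnings": warnings, "ok": not errors}


def run_pipeline(session: Session, config: RunConfig | None = None) -> RunReport:
    """Run every enabled stage on one session and assemble a report."""
    config = config or RunConfig()
    report = RunReport(config=config.to_dict())
    check = validate_session(session)
    if not check["ok"]:
        raise SchemaError("; ".join(check["errors"]))
    report.warnings.extend(check["warnings"])

    bundle = preprocess_session(
        session, r=config.neuropil_r, half_window=config.dff_half_window,
        pct=config.dff_percentile, tau=config.deconv_tau,
        event_floor=config.deconv_event_floor,
        compute_events=config.use_events or
        (config.run_tuning and len(session.tone_table) > 0))
    activity = bundle.events if config.use_events else bundle.dff

    records = infl.map_influence(
        session, activity, n_shuffles=config.n_shuffles,
        seed=int(config.substream("shuffles").integers(2 ** 31)),
        pre_len=config.pre_len, post_len=config.post_len,
        exclusion_radius=config.exclusion_radius)
    report.tables["influence_records"] = records
    retained = records.loc[~records["excluded"].astype(bool)]
    n_ret = len(retained)
    success = session.processed["target_success"]
    opsin = [t for t in session.target_ids if not session.control_target[t]]
    ctrl = [t for t in session.target_ids if session.control_target[t]]
    report.summary.update({
        "area_tag": session.area_tag,
        "n_targets_attempted": len(opsin),
        "n_targets_successful": int(sum(success[int(t)] for t in opsin)),
        "n_control_targets": len(ctrl),
        "n_control_successful": int(sum(success[int(t)] for t in ctrl)),
        "n_retained_pairs": int(n_ret),
        "frac_positive": float((retained["sig_class"] == "positive").mean())
        if n_ret else np.nan,
        "frac_negative": float((retained["sig_class"] == "negative").mean())
        if n_ret else np.nan,
    })
    if n_ret:
        report.tables["distance_table"] = spatialmap.distance_table(
            records, session.area_tag)
        report.tables["distance_profile"] = pd.DataFrame({
            "bin_center_um": (prof := spatialmap.distance_binned_influence(
                records, config.bin_width, config.max_dist)).bin_centers,
            "mean_influence": prof.mean_influence, "n": prof.counts})

    if config.run_popaxis and n_ret:
        axes, wtab = popaxis.session_stimulus_axes(
            session, activity, pre_len=config.pre_len, post_len=config.post_len,
            exclusion_radius=config.exclusion_radius)
        report.tables["stimulus_axis_weights"] = wtab
        report.summary["mean_axis_weight"] = float(wtab["weight"].mean()) \
            if len(wtab) else np.nan

    if config.run_state and n_ret:
        try:
            qtab = state.influence_by_quartile(
                session, activity, records=records, pre_len=config.pre_len,
                post_len=config.post_len, speed_window=config.speed_window)
            report.tables["influence_by_quartile"] = qtab.attrs["summary"]
            report.tables["activity_by_quartile"] = (
                state.activity_by_quartile(session, activity,
                                           pre_len=config.pre_len,
                                           speed_window=config.speed_window)
                .groupby(["quartile", "neuron_type"])["mean_activity"]
                .mean().reset_index())
        except ValueError as exc:
            report.warnings.append(f"state analysis skipped: {exc}")

    if config.run_noisecorr and n_ret:
        ncr = noisecorr.session_noise_correlations(
            session, activity, post_len=config.post_len,
            near_split_um=config.near_split_um)
        report.tables["noise_corr_records"] = ncr
        report.tables["corr_influence_table"] = \
            noisecorr.correlation_influence_relation(ncr, records,
                                                     config.near_split_um)

    if config.run_tuning and len(session.tone_table) and n_ret:
        ttab = tuning.session_tuning(
            session, seed=int(config.substream("tuning").integers(2 ** 31)))
        report.tables["tuning_records"] = ttab
        try:
            test = tuning.tuning_shuffle_test(
                records, ttab, n_shuffles=config.tuning_shuffles,
                seed=int(config.substream("tuning_shuffle").integers(2 ** 31)))
            report.summary["tuning_shuffle"] = {
                k: v for k, v in test.items() if k != "null_r"}
        except ValueError as exc:
            report.warnings.append(f"tuning shuffle skipped: {exc}")

    if config.out_dir:
        _write_report(report, Path(config.out_dir))
    return report


def _write_report(report: RunReport, out_dir: Path) -> None:
    from .io import write_json
    out_dir.mkdir(parents=True, exist_ok=True)
    for name, tab in report.tables.items():
        if isinstance(tab, pd.DataFrame):
            tab.to_csv(out_dir / f"{name}.csv", index=False)
    write_json({"config": report.config, "summary": report.summary,
                "warnings": report.warnings}, out_dir / "report.json")
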