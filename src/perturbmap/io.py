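"""Session HDF5 read/write and CSV export.

A session file holds fixed-name datasets (positions, labels, f_raw, f_neu,
stim_table, run_speed, tone_table, true_effect, target_ids,
best_frequency) plus root attributes; the generator parameters travel both
as a JSON attribute and as a ``<file>.json`` sidecar.  Processed activity
(ΔF/F, events) is written under a ``processed/`` group.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .params import GroundTruthParams
from .preprocess import ActivityBundle
from .syndata import Session

__all__ = ["save_session", "load_session", "export_tables", "save_processed"]

_LABELS = {"SOM": 1, "NonSOM": 0}


def save_session(session: Session, path: str | Path, *,
                 sidecar: bool = True) -> Path:
    path = Path(path)
    with h5py.File(path, "w") as h5:
        h5.create_dataset("positions", data=session.positions)
        labels = np.array([_LABELS[c] for c in session.cell_type], dtype=np.int8)
        h5.create_dataset("labels", data=labels)
        h5["labels"].attrs["encoding"] = "0=NonSOM, 1=SOM"
        h5.create_dataset("opsin_target", data=session.opsin_target.astype(np.int8))
        h5.create_dataset("control_target", data=session.control_target.astype(np.int8))
        h5.create_dataset("f_raw", data=session.f_raw)
        h5.create_dataset("f_neu", data=session.f_neu)
        h5.create_dataset("stim_table",
                          data=session.stim_table.to_numpy(dtype=np.int64))
        h5["stim_table"].attrs["columns"] = "target_id,onset_frame,trial_index"
        h5.create_dataset("run_speed", data=session.run_speed)
        tone = session.tone_table.to_numpy(dtype=np.float64) \
            if len(session.tone_table) else np.empty((0, 2))
        h5.create_dataset("tone_table", data=tone)
        h5["tone_table"].attrs["columns"] = "frequency_khz,onset_frame"
        h5.create_dataset("true_effect", data=session.true_effect)
        h5.create_dataset("target_ids", data=session.target_ids)
        h5.create_dataset("best_frequency", data=session.best_frequency)
        h5.attrs["area_tag"] = session.area_tag
        h5.attrs["frame_rate"] = session.frame_rate
        if session.params is not None:
            h5.attrs["params_json"] = session.params.to_json()
    if sidecar and session.params is not None:
        Path(str(path) + ".json").write_text(session.params.to_json())
    return path


def load_session(path: str | Path) -> Session:
    with h5py.File(path, "r") as h5:
        labels = h5["labels"][()]
        cell_type = np.where(labels == 1, "SOM", "NonSOM")
        stim = pd.DataFrame(h5["stim_table"][()],
                            columns=["target_id", "onset_frame", "trial_index"])
        tone_arr = h5["tone_table"][()]
        tone = pd.DataFrame(tone_arr, columns=["frequency_khz", "onset_frame"])
        tone["onset_frame"] = tone["onset_frame"].astype(int)
        params = None
        if "params_json" in h5.attrs:
            params = GroundTruthParams.from_json(str(h5.attrs["params_json"]))
        session = Session(
            positions=h5["positions"][()], cell_type=cell_type,
            opsin_target=h5["opsin_target"][()].astype(bool),
            control_target=h5["control_target"][()].astype(bool),
            f_raw=h5["f_raw"][()], f_neu=h5["f_neu"][()],
            stim_table=stim, run_speed=h5["run_speed"][()],
            tone_table=tone, true_effect=h5["true_effect"][()],
            target_ids=h5["target_ids"][()],
            best_frequency=h5["best_frequency"][()],
            area_tag=str(h5.attrs.get("area_tag", "generic")),
            frame_rate=float(h5.attrs.get("frame_rate", 30.0)),
            params=params)
        if "processed" in h5:
            grp = h5["processed"]
            events = grp["events"][()] if "events" in grp else None
            session.processed["bundle"] = ActivityBundle(
                dff=grp["dff"][()], events=events,
                frame_rate=session.frame_rate)
    return session


def save_processed(path: str | Path, bundle: ActivityBundle) -> None:
    """Write a processed ActivityBundle into an existing session file."""
    with h5py.File(path, "a") as h5:
        if "processed" in h5:
            del h5["processed"]
        grp = h5.create_group("processed")
        grp.create_dataset("dff", data=bundle.dff.astype(np.float32))
        if bundle.events is not None:
            grp.create_dataset("events", data=bundle.events.astype(np.float32))


def export_tables(session: Session, out_dir: str | Path) -> list[Path]:
    """CSV export of the stimulation and tone tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, tab in (("stim_table", session.stim_table),
                      ("tone_table", session.tone_table)):
        p = out_dir / f"{name}.csv"
        tab.to_csv(p, index=False)
        written.append(p)
    return written


def write_json(obj: dict, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))
    Path(path).write_text(json.dumps(obj, indent=2, default=_default))
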