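"""File formats: recordings, covariance archives, models and traces.

Recordings are read from EDF/GDF (through mne, when available) or from the
plain tabular fixture format: a CSV of samples × channels together with a
CSV event table ``onset_s,label``.  Covariance sets round-trip through a
JSON container (one matrix per record, labels and session ids alongside);
trained models serialize to versioned JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .classify import FGDA, MDM, FgMDM
from .geometry import SPDSet
from .preprocessing import RawRecording

__all__ = [
    "read_recording_csv",
    "write_recording_csv",
    "read_recording_edf",
    "read_spdset_json",
    "write_spdset_json",
    "save_fgmdm",
    "load_fgmdm",
]

FORMAT_VERSION = 1


def write_recording_csv(rec: RawRecording, data_path, events_path) -> None:
    """Write a recording as a samples × channels CSV plus an event-table CSV.

    The sampling rate and channel roles travel in a JSON sidecar header line
    (``# {...}``) at the top of the data file.
    """
    header = {
        "fs": rec.fs,
        "eog_channels": rec.eog_channels,
        "session_id": rec.session_id,
        "run_id": rec.run_id,
    }
    with open(data_path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        pd.DataFrame(rec.data, columns=rec.channel_names).to_csv(fh, index=False)
    pd.DataFrame(rec.events, columns=["onset_s", "label"]).to_csv(events_path, index=False)


def read_recording_csv(data_path, events_path=None) -> RawRecording:
    """Read the tabular fixture format written by :func:`write_recording_csv`."""
    with open(data_path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise ValueError("data file is missing the '# {json}' header line with fs")
        header = json.loads(first[2:])
        df = pd.read_csv(fh)
    events: List[Tuple[float, str]] = []
    if events_path is not None:
        ev = pd.read_csv(events_path)
        events = [(float(r.onset_s), str(r.label)) for r in ev.itertuples()]
    return RawRecording(
        data=df.to_numpy(float),
        fs=float(header["fs"]),
        channel_names=list(df.columns),
        events=events,
        eog_channels=header.get("eog_channels"),
        session_id=header.get("session_id", "S01"),
        run_id=header.get("run_id", "R01"),
    )


def read_recording_edf(path, eog_channels: Optional[List[str]] = None) -> RawRecording:
    """Read an EDF/GDF recording with its annotations as cue events (via mne)."""
    try:
        import mne
    except ImportError as err:  # pragma: no cover
        raise ImportError("reading EDF/GDF requires the 'mne' package") from err
    path = str(path)
    reader = mne.io.read_raw_gdf if path.lower().endswith(".gdf") else mne.io.read_raw_edf
    raw = reader(path, preload=True, verbose="error")
    data = raw.get_data().T * 1e6  # volts → μV
    events = [(float(on), str(desc)) for on, desc in zip(raw.annotations.onset, raw.annotations.description)]
    return RawRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_names=list(raw.ch_names),
        events=events,
        eog_channels=eog_channels,
    )


def write_spdset_json(covs: SPDSet, path) -> None:
    payload = {
        "version": FORMAT_VERSION,
        "mats": covs.mats.tolist(),
        "labels": None if covs.labels is None else covs.labels.tolist(),
        "session_ids": None if covs.session_ids is None else covs.session_ids.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def read_spdset_json(path) -> SPDSet:
    payload = json.loads(Path(path).read_text())
    return SPDSet(
        np.asarray(payload["mats"], float),
        None if payload["labels"] is None else np.asarray(payload["labels"]),
        None if payload["session_ids"] is None else np.asarray(payload["session_ids"]),
    )


def save_fgmdm(model: FgMDM, path) -> None:
    """Serialize a trained FgMDM (class means, projector W, tangent base)."""
    payload = {
        "version": FORMAT_VERSION,
        "kind": "fgmdm",
        "classes": model.classes_.tolist(),
        "mdm_means": model.mdm_.means_.tolist(),
        "fgda_base": model.fgda_.base_.tolist(),
        "fgda_w": model.fgda_.w_.tolist(),
        "shrinkage": model.shrinkage,
    }
    Path(path).write_text(json.dumps(payload))


def load_fgmdm(path) -> FgMDM:
    payload = json.loads(Path(path).read_text())
    if payload.get("kind") != "fgmdm" or payload.get("version") != FORMAT_VERSION:
        raise ValueError("not a recognized FgMDM model file")
    model = FgMDM(shrinkage=payload["shrinkage"])
    model.fgda_ = FGDA(shrinkage=payload["shrinkage"])
    model.fgda_.base_ = np.asarray(payload["fgda_base"], float)
    model.fgda_.w_ = np.asarray(payload["fgda_w"], float)
    model.mdm_ = MDM(
        classes_=np.asarray(payload["classes"]),
        means_=np.asarray(payload["mdm_means"], float),
    )
    return model
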