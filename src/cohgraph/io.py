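"""Readers and writers for recordings, matrices, tables, trees and manifests.

One fixed delimited dialect is used throughout: comma-separated, period
decimal, header row, UTF-8. Symmetric matrices carry electrode labels as
both header and first column. Raw EEG is read from EDF (via mne) or from
a delimited matrix (one row per channel) with a JSON sidecar holding the
sampling rate; recordings are written as delimited text + sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import get_band
from .connectivity import ConnectivityMatrix
from .graph_features import CLASS_COLUMN, FeatureTable, METRICS
from .montage import CHANNELS, canonical_label
from .preprocessing import EEGRecording, EventLog


def _resolve_channels(labels: list[str]) -> list[int]:
    """Map file channel labels to canonical montage order; returns the
    permutation such that data[perm] is in canonical order."""
    try:
        canon = [canonical_label(lab) for lab in labels]
    except ValueError as err:
        unknown = [lab for lab in labels if _is_unknown(lab)]
        raise ValueError(
            f"{len(labels)}-channel file has labels outside the 19-site "
            f"montage: {unknown}"
        ) from err
    if sorted(canon) != sorted(CHANNELS):
        missing = sorted(set(CHANNELS) - set(canon))
        raise ValueError(f"file is missing montage channels: {missing}")
    return [canon.index(c) for c in CHANNELS]


def _is_unknown(lab: str) -> bool:
    try:
        canonical_label(lab)
        return False
    except ValueError:
        return True


def read_recording(path: str | Path, format: str | None = None) -> EEGRecording:
    """Read a 19-channel recording from EDF or delimited text.

    Channels are re-ordered to canonical montage order regardless of file
    order; labels are matched case-insensitively. For delimited input a
    JSON sidecar ``<path>.json`` must provide ``fs`` (and may provide
    ``subject_id`` and ``channels``).
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "delimited"
    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        labels = list(raw.ch_names)
        perm = _resolve_channels(labels)
        data = raw.get_data() * 1e6  # mne uses volts
        return EEGRecording(samples=data[perm], fs=float(raw.info["sfreq"]),
                            subject_id=path.stem)
    if format == "delimited":
        frame = pd.read_csv(path, index_col=0)
        sidecar = Path(str(path) + ".json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        labels = list(frame.index)
        perm = _resolve_channels(labels)
        fs = float(meta.get("fs", 200.0))
        return EEGRecording(samples=frame.to_numpy()[perm], fs=fs,
                            subject_id=str(meta.get("subject_id", path.stem)))
    raise ValueError(f"unknown recording format {format!r}")


def write_recording(recording: EEGRecording, path: str | Path) -> None:
    path = Path(path)
    frame = pd.DataFrame(recording.samples, index=list(CHANNELS))
    frame.index.name = "channel"
    frame.to_csv(path)
    Path(str(path) + ".json").write_text(json.dumps(
        {"fs": recording.fs, "subject_id": recording.subject_id,
         "channels": list(CHANNELS)}, indent=2))


def read_event_log(path: str | Path) -> EventLog:
    frame = pd.read_csv(path)
    return EventLog(onsets=frame["onset_sample"].to_numpy(),
                    correct=frame["correct"].to_numpy().astype(bool))


def write_event_log(log: EventLog, path: str | Path) -> None:
    pd.DataFrame({"onset_sample": log.onsets,
                  "correct": log.correct.astype(int)}).to_csv(path, index=False)


def write_matrix(matrix: ConnectivityMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(matrix.W, index=list(CHANNELS), columns=list(CHANNELS))
    frame.index.name = "electrode"
    frame.to_csv(path)
    Path(str(path) + ".json").write_text(json.dumps(
        {"subject_id": matrix.subject_id, "band": matrix.band.name,
         "threshold": matrix.threshold_value}, indent=2))


def read_matrix(path: str | Path) -> ConnectivityMatrix:
    frame = pd.read_csv(path, index_col=0)
    meta = json.loads(Path(str(path) + ".json").read_text())
    return ConnectivityMatrix(
        W=frame.to_numpy(), threshold_value=float(meta["threshold"]),
        band=get_band(meta["band"]), subject_id=meta["subject_id"],
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """CSV with header ``Participant,<19 electrodes>,Achievement level``."""
    out = table.data.rename(columns={CLASS_COLUMN: "Achievement level"})
    out.to_csv(path)


def read_feature_table(path: str | Path, band: str, metric: str) -> FeatureTable:
    frame = pd.read_csv(path, index_col=0)
    frame = frame.rename(columns={"Achievement level": CLASS_COLUMN})
    return FeatureTable(data=frame, band=get_band(band).name, metric=metric)


def feature_table_filename(band: str, metric: str) -> str:
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    return f"B_{get_band(band).name}_G_{metric.lower()}.csv"


def write_tree_json(model, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def write_ground_truth(truth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=2))
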