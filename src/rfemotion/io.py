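"""Dataset container I/O.

A dataset is a single ``.npz`` archive holding, per recording, the phase
trace and optional ECG trace as named float arrays, plus one JSON metadata
block (subject, label, sampling rates, ground-truth profile, container
version). A flat CSV (time, value, subject, label, modality) is provided as
the interchange escape hatch.
"""

from __future__ import annotations

import dataclasses
import json
import zipfile
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import Recording, VitalSignProfile

CONTAINER_VERSION = 1


class ContainerError(ValueError):
    """Unreadable, truncated or version-incompatible dataset container."""


def write_dataset(recordings: list[Recording], path: str | Path) -> Path:
    path = Path(path)
    meta = {"container_version": CONTAINER_VERSION, "recordings": []}
    arrays: dict[str, np.ndarray] = {}
    for i, rec in enumerate(recordings):
        arrays[f"phase_{i:04d}"] = rec.phase_trace
        entry = {
            "subject_id": rec.subject_id,
            "label": rec.label,
            "sampling_rate": rec.sampling_rate,
            "ecg_sampling_rate": rec.ecg_sampling_rate,
            "has_ecg": rec.ecg_trace is not None,
            "ground_truth": dataclasses.asdict(rec.ground_truth)
            if rec.ground_truth is not None else None,
        }
        if rec.ecg_trace is not None:
            arrays[f"ecg_{i:04d}"] = rec.ecg_trace
        meta["recordings"].append(entry)
    arrays["meta"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)
    return path


def read_dataset(path: str | Path) -> list[Recording]:
    path = Path(path)
    try:
        with np.load(path) as npz:
            data = {k: npz[k] for k in npz.files}
    except (OSError, ValueError, zipfile.BadZipFile, KeyError) as exc:
        raise ContainerError(f"cannot read dataset container {path}: {exc}") from exc
    if "meta" not in data:
        raise ContainerError("container missing metadata block")
    meta = json.loads(bytes(data["meta"].tobytes()).decode())
    version = meta.get("container_version")
    if version != CONTAINER_VERSION:
        raise ContainerError(
            f"container version {version} unsupported (expected {CONTAINER_VERSION})")
    recordings = []
    for i, entry in enumerate(meta["recordings"]):
        key = f"phase_{i:04d}"
        if key not in data:
            raise ContainerError(f"container missing array {key}")
        phase = data[key]
        n = phase.size
        time = np.arange(n) / entry["sampling_rate"]
        gt = entry["ground_truth"]
        recordings.append(Recording(
            subject_id=entry["subject_id"], label=entry["label"], time=time,
            phase_trace=phase, sampling_rate=entry["sampling_rate"],
            ecg_trace=data.get(f"ecg_{i:04d}") if entry["has_ecg"] else None,
            ecg_sampling_rate=entry["ecg_sampling_rate"],
            ground_truth=VitalSignProfile(**gt) if gt else None))
    return recordings


def export_csv(recordings: list[Recording], path: str | Path) -> Path:
    """Flat long-format CSV: time, value, subject, label, modality."""
    path = Path(path)
    frames = []
    for rec in recordings:
        frames.append(pd.DataFrame({
            "time": rec.time, "value": rec.phase_trace,
            "subject": rec.subject_id, "label": rec.label, "modality": "rf"}))
        if rec.ecg_trace is not None:
            t_ecg = np.arange(rec.ecg_trace.size) / rec.ecg_sampling_rate
            frames.append(pd.DataFrame({
                "time": t_ecg, "value": rec.ecg_trace,
                "subject": rec.subject_id, "label": rec.label, "modality": "ecg"}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.12g")
    return path


def import_csv(path: str | Path) -> list[Recording]:
    """Rebuild recordings from the flat CSV (metadata beyond subject/label/
    sampling rate is not representable in the flat format)."""
    df = pd.read_csv(path)
    recordings = []
    for (subject, label), grp in df.groupby(["subject", "label"], sort=True):
        rf = grp[grp.modality == "rf"].sort_values("time")
        t = rf.time.to_numpy()
        fs = 1.0 / np.median(np.diff(t))
        ecg_grp = grp[grp.modality == "ecg"].sort_values("time")
        ecg = ecg_grp.value.to_numpy() if len(ecg_grp) else None
        ecg_fs = None
        if ecg is not None and len(ecg_grp) > 1:
            ecg_fs = 1.0 / np.median(np.diff(ecg_grp.time.to_numpy()))
        recordings.append(Recording(
            subject_id=subject, label=label, time=t,
            phase_trace=rf.value.to_numpy(), sampling_rate=float(round(fs, 6)),
            ecg_trace=ecg, ecg_sampling_rate=ecg_fs))
    return recordings
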