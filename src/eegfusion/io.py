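"""On-disk cohort layout, recording readers, and run artefacts.

Synthetic cohorts are written in a minimal BIDS-like layout::

    cohort/
      participants.tsv              # subject_id, class, class_name, mmse_raw
      sub-001/
        sub-001_eeg.npy             # channels x samples float array
        sub-001_eeg.json            # fs, channel labels, class, MMSE

Real recordings in EEGLAB ``.set`` format (e.g. the OpenNeuro ds004504
layout) can be read through :func:`read_recording` when ``mne`` is
installed; class labels and MMSE scores are then looked up in the BIDS
``participants.tsv`` if one is present.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .constants import CLASS_NAMES, MONTAGE_19
from .synthetic import EegRecording

__all__ = ["write_cohort", "read_recording", "read_cohort", "FormatError"]


class FormatError(ValueError):
    """The file is not a readable recording (unknown or truncated format)."""


def write_cohort(cohort: list[EegRecording], root: str | Path) -> Path:
    """Write one file per subject plus a cohort manifest; returns ``root``."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort:
        sid = rec.subject_id or f"sub-{len(rows) + 1:03d}"
        sub_dir = root / sid
        sub_dir.mkdir(exist_ok=True)
        np.save(sub_dir / f"{sid}_eeg.npy", rec.data)
        sidecar = {
            "fs": rec.fs,
            "channel_labels": list(rec.channel_labels),
            "class_label": rec.class_label,
            "mmse_raw": rec.mmse_raw,
            "subject_id": sid,
        }
        (sub_dir / f"{sid}_eeg.json").write_text(json.dumps(sidecar, indent=2))
        rows.append(
            {
                "subject_id": sid,
                "class": rec.class_label,
                "class_name": CLASS_NAMES[rec.class_label],
                "mmse_raw": rec.mmse_raw if rec.mmse_raw is not None else "n/a",
            }
        )
    pd.DataFrame(rows).to_csv(root / "participants.tsv", sep="\t", index=False)
    return root


def _read_npy_recording(path: Path, strict: bool) -> EegRecording:
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar for {path}")
    try:
        data = np.load(path)
        sidecar = json.loads(sidecar_path.read_text())
    except Exception as exc:  # truncated/corrupt -> fail closed
        raise FormatError(f"unreadable recording {path}: {exc}") from exc
    labels = tuple(sidecar["channel_labels"])
    if len(labels) != len(MONTAGE_19):
        msg = f"{path}: expected {len(MONTAGE_19)} channels, found {len(labels)}"
        if strict:
            raise FormatError(msg)
        warnings.warn(msg)
    return EegRecording(
        data=data,
        fs=float(sidecar["fs"]),
        channel_labels=labels,
        class_label=int(sidecar.get("class_label", 0)),
        mmse_raw=sidecar.get("mmse_raw"),  # absent stays None, never coerced to 0
        subject_id=sidecar.get("subject_id", path.stem.replace("_eeg", "")),
    )


def _read_set_recording(path: Path, strict: bool) -> EegRecording:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise FormatError(
            "reading EEGLAB .set files requires the optional 'mne' dependency"
        ) from exc
    try:
        raw = mne.io.read_raw_eeglab(path, preload=True, verbose="error")
    except Exception as exc:
        raise FormatError(f"unreadable EEGLAB file {path}: {exc}") from exc
    data = raw.get_data() * 1e6  # volts -> microvolts
    labels = tuple(raw.ch_names)
    if len(labels) != len(MONTAGE_19):
        msg = f"{path}: expected {len(MONTAGE_19)} channels, found {len(labels)}"
        if strict:
            raise FormatError(msg)
        warnings.warn(msg)
    # BIDS subject id, e.g. sub-001_task-eyesclosed_eeg.set -> sub-001
    sid = path.stem.split("_")[0]
    cls, mmse = 0, None
    for parent in (path.parent, path.parent.parent, path.parent.parent.parent):
        manifest = parent / "participants.tsv"
        if manifest.exists():
            df = pd.read_csv(manifest, sep="\t")
            row = df[df.get("participant_id", df.columns[0]) == sid]
            if len(row):
                group = str(row.iloc[0].get("Group", "C"))
                cls = {"C": 0, "F": 1, "A": 2}.get(group, 0)
                if "MMSE" in row.columns and not pd.isna(row.iloc[0]["MMSE"]):
                    mmse = int(row.iloc[0]["MMSE"])
            break
    return EegRecording(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=labels,
        class_label=cls,
        mmse_raw=mmse,
        subject_id=sid,
    )


def read_recording(path: str | Path, strict: bool = False) -> EegRecording:
    """Read a single recording (synthetic ``.npy`` + sidecar, or EEGLAB ``.set``).

    ``strict`` turns the 19-channel count check from a warning into an error.
    A missing MMSE score is recorded as ``None``, never as zero.
    """
    path = Path(path)
    if path.is_dir():
        candidates = sorted(path.glob("*_eeg.npy"))
        if not candidates:
            raise FormatError(f"no recording found in directory {path}")
        path = candidates[0]
    if path.suffix == ".npy":
        return _read_npy_recording(path, strict)
    if path.suffix == ".set":
        return _read_set_recording(path, strict)
    raise FormatError(f"unknown recording format: {path.suffix!r} ({path})")


def read_cohort(root: str | Path, strict: bool = False) -> list[EegRecording]:
    """Read every subject listed in a cohort directory's manifest."""
    root = Path(root)
    manifest = root / "participants.tsv"
    if not manifest.exists():
        raise FormatError(f"no participants.tsv manifest in {root}")
    df = pd.read_csv(manifest, sep="\t")
    return [read_recording(root / sid, strict=strict) for sid in df["subject_id"]]
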