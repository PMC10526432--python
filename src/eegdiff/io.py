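"""Readers and writers: delimited-matrix recordings, EDF input, manifests.

The native on-disk format for synthetic cohorts is a tab-delimited text
matrix — one row per sample, one column per channel, header row of
channel names — plus a cohort manifest CSV (subject_id, group, path,
fs). EDF files are read through :mod:`mne`.
"""
from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import MONTAGE_16, Recording

MANIFEST_COLUMNS = ("subject_id", "group", "path", "fs")


def write_recording_matrix(rec: Recording, path) -> Path:
    """Write a recording as a TSV matrix (samples x channels, header row)."""
    path = Path(path)
    df = pd.DataFrame(rec.data.T, columns=list(rec.channel_names))
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    return path


def read_recording_matrix(path, fs: float, subject_id: str = "",
                          group: str = "") -> Recording:
    """Read a TSV/CSV matrix written by :func:`write_recording_matrix`."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep)
    return Recording(subject_id=subject_id or path.stem, group=group,
                     data=df.to_numpy(float).T, fs=fs,
                     channel_names=tuple(df.columns))


def read_recording_edf(path, subject_id: str = "", group: str = "",
                       strict_montage: bool = True) -> Recording:
    """Read an EDF recording; channel names validated against the
    16-label montage (canonical order) unless ``strict_montage=False``."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = [n.upper().strip() for n in raw.ch_names]
    missing = [c for c in MONTAGE_16 if c not in names]
    if missing:
        msg = f"EDF {path} lacks montage channels: {', '.join(missing)}"
        if strict_montage:
            raise ValueError(msg)
        warnings.warn(msg)
        order = names
    else:
        order = list(MONTAGE_16)
    idx = [names.index(c) for c in order]
    data = raw.get_data()[idx] * 1e6  # volts -> microvolts
    return Recording(subject_id=subject_id or Path(path).stem, group=group,
                     data=data, fs=float(raw.info["sfreq"]),
                     channel_names=tuple(order))


def read_recording(path, format: str = "matrix", fs: float | None = None,
                   **kw) -> Recording:
    """Dispatch on declared format ('matrix' or 'edf')."""
    if format == "matrix":
        if fs is None:
            raise ValueError("matrix format requires an explicit fs")
        return read_recording_matrix(path, fs=fs, **kw)
    if format == "edf":
        return read_recording_edf(path, **kw)
    raise ValueError(f"unknown format {format!r}")


def save_cohort(recordings: list[Recording], out_dir) -> Path:
    """Write every recording as a TSV matrix plus a manifest CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        p = write_recording_matrix(rec, out_dir / f"{rec.subject_id}.tsv")
        rows.append({"subject_id": rec.subject_id, "group": rec.group,
                     "path": p.name, "fs": rec.fs})
    manifest = out_dir / "cohort.csv"
    pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS)).to_csv(
        manifest, index=False)
    return manifest


def load_cohort(manifest_path) -> list[Recording]:
    """Read back a cohort from its manifest CSV."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"cohort manifest not found: {manifest_path}")
    base = manifest_path.parent
    df = pd.read_csv(manifest_path)
    out = []
    for row in df.itertuples(index=False):
        p = Path(row.path)
        if not p.is_absolute():
            p = base / p
        if p.suffix.lower() == ".edf":
            rec = read_recording_edf(p, subject_id=row.subject_id,
                                     group=row.group)
        else:
            rec = read_recording_matrix(p, fs=float(row.fs),
                                        subject_id=row.subject_id,
                                        group=row.group)
        out.append(rec)
    return out


def save_feature_table(table: pd.DataFrame, path, params: dict | None = None,
                       ) -> Path:
    """Feature table to CSV with a JSON sidecar of extraction parameters."""
    import json

    path = Path(path)
    table.to_csv(path, index=False)
    if params is not None:
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(params, indent=2, default=str))
    return path


def load_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
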