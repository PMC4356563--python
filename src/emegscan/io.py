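"""Table and container I/O.

Dipole-result tables follow the schema of the deposited deviation-scan
spreadsheet: one page per modality (EMEG, EEG, MEG) with per-realization SNR,
residual variance, dipole location, normal and strength, plus a fourth page of
sEEG contact names, numbers and coordinates.  Both a CSV dialect (one file,
``modality`` column) and an XLSX dialect (page per modality, matched by sheet
name with positional fallback) are supported, with exact round-tripping.

Continuous recordings are persisted in a self-describing HDF5 container.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, InputError
from .phantom import ContinuousRecording, SEEGContactTable, SpikeEvent

DIPOLE_COLUMNS = [
    "modality",
    "group",
    "time_ms",
    "snr",
    "residual_variance",
    "loc_x_mm",
    "loc_y_mm",
    "loc_z_mm",
    "norm_x",
    "norm_y",
    "norm_z",
    "strength_nAm",
]
CONTACT_COLUMNS = ["electrode_name", "contact_number", "x_mm", "y_mm", "z_mm", "label"]
PAGE_ORDER = ["EMEG", "EEG", "MEG"]  # positional fallback: pages 1..3, contacts 4
_NUMERIC = DIPOLE_COLUMNS[2:]


def _validate_dipole_frame(df: pd.DataFrame, origin: str) -> pd.DataFrame:
    for col in DIPOLE_COLUMNS:
        if col not in df.columns:
            raise InputError(f"{origin}: missing required column {col!r}")
    df = df[DIPOLE_COLUMNS].copy()
    for col in _NUMERIC:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            raise InputError(
                f"{origin}: non-numeric value in column {col!r} at row {int(bad[0]) + 2}"
            )
        df[col] = coerced
    rv = df["residual_variance"].dropna()
    if len(rv) and ((rv < 0) | (rv > 1)).any():
        row = int(df.index[(df["residual_variance"] < 0) | (df["residual_variance"] > 1)][0]) + 2
        raise InputError(f"{origin}: residual_variance outside [0, 1] at row {row}")
    return df


def read_dipole_table(path, page: str = "EMEG") -> pd.DataFrame:
    """Read one modality page of a dipole table (CSV or XLSX)."""
    path = Path(path)
    if page not in PAGE_ORDER:
        raise ConfigurationError(f"page must be one of {PAGE_ORDER}, got {page!r}")
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if path.suffix.lower() in (".xlsx", ".xls"):
        book = pd.read_excel(path, sheet_name=None, engine="openpyxl")
        if page in book:
            df = book[page]
        else:  # positional fallback: page 1 EMEG, 2 EEG, 3 MEG
            names = list(book)
            idx = PAGE_ORDER.index(page)
            if idx >= len(names):
                raise InputError(f"{path}: no sheet for page {page}")
            df = book[names[idx]]
        if "modality" not in df.columns:
            df = df.assign(modality=page)
    else:
        df = pd.read_csv(path)
        if "modality" in df.columns:
            df = df[df["modality"] == page].reset_index(drop=True)
        else:
            df = df.assign(modality=page)
    return _validate_dipole_frame(df, f"{path}[{page}]")


def write_dipole_table(df: pd.DataFrame, path) -> None:
    """Write a dipole table; dialect chosen by the file extension."""
    path = Path(path)
    out = df.copy()
    for col in DIPOLE_COLUMNS:
        if col not in out.columns:
            raise InputError(f"cannot write dipole table: missing column {col!r}")
    out = out[DIPOLE_COLUMNS]
    if path.suffix.lower() in (".xlsx", ".xls"):
        with pd.ExcelWriter(path, engine="openpyxl") as writer:
            for page in PAGE_ORDER:
                sub = out[out["modality"] == page]
                sub.to_excel(writer, sheet_name=page, index=False)
    else:
        out.to_csv(path, index=False)


def read_contact_table(path, labels_path=None) -> SEEGContactTable:
    """Read an sEEG contact table (CSV, or page 4 of the XLSX dialect).

    ``labels_path`` supplies activity labels from a sidecar CSV
    (electrode_name, contact_number, label) when the main file has none;
    contacts without a label default to "inactive".
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        book = pd.read_excel(path, sheet_name=None, engine="openpyxl")
        if "contacts" in book:
            df = book["contacts"]
        else:
            names = list(book)
            if len(names) < 4:
                raise InputError(f"{path}: no contacts page (expected page 4)")
            df = book[names[3]]
    else:
        df = pd.read_csv(path)
    for col in CONTACT_COLUMNS[:5]:
        if col not in df.columns:
            raise InputError(f"{path}: missing required column {col!r}")
    if "label" not in df.columns:
        df = df.assign(label="inactive")
    df["label"] = df["label"].fillna("inactive")
    if labels_path is not None:
        side = pd.read_csv(labels_path)
        key = ["electrode_name", "contact_number"]
        df = df.drop(columns="label").merge(side[key + ["label"]], on=key, how="left")
        df["label"] = df["label"].fillna("inactive")
    dup = df.duplicated(subset=["electrode_name", "contact_number"])
    if dup.any():
        raise InputError(f"{path}: duplicate contact at row {int(df.index[dup][0]) + 2}")
    bad = df[~df["label"].isin(["ictal", "interictal", "inactive"])]
    if len(bad):
        raise InputError(f"{path}: unknown label {bad['label'].iloc[0]!r}")
    return SEEGContactTable(
        electrode_names=df["electrode_name"].astype(str).tolist(),
        contact_numbers=df["contact_number"].astype(int).tolist(),
        positions=df[["x_mm", "y_mm", "z_mm"]].to_numpy(float),
        labels=df["label"].tolist(),
    )


def write_contact_table(contacts: SEEGContactTable, path) -> None:
    df = pd.DataFrame(
        {
            "electrode_name": contacts.electrode_names,
            "contact_number": contacts.contact_numbers,
            "x_mm": contacts.positions[:, 0],
            "y_mm": contacts.positions[:, 1],
            "z_mm": contacts.positions[:, 2],
            "label": contacts.labels,
        }
    )
    df.to_csv(path, index=False)


def save_recording(recording: ContinuousRecording, path) -> None:
    """Persist a recording (data, rate, channel metadata, ground truth) to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=recording.data, compression="gzip", compression_opts=1)
        f.attrs["sfreq"] = recording.sfreq
        f.create_dataset(
            "channel_names", data=np.array(recording.channel_names, dtype="S32")
        )
        f.create_dataset(
            "channel_kinds", data=np.array(recording.channel_kinds, dtype="S8")
        )
        if recording.ground_truth:
            gt = np.array(
                [
                    (e.onset_sample, e.origin_index, e.amplitude_nAm, e.peak_sample, e.lateral_index)
                    for e in recording.ground_truth
                ]
            )
            f.create_dataset("ground_truth", data=gt)


def load_recording(path) -> ContinuousRecording:
    with h5py.File(path, "r") as f:
        events = []
        if "ground_truth" in f:
            for onset, origin, amp, peak, lateral in f["ground_truth"][()]:
                events.append(
                    SpikeEvent(
                        onset_sample=int(onset),
                        origin_index=int(origin),
                        amplitude_nAm=float(amp),
                        peak_sample=int(peak),
                        lateral_index=int(lateral),
                    )
                )
        return ContinuousRecording(
            data=f["data"][()],
            sfreq=float(f.attrs["sfreq"]),
            channel_names=[s.decode() for s in f["channel_names"][()]],
            channel_kinds=[s.decode() for s in f["channel_kinds"][()]],
            ground_truth=events,
        )


def load_config(path) -> dict:
    with open(path) as f:
        cfg = yaml.safe_load(f) or {}
    if not isinstance(cfg, dict):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return cfg


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(cfg, f, sort_keys=True)


def config_hash(cfg: dict) -> str:
    import hashlib

    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]
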