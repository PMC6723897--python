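"""Delimited-text readers and writers for all pipeline artifacts.

Spectra: CSV with the wavenumber grid as header and one row per tablet
(first column tablet_id).  Profiles: CSV with the time grid (min) in the
first column and one column per tablet.  Tablets: one row per tablet with
nominal and true composition, force and role.  Readers validate structure
and report the offending row/column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .preprocess import SpectrumSet
from .synthetic import DesignSetting, TabletRecord

__all__ = [
    "write_spectra_csv", "read_spectra_csv",
    "write_profiles_csv", "read_profiles_csv",
    "write_tablets_csv", "read_tablets_csv",
    "write_json", "read_json",
]


def write_spectra_csv(path: str | Path, s: SpectrumSet) -> None:
    df = pd.DataFrame(s.intensities, columns=[f"{w:g}" for w in s.wavenumbers])
    df.insert(0, "tablet_id", list(s.sample_ids))
    df.to_csv(path, index=False)


def read_spectra_csv(path: str | Path, modality: str = "") -> SpectrumSet:
    df = pd.read_csv(path)
    if df.columns[0] != "tablet_id":
        raise ValueError(f"{path}: first column must be 'tablet_id', got {df.columns[0]!r}")
    try:
        wn = np.array([float(c) for c in df.columns[1:]])
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric wavenumber header: {exc}") from exc
    d = np.diff(wn)
    if wn.size > 1 and not (np.all(d > 0) or np.all(d < 0)):
        bad = int(np.flatnonzero(~(d > 0))[0]) + 1 if np.any(d > 0) else 1
        raise ValueError(f"{path}: wavenumber header not monotone near column "
                         f"{df.columns[1 + bad]!r}")
    vals = df.iloc[:, 1:].to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        for j, col in enumerate(df.columns[1:], start=1):
            if not pd.api.types.is_numeric_dtype(df.iloc[:, j]):
                raise ValueError(f"{path}: non-numeric cell in column {col!r}")
    return SpectrumSet(wavenumbers=wn, intensities=vals.astype(float),
                       sample_ids=tuple(df["tablet_id"].astype(str)),
                       modality=modality, provenance=(f"read({path})",))


def write_profiles_csv(path: str | Path, times: np.ndarray,
                       profiles: np.ndarray, tablet_ids: Sequence[str]) -> None:
    df = pd.DataFrame(np.asarray(profiles, dtype=float).T,
                      columns=list(tablet_ids))
    df.insert(0, "time_min", np.asarray(times, dtype=float))
    df.to_csv(path, index=False)


def read_profiles_csv(path: str | Path) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Returns (times, profiles as tablets x points, tablet_ids)."""
    df = pd.read_csv(path)
    if df.columns[0] != "time_min":
        raise ValueError(f"{path}: first column must be 'time_min', got {df.columns[0]!r}")
    times = df["time_min"].to_numpy(dtype=float)
    if times.size > 1 and not np.all(np.diff(times) > 0):
        raise ValueError(f"{path}: time column must be strictly increasing")
    vals = df.iloc[:, 1:]
    for col in vals.columns:
        if not pd.api.types.is_numeric_dtype(vals[col]):
            raise ValueError(f"{path}: non-numeric cell in column {col!r}")
    return times, vals.to_numpy(dtype=float).T, tuple(vals.columns)


_TABLET_COLS = ["setting_id", "tablet_id", "dr_nominal", "hpmc_nominal",
                "dr_true", "hpmc_true", "force", "role"]


def write_tablets_csv(path: str | Path, tablets: Sequence[TabletRecord]) -> None:
    rows = [{
        "setting_id": tb.setting.setting_id,
        "tablet_id": tb.tablet_id,
        "dr_nominal": tb.setting.dr_nominal,
        "hpmc_nominal": tb.setting.hpmc_nominal,
        "dr_true": tb.dr_true,
        "hpmc_true": tb.hpmc_true,
        "force": tb.force_measured,
        "role": tb.setting.role,
        "origin": tb.setting.origin,
        "force_nominal": tb.setting.force,
    } for tb in tablets]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tablets_csv(path: str | Path) -> list[TabletRecord]:
    df = pd.read_csv(path)
    missing = [c for c in _TABLET_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    tablets = []
    for i, row in df.iterrows():
        if row["role"] not in ("train", "test"):
            raise ValueError(f"{path}: row {i}: role must be train/test")
        setting = DesignSetting(
            setting_id=int(row["setting_id"]),
            dr_nominal=float(row["dr_nominal"]),
            hpmc_nominal=float(row["hpmc_nominal"]),
            force=float(row.get("force_nominal", row["force"])),
            role=str(row["role"]),
            origin=str(row.get("origin", "factorial")),
        )
        tablets.append(TabletRecord(
            tablet_id=str(row["tablet_id"]), setting=setting,
            dr_true=float(row["dr_true"]), hpmc_true=float(row["hpmc_true"]),
            force_measured=float(row["force"])))
    return tablets


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
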