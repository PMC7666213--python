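"""Reading and writing localization tables.

Two dialects, both lossless for every column plus metadata:

* HDF5 (``.h5`` / ``.hdf5``): one group per round, one dataset per
  column, metadata as JSON in a group attribute.
* CSV (``.csv``): one file per round, metadata as ``# key: json``
  comment lines before the header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd

from .simulate import LOC_COLUMNS, LocalizationTable

__all__ = [
    "LocalizationIOError",
    "write_localizations",
    "read_localizations",
    "write_experiment",
    "read_experiment",
]

_FLOAT_COLUMNS = [c for c in LOC_COLUMNS if c not in ("frame", "round")]


class LocalizationIOError(ValueError):
    """A localization file is malformed; the message names the field."""


def _validate(df: pd.DataFrame, path) -> pd.DataFrame:
    for col in LOC_COLUMNS:
        if col not in df.columns:
            raise LocalizationIOError(f"{path}: missing column {col!r}")
    try:
        df["frame"] = df["frame"].astype(np.int64)
        for col in _FLOAT_COLUMNS:
            df[col] = df[col].astype(np.float64)
    except (TypeError, ValueError) as exc:
        raise LocalizationIOError(f"{path}: non-numeric values ({exc})") from None
    df["round"] = df["round"].astype(str)
    return df[LOC_COLUMNS]


def write_localizations(table: LocalizationTable, path) -> None:
    """Write one table; the dialect is chosen from the file suffix."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            _write_h5_group(fh, table.metadata.get("round", "R1"), table)
    elif path.suffix == ".csv":
        _write_csv(table, path)
    else:
        raise LocalizationIOError(f"unsupported suffix {path.suffix!r} (use .h5/.hdf5/.csv)")


def read_localizations(path) -> LocalizationTable:
    """Read one table written by :func:`write_localizations`."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as fh:
            groups = list(fh.keys())
            if len(groups) != 1:
                raise LocalizationIOError(
                    f"{path}: expected one round group, found {groups}"
                )
            return _read_h5_group(fh[groups[0]], path)
    if path.suffix == ".csv":
        return _read_csv(path)
    raise LocalizationIOError(f"unsupported suffix {path.suffix!r} (use .h5/.hdf5/.csv)")


def write_experiment(tables: Mapping[str, LocalizationTable], path) -> list[Path]:
    """Write a multi-round experiment.

    For HDF5 all rounds go into one file (one group per round); for CSV
    one file per round is written next to ``path`` with the round id
    appended to the stem.  Returns the paths written.
    """
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            for round_id, table in tables.items():
                _write_h5_group(fh, round_id, table)
        return [path]
    if path.suffix == ".csv":
        written = []
        for round_id, table in tables.items():
            p = path.with_name(f"{path.stem}_{round_id}.csv")
            _write_csv(table, p)
            written.append(p)
        return written
    raise LocalizationIOError(f"unsupported suffix {path.suffix!r}")


def read_experiment(path) -> dict[str, LocalizationTable]:
    """Read a multi-round HDF5 experiment file."""
    path = Path(path)
    out: dict[str, LocalizationTable] = {}
    with h5py.File(path, "r") as fh:
        for round_id in fh.keys():
            out[round_id] = _read_h5_group(fh[round_id], path)
    return out


def _write_h5_group(fh: h5py.File, name: str, table: LocalizationTable) -> None:
    g = fh.create_group(str(name))
    df = table.df
    g.create_dataset("frame", data=df["frame"].to_numpy(np.int64))
    g.create_dataset("round", data=np.array(df["round"].astype(str), dtype="S32"))
    for col in _FLOAT_COLUMNS:
        g.create_dataset(col, data=df[col].to_numpy(np.float64))
    g.attrs["metadata"] = json.dumps(table.metadata, sort_keys=True, default=str)


def _read_h5_group(g, path) -> LocalizationTable:
    data = {}
    for col in LOC_COLUMNS:
        if col not in g:
            raise LocalizationIOError(f"{path}: missing column {col!r}")
        values = g[col][()]
        if col == "round":
            values = np.array([v.decode() for v in values])
        data[col] = values
    meta = json.loads(g.attrs.get("metadata", "{}"))
    return LocalizationTable(_validate(pd.DataFrame(data), path), meta)


def _write_csv(table: LocalizationTable, path: Path) -> None:
    with open(path, "w") as fh:
        for key in sorted(table.metadata):
            fh.write(f"# {key}: {json.dumps(table.metadata[key], default=str)}\n")
        table.df.to_csv(fh, index=False, float_format="%.17g")


def _read_csv(path: Path) -> LocalizationTable:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            pos = fh.tell()
            key, _, raw = line[1:].partition(":")
            try:
                meta[key.strip()] = json.loads(raw.strip())
            except json.JSONDecodeError:
                meta[key.strip()] = raw.strip()
        try:
            df = pd.read_csv(fh, float_precision="round_trip")
        except pd.errors.EmptyDataError:
            raise LocalizationIOError(f"{path}: no header row") from None
    return LocalizationTable(_validate(df, path), meta)
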