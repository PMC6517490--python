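"""Spike-event tables: the lingua franca between all modules.

An event table is a pandas DataFrame with columns ``time_ms`` (float),
``channel`` (int; electrode index or neuron id) and ``source_tag``
(one of culture/hardware/background/stimulus), sorted by time.
Tables are read and written as CSV or HDF5 (h5py).
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "SOURCE_TAGS",
    "event_table",
    "empty_table",
    "concat_tables",
    "validate_table",
    "read_csv",
    "write_csv",
    "read_hdf5",
    "write_hdf5",
]

SOURCE_TAGS = ("culture", "hardware", "background", "stimulus")
COLUMNS = ["time_ms", "channel", "source_tag"]


def event_table(times_ms, channels, source_tag: str = "culture") -> pd.DataFrame:
    """Build a sorted event table from parallel arrays."""
    df = pd.DataFrame({
        "time_ms": np.asarray(times_ms, dtype=float),
        "channel": np.asarray(channels, dtype=np.int64),
        "source_tag": source_tag,
    })
    return df.sort_values("time_ms", kind="stable", ignore_index=True)


def empty_table() -> pd.DataFrame:
    return pd.DataFrame({"time_ms": pd.Series(dtype=float),
                         "channel": pd.Series(dtype=np.int64),
                         "source_tag": pd.Series(dtype=object)})


def concat_tables(tables) -> pd.DataFrame:
    tables = [t for t in tables if len(t)]
    if not tables:
        return empty_table()
    df = pd.concat(tables, ignore_index=True)
    return df.sort_values("time_ms", kind="stable", ignore_index=True)


def validate_table(df: pd.DataFrame) -> pd.DataFrame:
    if list(df.columns[:3]) != COLUMNS and not set(COLUMNS) <= set(df.columns):
        raise ValueError(f"event table requires columns {COLUMNS}")
    t = df["time_ms"].to_numpy()
    if len(t) and (t[0] < 0 or np.any(np.diff(t) < 0)):
        raise ValueError("event times must be >= 0 and non-decreasing")
    return df


def write_csv(df: pd.DataFrame, path) -> None:
    validate_table(df).to_csv(path, index=False)


def read_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["channel"] = df["channel"].astype(np.int64)
    return validate_table(df)


def write_hdf5(df: pd.DataFrame, path, group: str = "events") -> None:
    validate_table(df)
    with h5py.File(path, "a") as fh:
        if group in fh:
            del fh[group]
        g = fh.create_group(group)
        g.create_dataset("time_ms", data=df["time_ms"].to_numpy(float))
        g.create_dataset("channel", data=df["channel"].to_numpy(np.int64))
        tags = df["source_tag"].astype(str).to_numpy()
        g.create_dataset("source_tag",
                         data=np.array(tags, dtype=h5py.string_dtype()))


def read_hdf5(path, group: str = "events") -> pd.DataFrame:
    with h5py.File(path, "r") as fh:
        g = fh[group]
        tags = [t.decode() if isinstance(t, bytes) else str(t)
                for t in g["source_tag"][()]]
        df = pd.DataFrame({
            "time_ms": g["time_ms"][()].astype(float),
            "channel": g["channel"][()].astype(np.int64),
            "source_tag": tags,
        })
    return validate_table(df)
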