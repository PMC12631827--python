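"""Readers and writers for the pipeline's on-disk formats.

Epochs and trial-pattern matrices travel as HDF5; behavioral and
per-subject tables as CSV with a header; results as JSON.  Loaders
re-assert the container invariants and raise :class:`SchemaError` with
field-level diagnostics instead of propagating raw h5py/pandas failures.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochedEEG, TrialBetaMatrix

__all__ = [
    "SchemaError",
    "save_epochs",
    "load_epochs",
    "save_trials",
    "load_trials",
    "load_curve",
    "write_json",
]


class SchemaError(ValueError):
    """An on-disk file does not match the expected schema."""


def save_epochs(epochs: EpochedEEG, path: str | Path) -> None:
    """Write epochs: datasets ``data`` [trial, channel, sample] and
    ``channel_names``, attributes ``fs_hz`` and ``t0_s``."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset(
            "channel_names", data=np.array(epochs.channel_names, dtype=h5py.string_dtype())
        )
        f.attrs["fs_hz"] = epochs.fs_hz
        f.attrs["t0_s"] = epochs.t0_s


def load_epochs(path: str | Path) -> EpochedEEG:
    try:
        with h5py.File(path, "r") as f:
            for name in ("data", "channel_names"):
                if name not in f:
                    raise SchemaError(f"{path}: missing dataset {name!r}")
            for attr in ("fs_hz",):
                if attr not in f.attrs:
                    raise SchemaError(f"{path}: missing attribute {attr!r}")
            data = f["data"][()]
            names = tuple(s.decode() if isinstance(s, bytes) else str(s) for s in f["channel_names"][()])
            fs = float(f.attrs["fs_hz"])
            t0 = float(f.attrs.get("t0_s", 0.0))
    except OSError as e:
        raise SchemaError(f"{path}: not a readable HDF5 file ({e})") from e
    try:
        return EpochedEEG(data=data, channel_names=names, fs_hz=fs, t0_s=t0)
    except ValueError as e:
        raise SchemaError(f"{path}: {e}") from e


def save_trials(trials: TrialBetaMatrix, path: str | Path) -> None:
    """Write a trial-pattern matrix: ``patterns``, ``condition``, ``run``,
    and one dataset per rating under the ``ratings/`` group."""
    with h5py.File(path, "w") as f:
        f.create_dataset("patterns", data=trials.patterns)
        f.create_dataset(
            "condition", data=np.array([str(c) for c in trials.condition], dtype=h5py.string_dtype())
        )
        f.create_dataset("run", data=trials.run)
        grp = f.create_group("ratings")
        for name, vals in trials.ratings.items():
            grp.create_dataset(name, data=vals)


def load_trials(path: str | Path) -> TrialBetaMatrix:
    try:
        with h5py.File(path, "r") as f:
            for name in ("patterns", "condition", "run"):
                if name not in f:
                    raise SchemaError(f"{path}: missing dataset {name!r}")
            patterns = f["patterns"][()]
            condition = np.array(
                [s.decode() if isinstance(s, bytes) else str(s) for s in f["condition"][()]]
            )
            run = f["run"][()]
            ratings = {}
            if "ratings" in f:
                for name in f["ratings"]:
                    ratings[name] = f["ratings"][name][()]
    except OSError as e:
        raise SchemaError(f"{path}: not a readable HDF5 file ({e})") from e
    try:
        return TrialBetaMatrix(patterns=patterns, condition=condition, run=run, ratings=ratings)
    except ValueError as e:
        raise SchemaError(f"{path}: {e}") from e


def load_curve(path: str | Path, column: str | None = None) -> np.ndarray:
    """Read a 1D curve from a one-column (or named-column) CSV."""
    df = pd.read_csv(path)
    if df.shape[1] == 0:
        raise SchemaError(f"{path}: empty CSV")
    if column is None:
        if df.shape[1] != 1:
            raise SchemaError(
                f"{path}: expected a single column, found {list(df.columns)}; pass column="
            )
        column = df.columns[0]
    elif column not in df.columns:
        raise SchemaError(f"{path}: no column {column!r}; found {list(df.columns)}")
    vals = df[column].to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise SchemaError(f"{path}: column {column!r} contains non-finite values")
    return vals


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON dump (sorted keys, fixed separators, trailing newline)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.bool_,)):
            return bool(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(
        json.dumps(obj, sort_keys=True, indent=2, default=default) + "\n"
    )
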