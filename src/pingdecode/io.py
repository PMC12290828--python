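"""HDF5 / CSV / JSON persistence.

Canonical epochs layout (one HDF5 file per participant and lock):

    /data      float32, trial x channel x time (µV)
    /times     float64, ms
    /channels  utf-8 strings
    /metadata/<column>  one dataset per trial-table column
    root attrs: sfreq, lock, seed (-1 when unseeded), metadata_columns

Features are stored under /features with the analogous axes. Configs
round-trip through JSON (or YAML) via their dataclass dicts.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import EpochedEEG, FeatureSeries

__all__ = ["write_epochs", "read_epochs", "write_features", "read_features",
           "write_decoding", "read_decoding", "save_config", "load_config"]

_STR = h5py.string_dtype(encoding="utf-8")


def _write_metadata(group: h5py.Group, df: pd.DataFrame) -> None:
    for col in df.columns:
        values = df[col]
        if values.dtype == object or pd.api.types.is_string_dtype(values):
            group.create_dataset(col, data=values.astype(str).to_numpy(dtype=object),
                                 dtype=_STR)
            group[col].attrs["pandas_dtype"] = "str"
        elif pd.api.types.is_bool_dtype(values):
            group.create_dataset(col, data=values.to_numpy(dtype=np.uint8))
            group[col].attrs["pandas_dtype"] = "bool"
        else:
            group.create_dataset(col, data=values.to_numpy())
            group[col].attrs["pandas_dtype"] = str(values.dtype)


def _read_metadata(group: h5py.Group, columns) -> pd.DataFrame:
    out = {}
    for col in columns:
        ds = group[col]
        kind = ds.attrs.get("pandas_dtype", "")
        if kind == "str":
            out[col] = [v.decode() if isinstance(v, bytes) else str(v) for v in ds[()]]
        elif kind == "bool":
            out[col] = ds[()].astype(bool)
        else:
            out[col] = ds[()]
    return pd.DataFrame(out, columns=list(columns))


def write_epochs(epochs: EpochedEEG, path) -> None:
    """Write an :class:`EpochedEEG` to the canonical HDF5 layout."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("times", data=epochs.times.astype(np.float64))
        f.create_dataset("channels", data=np.array(epochs.ch_names, dtype=object),
                         dtype=_STR)
        _write_metadata(f.create_group("metadata"), epochs.metadata)
        f.attrs["sfreq"] = float(epochs.sfreq)
        f.attrs["lock"] = epochs.lock
        f.attrs["seed"] = -1 if epochs.seed is None else int(epochs.seed)
        f.attrs["metadata_columns"] = list(epochs.metadata.columns)


def read_epochs(path) -> EpochedEEG:
    """Read an :class:`EpochedEEG`; missing datasets raise a named error."""
    with h5py.File(path, "r") as f:
        for name in ("data", "times", "channels", "metadata"):
            if name not in f:
                raise ValueError(f"malformed epochs file {path}: missing /{name}")
        meta = _read_metadata(f["metadata"], f.attrs["metadata_columns"])
        seed = int(f.attrs["seed"])
        return EpochedEEG(
            f["data"][()], f["times"][()], float(f.attrs["sfreq"]),
            [c.decode() if isinstance(c, bytes) else str(c) for c in f["channels"][()]],
            meta, str(f.attrs["lock"]), None if seed == -1 else seed,
        )


def write_features(fs: FeatureSeries, path) -> None:
    with h5py.File(path, "w") as f:
        g = f.create_group("features")
        g.create_dataset("values", data=fs.values)
        g.create_dataset("window_times", data=fs.window_times)
        g.create_dataset("feature_names", data=np.array(fs.feature_names, dtype=object),
                         dtype=_STR)
        g.attrs["provenance"] = fs.provenance
        if fs.metadata is not None:
            _write_metadata(g.create_group("metadata"), fs.metadata)
            g.attrs["metadata_columns"] = list(fs.metadata.columns)


def read_features(path) -> FeatureSeries:
    with h5py.File(path, "r") as f:
        if "features" not in f:
            raise ValueError(f"malformed features file {path}: missing /features")
        g = f["features"]
        meta = None
        if "metadata" in g:
            meta = _read_metadata(g["metadata"], g.attrs["metadata_columns"])
        return FeatureSeries(
            g["values"][()], g["window_times"][()],
            [c.decode() if isinstance(c, bytes) else str(c)
             for c in g["feature_names"][()]],
            str(g.attrs["provenance"]), meta,
        )


def write_decoding(tc, path) -> None:
    """Write a :class:`DecodingTimecourse` (datasets under /decoding)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("decoding")
        g.create_dataset("times", data=tc.window_times)
        g.create_dataset("empirical", data=tc.empirical)
        if tc.shuffled is not None:
            g.create_dataset("shuffled", data=tc.shuffled)
        g.attrs["metric"] = tc.metric
        g.attrs["chance"] = float(tc.chance)
        g.attrs["n_classes"] = int(tc.n_classes)


def read_decoding(path):
    from .containers import DecodingTimecourse

    with h5py.File(path, "r") as f:
        if "decoding" not in f:
            raise ValueError(f"malformed decoding file {path}: missing /decoding")
        g = f["decoding"]
        shuffled = g["shuffled"][()] if "shuffled" in g else None
        return DecodingTimecourse(g["times"][()], g["empirical"][()], shuffled,
                                  str(g.attrs["metric"]), float(g.attrs["chance"]),
                                  int(g.attrs["n_classes"]))


def save_config(config, path) -> None:
    """Serialise a config dataclass (or plain dict) to JSON or YAML by suffix."""
    if dataclasses.is_dataclass(config) and not isinstance(config, type):
        d = config.to_dict() if hasattr(config, "to_dict") else dataclasses.asdict(config)
    else:
        d = dict(config)
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=2))


def load_config(path) -> dict:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)
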