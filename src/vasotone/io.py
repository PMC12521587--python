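"""Readers and writers for recordings, traces, and run configuration.

Two containers are supported for multichannel recordings:

* **delimited text** (``.csv``/``.tsv``): a time column in seconds plus one
  column per channel (``ch01..``) in μV, written at a documented precision of
  1e-6 μV, with a JSON sidecar (``<file>.meta.json``) carrying the sampling
  rate, channel mask, grid coordinates and free-form metadata;
* **HDF5** (``.h5``): lossless binary container for large simulations.

Round trips preserve sample count, channel order, sampling rate and mask.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .recording import MultichannelRecording
from .stiffness import HemodynamicTrace

__all__ = [
    "FormatError",
    "read_recording",
    "write_recording",
    "read_trace",
    "write_trace",
    "RunConfig",
    "data_digest",
]

CSV_PRECISION = 6  # decimal places (μV) kept by the delimited-text container


class FormatError(ValueError):
    """Raised on container/shape/unit mismatches during read or write."""


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt in ("delimited", "txt"):
            fmt = "csv"
        if fmt not in ("csv", "tsv", "h5"):
            raise FormatError(
                f"unsupported format {fmt!r}; supported: csv, tsv, h5"
            )
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("csv", "tsv"):
        return suffix
    if suffix in ("h5", "hdf5"):
        return "h5"
    raise FormatError(
        f"cannot infer container from suffix {path.suffix!r}; supported: csv, tsv, h5"
    )


def _meta_path(path: Path) -> Path:
    return path.with_name(path.name + ".meta.json")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_recording(
    rec: MultichannelRecording, path: str | Path, fmt: str | None = None
) -> Path:
    """Write a recording; returns the path written.

    Delimited text is lossless at :data:`CSV_PRECISION` decimal places; HDF5
    is exact.  The channel mask and metadata travel in the JSON sidecar (csv)
    or in attributes (h5).
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    meta = {
        "fs": rec.fs,
        "channel_ids": rec.channel_ids,
        "coords": [list(rc) for rc in rec.coords],
        "mask": rec.mask.astype(int).tolist(),
        "metadata": _jsonable(rec.metadata),
    }
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.DataFrame(rec.data.T, columns=rec.channel_ids)
        df.insert(0, "time", rec.times)
        df.to_csv(path, sep=sep, index=False, float_format=f"%.{CSV_PRECISION}f")
        _meta_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    else:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=rec.data)
            f.attrs["fs"] = rec.fs
            f.attrs["meta_json"] = json.dumps(meta, sort_keys=True)
    return path


def read_recording(
    path: str | Path, fmt: str | None = None, fs: float | None = None
) -> MultichannelRecording:
    """Read a recording written by :func:`write_recording`.

    For delimited text without a sidecar, ``fs`` must be given and is checked
    against the file's time column; a declared rate inconsistent with the
    container is a format error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, fmt)
    if fmt == "h5":
        import h5py

        with h5py.File(path, "r") as f:
            data = f["data"][()]
            meta = json.loads(f.attrs["meta_json"])
    else:
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep)
        if "time" not in df.columns:
            raise FormatError(f"{path}: missing required column 'time'")
        meta_file = _meta_path(path)
        meta = json.loads(meta_file.read_text()) if meta_file.exists() else None
        if meta is not None:
            missing = [c for c in meta["channel_ids"] if c not in df.columns]
            if missing:
                raise FormatError(
                    f"{path}: missing channel column(s) {missing}; file has "
                    f"{len(df.columns) - 1} channel columns"
                )
            chan_cols = meta["channel_ids"]
        else:
            chan_cols = [c for c in df.columns if c != "time"]
        data = df[chan_cols].to_numpy(dtype=float).T
        t = df["time"].to_numpy(dtype=float)
        fs_file = 1.0 / np.median(np.diff(t)) if t.size > 1 else None
        if meta is None:
            if fs is None:
                fs = fs_file
            meta = {
                "fs": fs,
                "channel_ids": chan_cols,
                "coords": None,
                "mask": [1] * len(chan_cols),
                "metadata": {},
            }
        if fs_file is not None and meta["fs"] is not None:
            if abs(fs_file - meta["fs"]) / meta["fs"] > 0.01:
                raise FormatError(
                    f"{path}: time column implies fs≈{fs_file:.3f} Hz but "
                    f"declared fs is {meta['fs']} Hz"
                )
    if fs is not None and abs(fs - meta["fs"]) / meta["fs"] > 0.01:
        raise FormatError(
            f"{path}: declared fs {fs} Hz disagrees with container fs {meta['fs']} Hz"
        )
    coords = (
        [tuple(rc) for rc in meta["coords"]] if meta.get("coords") else None
    )
    return MultichannelRecording(
        data=np.asarray(data, dtype=float),
        fs=float(meta["fs"]),
        channel_ids=list(meta["channel_ids"]),
        coords=coords,
        mask=np.asarray(meta["mask"], dtype=bool),
        metadata=meta.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# hemodynamic traces
# ---------------------------------------------------------------------------


def write_trace(trace: HemodynamicTrace, path: str | Path) -> Path:
    """Delimited-text diameter trace (time s, diameter mm) + JSON sidecar with
    the pressures."""
    path = Path(path)
    t = np.arange(trace.diameter.size) / trace.fs
    pd.DataFrame({"time": t, "diameter": trace.diameter}).to_csv(
        path, index=False, float_format="%.6f"
    )
    meta = {
        "fs": trace.fs,
        "Ps": trace.Ps,
        "Pd": trace.Pd,
        "heart_rate": trace.heart_rate,
        "metadata": _jsonable(trace.metadata),
    }
    _meta_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True))
    return path


def read_trace(
    path: str | Path, Ps: float | None = None, Pd: float | None = None
) -> HemodynamicTrace:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time", "diameter"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    meta_file = _meta_path(path)
    meta = json.loads(meta_file.read_text()) if meta_file.exists() else {}
    t = df["time"].to_numpy(dtype=float)
    fs = meta.get("fs") or (1.0 / np.median(np.diff(t)))
    Ps = Ps if Ps is not None else meta.get("Ps")
    Pd = Pd if Pd is not None else meta.get("Pd")
    if Ps is None or Pd is None:
        raise FormatError(f"{path}: systolic/diastolic pressures not provided")
    return HemodynamicTrace(
        diameter=df["diameter"].to_numpy(dtype=float),
        fs=float(fs),
        Ps=float(Ps),
        Pd=float(Pd),
        heart_rate=meta.get("heart_rate"),
        metadata=meta.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; unknown keys are rejected.

    Each section mirrors the defaults of the corresponding stage; every run
    writes an echo of the resolved config next to its outputs.
    """

    seed: int = 0
    out_dir: str = "vasotone_run"
    simulate: dict = field(default_factory=dict)  # GenConfig overrides + 'state'
    preprocess: dict = field(default_factory=dict)
    features: dict = field(default_factory=dict)
    embed: dict = field(default_factory=dict)
    stiffness: dict = field(default_factory=dict)
    closedloop: dict = field(default_factory=dict)
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as f:
            d = yaml.safe_load(f) or {}
        return cls.from_dict(d)

    def echo(self, out_dir: str | Path) -> Path:
        out = Path(out_dir) / "config_echo.yaml"
        out.parent.mkdir(parents=True, exist_ok=True)
        out.write_text(yaml.safe_dump(asdict(self), sort_keys=True))
        return out


def data_digest(arr: np.ndarray) -> str:
    """Stable content digest of an array, for run logs."""
    return hashlib.sha256(np.ascontiguousarray(arr).tobytes()).hexdigest()[:16]
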