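"""Reading and writing the pipeline's file formats.

Movies and gated FLIM stacks travel as multi-page TIFF (via tifffile),
tracks and detections as CSV, configs and fit results as JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .flim import DecayStack

__all__ = [
    "write_movie_tiff",
    "read_movie_tiff",
    "write_flim_tiff",
    "read_flim_tiff",
    "write_tracks_csv",
    "read_tracks_csv",
    "write_json",
    "read_json",
]


def write_movie_tiff(path, movie: np.ndarray) -> None:
    """Multi-page float32 TIFF, one page per frame."""
    tifffile.imwrite(str(path), np.asarray(movie, dtype=np.float32))


def read_movie_tiff(path) -> np.ndarray:
    movie = tifffile.imread(str(path)).astype(float)
    if movie.ndim == 2:
        movie = movie[None]
    return movie


def write_flim_tiff(path, stack: DecayStack, meta_path=None) -> None:
    """Gated stack as multi-page TIFF plus a JSON gate-time sidecar."""
    tifffile.imwrite(str(path), stack.gates.astype(np.float32))
    if meta_path is None:
        meta_path = Path(str(path)).with_suffix(".json")
    write_json(meta_path, {"gate_times_ns": list(map(float, stack.gate_times_ns))})


def read_flim_tiff(path, meta_path=None) -> DecayStack:
    gates = tifffile.imread(str(path)).astype(float)
    if meta_path is None:
        meta_path = Path(str(path)).with_suffix(".json")
    meta = read_json(meta_path)
    return DecayStack(gates=gates, gate_times_ns=np.asarray(meta["gate_times_ns"]))


def write_tracks_csv(path, tracks: pd.DataFrame) -> None:
    tracks.to_csv(str(path), index=False, float_format="%.6g")


def read_tracks_csv(path) -> pd.DataFrame:
    return pd.read_csv(str(path))


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json(path, obj) -> None:
    with open(str(path), "w") as fh:
        json.dump(_jsonable(obj), fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path):
    with open(str(path)) as fh:
        return json.load(fh)
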