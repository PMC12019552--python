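"""Readers and writers for the pipeline's on-disk formats.

Localization tables and per-track/estimate tables travel as CSV (floats at 9
significant digits so reruns are byte-identical), image stacks as multi-page
TIFF (tifffile), configurations as YAML.  A column-mapping hook lets the
localization reader ingest TrackMate-style spot exports.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .detect_link import Track, TrackSet
from .simulate import LOC_COLUMNS

FLOAT_FMT = "%.9g"


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_localizations(path, column_map: dict[str, str] | None = None
                       ) -> pd.DataFrame:
    """Read a localization CSV, optionally renaming foreign columns.

    ``column_map`` maps source column names to the canonical
    ``frame,x_um,y_um,intensity,sigma_um,molecule_id`` schema (e.g. a
    TrackMate export's ``FRAME -> frame, POSITION_X -> x_um`` ...).  Missing
    intensity/sigma columns default to 1 and 0; missing molecule ids to -1.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    for col, default in (("intensity", 1.0), ("sigma_um", 0.0),
                         ("molecule_id", -1)):
        if col not in df.columns:
            df[col] = default
    missing = [c for c in ("frame", "x_um", "y_um") if c not in df.columns]
    if missing:
        raise ValueError(f"localization table missing columns: {missing}")
    return df[LOC_COLUMNS].astype({"frame": np.int64, "molecule_id": np.int64})


def write_localizations(df: pd.DataFrame, path) -> None:
    write_csv(df[LOC_COLUMNS], path)


def write_tracks(tracks: TrackSet, csv_path, meta_path=None) -> None:
    """Tracks as long CSV `track_id,frame,x_um,y_um` + JSON metadata sidecar."""
    write_csv(tracks.to_frame(), csv_path)
    if meta_path is not None:
        meta = [{"track_id": t.track_id, "n_steps": t.n_steps,
                 "gap_frames": t.gap_frames} for t in tracks]
        Path(meta_path).write_text(json.dumps(meta, indent=1))


def read_tracks(csv_path, meta_path=None) -> TrackSet:
    df = pd.read_csv(csv_path)
    gaps: dict[int, list[int]] = {}
    if meta_path is not None and Path(meta_path).exists():
        for m in json.loads(Path(meta_path).read_text()):
            gaps[int(m["track_id"])] = list(m["gap_frames"])
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        grp = grp.sort_values("frame").reset_index(drop=True)
        members = grp[["frame", "x_um", "y_um"]].copy()
        members["intensity"] = 1.0
        members["sigma_um"] = 0.0
        members["molecule_id"] = -1
        tracks.append(Track(track_id=int(tid), members=members,
                            gap_frames=gaps.get(int(tid), [])))
    return TrackSet(tracks)


def write_stack(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32))


def read_stack(path) -> np.ndarray:
    arr = tifffile.imread(path).astype(float)
    if np.any(arr < 0):
        arr = np.clip(arr, 0, None)
    return arr if arr.ndim == 3 else arr[None]


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=True)


def config_hash(obj: dict) -> str:
    """Stable short hash of a config mapping (canonical YAML, sha256)."""
    canon = yaml.safe_dump(obj, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
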