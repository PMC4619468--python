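"""Reading and writing skeleton-CSV recordings.

Two plain-text dialects are supported, both with a JSON metadata sidecar
(``<stem>.json``) carrying fps, subject id, group label and the coordinate
unit:

long
    one row per joint per frame: ``segment,frame,time_s,joint_id,x,y,z``
wide
    one row per frame: ``segment,frame,time_s`` followed by 60 coordinate
    columns ``j01_x, j01_y, j01_z, ..., j20_z``

Coordinates are metres on disk unless the sidecar (or the ``unit``
argument) says ``mm``, in which case they are converted on read.  Frames
are ordered by (segment, frame) index; joint ids are 1-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .joints import N_JOINTS
from .skeleton import SkeletonRecording

WIDE_COORD_COLS = [
    f"j{m:02d}_{axis}" for m in range(1, N_JOINTS + 1) for axis in "xyz"
]

_UNIT_SCALE = {"m": 1.0, "mm": 1e-3}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def read_recording(
    path: str | Path,
    dialect: str = "long",
    unit: str | None = None,
) -> SkeletonRecording:
    """Read and validate a skeleton recording from a CSV file.

    Parameters
    ----------
    path
        CSV file in one of the two documented dialects.  A JSON sidecar
        next to it (same stem, ``.json``) supplies fps and labels.
    dialect
        ``"long"`` or ``"wide"``.
    unit
        ``"m"`` or ``"mm"``.  Overrides the sidecar; defaults to metres.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    unit = unit or meta.get("unit", "m")
    if unit not in _UNIT_SCALE:
        raise ValueError(f"unknown unit {unit!r}; expected 'm' or 'mm'")
    scale = _UNIT_SCALE[unit]

    df = pd.read_csv(path)
    if dialect == "long":
        segments, frame_indices = _parse_long(df, path)
    elif dialect == "wide":
        segments, frame_indices = _parse_wide(df, path)
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")

    segments = [s * scale for s in segments]
    return SkeletonRecording(
        segments=segments,
        frame_indices=frame_indices,
        fps=float(meta.get("fps", 30.0)),
        subject_id=str(meta.get("subject_id", path.stem)),
        group_label=meta.get("group_label"),
    )


def _parse_long(df: pd.DataFrame, path: Path):
    required = {"segment", "frame", "joint_id", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    bad = df[(df.joint_id < 1) | (df.joint_id > N_JOINTS)]
    if len(bad):
        row = bad.index[0]
        raise ValueError(
            f"{path}: row {row}: unknown joint_id {int(bad.joint_id.iloc[0])} "
            f"(segment {int(bad.segment.iloc[0])}, frame {int(bad.frame.iloc[0])})"
        )
    segments, frame_indices = [], []
    for k, seg_df in df.groupby("segment", sort=True):
        frames = []
        idx = []
        for j, frame_df in seg_df.groupby("frame", sort=True):
            ids = np.sort(frame_df.joint_id.to_numpy())
            if len(ids) != N_JOINTS or not np.array_equal(
                ids, np.arange(1, N_JOINTS + 1)
            ):
                raise ValueError(
                    f"{path}: segment {k}, frame {j}: expected all "
                    f"{N_JOINTS} joints exactly once, got {len(frame_df)} rows"
                )
            ordered = frame_df.sort_values("joint_id")
            frames.append(ordered[["x", "y", "z"]].to_numpy(dtype=float))
            idx.append(int(j))
        if np.any(np.diff(idx) <= 0):
            raise ValueError(f"{path}: segment {k}: non-monotone frame indices")
        segments.append(np.stack(frames))
        frame_indices.append(np.asarray(idx))
    return segments, frame_indices


def _parse_wide(df: pd.DataFrame, path: Path):
    missing = [c for c in ["segment", "frame", *WIDE_COORD_COLS] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing[:5]}...")
    segments, frame_indices = [], []
    for k, seg_df in df.groupby("segment", sort=True):
        seg_df = seg_df.sort_values("frame")
        idx = seg_df.frame.to_numpy(dtype=int)
        if np.any(np.diff(idx) <= 0):
            raise ValueError(f"{path}: segment {k}: non-monotone frame indices")
        coords = seg_df[WIDE_COORD_COLS].to_numpy(dtype=float)
        if np.any(~np.isfinite(coords)):
            j = idx[int(np.argwhere(~np.isfinite(coords).all(axis=1))[0, 0])]
            raise ValueError(
                f"{path}: segment {k}, frame {j}: missing or non-finite joints"
            )
        segments.append(coords.reshape(len(coords), N_JOINTS, 3))
        frame_indices.append(idx)
    return segments, frame_indices


def write_recording(
    rec: SkeletonRecording,
    path: str | Path,
    dialect: str = "long",
) -> Path:
    """Write a recording to CSV (metres) plus its JSON metadata sidecar.

    ``read_recording(write_recording(rec))`` reproduces the recording to
    1e-9 m in either dialect.
    """
    rec.validate()
    path = Path(path)
    rows = []
    if dialect == "long":
        for k, (seg, idx) in enumerate(zip(rec.segments, rec.frame_indices), 1):
            for j, frame in zip(idx, seg):
                for m in range(N_JOINTS):
                    rows.append(
                        (k, int(j), j / rec.fps, m + 1, *frame[m])
                    )
        df = pd.DataFrame(
            rows, columns=["segment", "frame", "time_s", "joint_id", "x", "y", "z"]
        )
    elif dialect == "wide":
        for k, (seg, idx) in enumerate(zip(rec.segments, rec.frame_indices), 1):
            flat = seg.reshape(len(seg), N_JOINTS * 3)
            for j, coords in zip(idx, flat):
                rows.append((k, int(j), j / rec.fps, *coords))
        df = pd.DataFrame(rows, columns=["segment", "frame", "time_s", *WIDE_COORD_COLS])
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'long' or 'wide'")
    df.to_csv(path, index=False, float_format="%.10g")
    meta = {
        "fps": rec.fps,
        "subject_id": rec.subject_id,
        "group_label": rec.group_label,
        "unit": "m",
        "dialect": dialect,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path
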