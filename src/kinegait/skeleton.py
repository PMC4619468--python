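"""In-memory container for skeleton-joint recordings.

A recording holds the 4-D coordinate field T(m, n, j, k): joint m = 1..20,
coordinate n = 1..3 (x right, y up, z depth from the sensor, metres), frame
j within segment, and walk segment k.  Internally each segment is stored as
a float array of shape (J, 20, 3); the 1-based joint convention applies only
at the API surface.

``frame_indices`` keeps the original frame number of every retained frame,
so that wall-clock timing (frame / fps) survives outlier-frame rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .joints import N_JOINTS

GROUP_LABELS = ("PD", "NORM", "STUD")


@dataclass
class SkeletonRecording:
    """Ordered walk segments of per-frame 3-D joint positions (metres)."""

    segments: list[np.ndarray]
    frame_indices: list[np.ndarray] | None = None
    fps: float = 30.0
    subject_id: str = ""
    group_label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.segments = [np.asarray(s, dtype=float) for s in self.segments]
        if self.frame_indices is None:
            self.frame_indices = [np.arange(len(s)) for s in self.segments]
        else:
            self.frame_indices = [
                np.asarray(f, dtype=int) for f in self.frame_indices
            ]
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        if self.fps <= 0:
            raise ValueError(f"fps must be positive, got {self.fps}")
        if not self.segments:
            raise ValueError("recording has no segments")
        if self.group_label is not None and self.group_label not in GROUP_LABELS:
            raise ValueError(f"unknown group label {self.group_label!r}")
        if len(self.frame_indices) != len(self.segments):
            raise ValueError("frame_indices must align with segments")
        for k, (seg, idx) in enumerate(zip(self.segments, self.frame_indices), 1):
            if seg.ndim != 3 or seg.shape[1:] != (N_JOINTS, 3):
                raise ValueError(
                    f"segment {k}: expected shape (J, {N_JOINTS}, 3), "
                    f"got {seg.shape}"
                )
            if len(seg) < 2:
                raise ValueError(f"segment {k}: needs at least 2 frames")
            if not np.all(np.isfinite(seg)):
                j = int(np.argwhere(~np.isfinite(seg).all(axis=(1, 2)))[0, 0])
                raise ValueError(
                    f"segment {k}, frame {j + 1}: non-finite coordinates"
                )
            if len(idx) != len(seg):
                raise ValueError(f"segment {k}: frame index length mismatch")
            if np.any(np.diff(idx) <= 0):
                raise ValueError(f"segment {k}: frame indices not increasing")

    # -- convenience -----------------------------------------------------

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def n_frames(self) -> int:
        return int(sum(len(s) for s in self.segments))

    def joints(self, indices: Sequence[int], segment: int) -> np.ndarray:
        """Positions of 1-based joints ``indices`` in segment (0-based)."""
        idx = np.asarray(indices, dtype=int) - 1
        if np.any(idx < 0) or np.any(idx >= N_JOINTS):
            raise ValueError(f"joint indices out of range 1..{N_JOINTS}")
        return self.segments[segment][:, idx, :]

    def copy(self) -> "SkeletonRecording":
        return replace(
            self,
            segments=[s.copy() for s in self.segments],
            frame_indices=[f.copy() for f in self.frame_indices],
            meta=dict(self.meta),
        )

    def transformed(
        self, rotation: np.ndarray | None = None, translation: Sequence[float] = (0, 0, 0)
    ) -> "SkeletonRecording":
        """Rigidly transform every joint position (rotation then translation)."""
        t = np.asarray(translation, dtype=float)
        out = self.copy()
        for k in range(out.n_segments):
            seg = out.segments[k]
            if rotation is not None:
                seg = seg @ np.asarray(rotation, dtype=float).T
            out.segments[k] = seg + t
        return out
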