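"""Gross-error frame rejection and Savitzky-Golay trajectory smoothing.

The per-frame centre of mass (COM) is the mean position of the three torso
joints (hip centre, spine, shoulder centre).  Sensor glitches displace the
whole skeleton, most visibly in the COM depth coordinate, so frames whose
COM z falls outside a band around the per-segment median are dropped.  The
band half-width is ``k_sd`` times a scale estimate of the COM z values:
by default the normal-consistent MAD (1.4826 * median absolute deviation),
which matches the standard deviation on clean Gaussian data but is not
inflated by the very outliers being screened; ``scale="sd"`` selects the
plain standard deviation instead.

Smoothing uses a Savitzky-Golay FIR filter built from first principles:
the convolution weights realise a local least-squares polynomial fit of
order R over a window of 2*L_w+1 frames, evaluated at the window centre.
Edge frames are handled by shrinking-window fits of the same order so that
segment lengths are preserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .joints import COM_JOINTS
from .skeleton import SkeletonRecording

log = logging.getLogger(__name__)

#: scale factor making the MAD consistent with the SD under normality
MAD_TO_SD = 1.4826022185056018


@dataclass
class COMTrace:
    """Per-frame torso centre-of-mass positions, one array per segment."""

    positions: list[np.ndarray]  # each (J, 3)
    z_median: np.ndarray = field(init=False)
    z_sd: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.z_median = np.array([np.median(p[:, 2]) for p in self.positions])
        self.z_sd = np.array([np.std(p[:, 2]) for p in self.positions])

    def z(self, segment: int) -> np.ndarray:
        return self.positions[segment][:, 2]


def compute_com(
    rec: SkeletonRecording, joints: tuple[int, ...] = COM_JOINTS
) -> COMTrace:
    """Coordinate-wise mean position of the listed 1-based joints per frame."""
    if len(joints) == 0:
        raise ValueError("joint list must not be empty")
    positions = [
        rec.joints(joints, k).mean(axis=1) for k in range(rec.n_segments)
    ]
    return COMTrace(positions=positions)


def reject_outlier_frames(
    trace: COMTrace, k_sd: float = 1.0, scale: str = "mad"
) -> list[np.ndarray]:
    """Boolean retain-mask per segment from the COM z band.

    A frame is removed iff its COM z lies outside
    ``[median - k_sd*scale, median + k_sd*scale]`` where median and scale
    are computed over the segment's COM z values.  A zero scale (constant
    trace) retains every frame.
    """
    if k_sd <= 0:
        raise ValueError(f"k_sd must be positive, got {k_sd}")
    masks = []
    for k, pos in enumerate(trace.positions):
        z = pos[:, 2]
        if len(z) < 3:
            raise ValueError(f"segment {k + 1}: needs >= 3 frames for rejection")
        med = np.median(z)
        if scale == "mad":
            s = MAD_TO_SD * np.median(np.abs(z - med))
        elif scale == "sd":
            s = float(np.std(z))
        else:
            raise ValueError(f"unknown scale estimator {scale!r}")
        if s == 0.0:
            log.info("segment %d: constant COM z trace, retaining all frames", k + 1)
            masks.append(np.ones(len(z), dtype=bool))
            continue
        masks.append(np.abs(z - med) <= k_sd * s)
    return masks


def com_band(z: np.ndarray, k_sd: float = 1.0, scale: str = "mad") -> tuple[float, float]:
    """Centre and half-width of the rejection band for one z series."""
    med = float(np.median(z))
    if scale == "mad":
        s = MAD_TO_SD * float(np.median(np.abs(z - med)))
    else:
        s = float(np.std(z))
    return med, k_sd * s


def apply_frame_mask(
    rec: SkeletonRecording, masks: list[np.ndarray]
) -> SkeletonRecording:
    """Drop masked-out frames, keeping original frame indices for timing."""
    if len(masks) != rec.n_segments:
        raise ValueError("one mask per segment required")
    segments, indices = [], []
    for k, (seg, idx, m) in enumerate(
        zip(rec.segments, rec.frame_indices, masks), 1
    ):
        if len(m) != len(seg):
            raise ValueError(f"segment {k}: mask length mismatch")
        kept = seg[m]
        if len(kept) < 2:
            raise ValueError(f"segment {k}: fewer than 2 frames retained")
        removed = int(len(seg) - len(kept))
        if removed:
            log.info("segment %d: removed %d of %d frames", k, removed, len(seg))
        segments.append(kept)
        indices.append(idx[m])
    out = rec.copy()
    out.segments = segments
    out.frame_indices = indices
    out.validate()
    return out


# -- Savitzky-Golay filter ----------------------------------------------


def _lsq_weights(offsets: np.ndarray, order: int, at: float = 0.0) -> np.ndarray:
    """Weights of the least-squares degree-``order`` fit evaluated at ``at``.

    Solving the normal equations (A^T A) c = A^T y for the polynomial
    coefficients c and evaluating at ``at`` expresses the fitted value as a
    fixed linear combination of the samples; those combination weights are
    returned.
    """
    offsets = np.asarray(offsets, dtype=float)
    if len(offsets) < order + 1:
        raise ValueError(
            f"window of {len(offsets)} samples too small for order {order}"
        )
    A = np.vander(offsets, order + 1, increasing=True)
    e = np.power(float(at), np.arange(order + 1))
    # weights = e^T (A^T A)^{-1} A^T
    return np.linalg.solve(A.T @ A, A.T).T @ e


@dataclass(frozen=True)
class SavitzkyGolaySpec:
    """Polynomial order R, half-window L_w and the centre-point weights."""

    order: int
    half_window: int
    weights: np.ndarray = field(default=None)  # a_l for l = -L_w..L_w

    def __post_init__(self) -> None:
        if self.order < 0:
            raise ValueError("order must be >= 0")
        if self.half_window < 1:
            raise ValueError("half-window must be >= 1")
        if self.window < self.order + 1:
            raise ValueError(
                f"window {self.window} too small for order {self.order}"
            )
        if self.weights is None:
            w = _lsq_weights(
                np.arange(-self.half_window, self.half_window + 1), self.order
            )
            object.__setattr__(self, "weights", w)

    @property
    def window(self) -> int:
        return 2 * self.half_window + 1


def savgol_weights(order: int, half_window: int) -> SavitzkyGolaySpec:
    """Savitzky-Golay convolution weights for the given order and window.

    The weights are symmetric, sum to one (a constant signal passes
    through unchanged) and reproduce any polynomial of degree <= order
    exactly at interior samples.
    """
    return SavitzkyGolaySpec(order=order, half_window=half_window)


DEFAULT_SG = SavitzkyGolaySpec(order=2, half_window=12)  # 25-frame window


def _smooth_block(block: np.ndarray, spec: SavitzkyGolaySpec) -> np.ndarray:
    """Filter each column of a (J, C) block along axis 0."""
    J = len(block)
    R, Lw = spec.order, spec.half_window
    if J < R + 1:
        raise ValueError(f"segment of {J} frames too short for order {R}")
    out = np.empty_like(block)
    if J >= spec.window:
        windows = sliding_window_view(block, spec.window, axis=0)  # (J-2Lw, C, W)
        out[Lw:J - Lw] = windows @ spec.weights
        edge_idx = [*range(Lw), *range(J - Lw, J)]
    else:
        edge_idx = range(J)  # too short for the full window: fit everywhere
    for i in edge_idx:
        lo, hi = max(0, i - Lw), min(J, i + Lw + 1)
        w = _lsq_weights(np.arange(lo, hi) - i, min(R, hi - lo - 1))
        out[i] = w @ block[lo:hi]
    return out


def smooth_recording(
    rec: SkeletonRecording, spec: SavitzkyGolaySpec = DEFAULT_SG
) -> SkeletonRecording:
    """Apply the Savitzky-Golay filter to every joint-coordinate sequence.

    Interior frames use the centre-point convolution weights; frames within
    L_w of a segment edge use shrinking-window least-squares fits of the
    same order, so segment lengths are preserved.
    """
    out = rec.copy()
    for k, seg in enumerate(out.segments):
        J = len(seg)
        block = seg.reshape(J, -1)
        out.segments[k] = _smooth_block(block, spec).reshape(seg.shape)
    return out


def preprocess(
    rec: SkeletonRecording,
    k_sd: float = 1.0,
    scale: str = "mad",
    sg: SavitzkyGolaySpec = DEFAULT_SG,
) -> tuple[SkeletonRecording, SkeletonRecording, dict]:
    """Full preprocessing: reject COM outlier frames, then smooth.

    Returns ``(retained_raw, smoothed, report)``.  ``retained_raw`` holds
    the surviving frames before smoothing (used for leg-length estimation,
    which is biased by low-pass filtering of the swing trajectories);
    ``smoothed`` is the filtered version used for step detection and
    walk-span identification.
    """
    trace = compute_com(rec)
    masks = reject_outlier_frames(trace, k_sd=k_sd, scale=scale)
    retained = apply_frame_mask(rec, masks)
    smoothed = smooth_recording(retained, sg)
    report = {
        "frames_total": rec.n_frames,
        "frames_removed_per_segment": [int((~m).sum()) for m in masks],
        "frames_retained": retained.n_frames,
    }
    return retained, smoothed, report
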