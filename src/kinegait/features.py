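"""Gait-feature estimation: leg lengths, steps, stride length, velocity.

The per-frame inter-foot distance DIST(j, k) — the Euclidean distance
between the left leg centre (mean of ankle/foot left, joints 15-16) and
the right leg centre (joints 19-20) — attains one local maximum per step.
Counting those maxima inside a straight-walk span, together with the
displacement of the whole-skeleton mean position, yields:

* stride length  SL = walking distance / step count   [m]
* gait velocity  GV = walking distance / elapsed time [m/s]

where the span is clipped to [first peak, last peak] and elapsed time uses
original frame indices divided by fps, so dropped outlier frames do not
distort the wall clock.  Leg length is the frame-averaged sum of the
hip-knee and knee-ankle distances per side (joints 13-14-15 left,
17-18-19 right); SL is additionally reported normalised by it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .joints import (
    LEFT_FOOT_JOINTS,
    LEFT_SHANK,
    LEFT_THIGH,
    RIGHT_FOOT_JOINTS,
    RIGHT_SHANK,
    RIGHT_THIGH,
)
from .skeleton import SkeletonRecording

log = logging.getLogger(__name__)


def euclid(d) -> float:
    """Euclidean length of a 3-vector of coordinate differences (metres)."""
    d = np.asarray(d, dtype=float)
    if d.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {d.shape}")
    if not np.all(np.isfinite(d)):
        raise ValueError("non-finite coordinate difference")
    return float(np.sqrt(np.sum(d * d)))


def _pair_distance(rec: SkeletonRecording, pair: tuple[int, int], k: int) -> np.ndarray:
    a = rec.joints([pair[0]], k)[:, 0, :]
    b = rec.joints([pair[1]], k)[:, 0, :]
    return np.linalg.norm(a - b, axis=1)


@dataclass
class LegLengthEstimate:
    """Per-frame and aggregate leg lengths (metres)."""

    ll: list[np.ndarray]  # left leg per frame, per segment
    rl: list[np.ndarray]  # right leg
    left_mean: float = field(init=False)
    right_mean: float = field(init=False)
    mean: float = field(init=False)
    asymmetry: float = field(init=False)

    def __post_init__(self) -> None:
        ll = np.concatenate(self.ll)
        rl = np.concatenate(self.rl)
        self.left_mean = float(ll.mean())
        self.right_mean = float(rl.mean())
        self.mean = 0.5 * (self.left_mean + self.right_mean)
        self.asymmetry = abs(self.left_mean - self.right_mean)

    def per_frame_mean(self, segment: int) -> np.ndarray:
        return 0.5 * (self.ll[segment] + self.rl[segment])


def estimate_leg_lengths(rec: SkeletonRecording) -> LegLengthEstimate:
    """Estimate leg lengths from hip-knee plus knee-ankle distances.

    Frames in which any limb segment degenerates to zero length (coincident
    joints) are excluded from the averages and logged.
    """
    ll_segs, rl_segs = [], []
    for k in range(rec.n_segments):
        lt = _pair_distance(rec, LEFT_THIGH, k)
        ls = _pair_distance(rec, LEFT_SHANK, k)
        rt = _pair_distance(rec, RIGHT_THIGH, k)
        rs = _pair_distance(rec, RIGHT_SHANK, k)
        ok = (lt > 0) & (ls > 0) & (rt > 0) & (rs > 0)
        if not ok.all():
            log.warning(
                "segment %d: excluded %d degenerate frame(s) from leg-length "
                "estimate", k + 1, int((~ok).sum()),
            )
        if not ok.any():
            raise ValueError(f"segment {k + 1}: no usable frames for leg length")
        ll_segs.append((lt + ls)[ok])
        rl_segs.append((rt + rs)[ok])
    return LegLengthEstimate(ll=ll_segs, rl=rl_segs)


def foot_distance(rec: SkeletonRecording) -> list[np.ndarray]:
    """Per-frame distance between the left and right leg centres, per segment."""
    series = []
    for k in range(rec.n_segments):
        left = rec.joints(LEFT_FOOT_JOINTS, k).mean(axis=1)
        right = rec.joints(RIGHT_FOOT_JOINTS, k).mean(axis=1)
        series.append(np.linalg.norm(left - right, axis=1))
    return series


def detect_steps(
    series: np.ndarray,
    min_prominence: float = 0.05,
    min_separation: int = 10,
) -> np.ndarray:
    """Indices of inter-foot-distance maxima qualifying as steps.

    A step is a local maximum with prominence >= ``min_prominence`` metres
    and at least ``min_separation`` frames from its neighbours.  Defaults
    sit below the physiological step scale and above sensor noise.  An
    empty result means the segment shows no stepping (caller flags it
    invalid).
    """
    series = np.asarray(series, dtype=float)
    if len(series) < 3:
        raise ValueError("series too short for peak detection")
    peaks, _ = find_peaks(
        series, prominence=min_prominence, distance=max(1, int(min_separation))
    )
    return peaks


@dataclass(frozen=True)
class WalkSpan:
    """Half-open position range [start, stop) of straight walking."""

    segment: int
    start: int
    stop: int

    def __len__(self) -> int:
        return self.stop - self.start


def _mean_trajectory(rec: SkeletonRecording, k: int) -> np.ndarray:
    return rec.segments[k].mean(axis=1)


def detect_walk_spans(
    rec: SkeletonRecording,
    trim_radius: int = 15,
    min_span: int = 30,
    speed_floor: float = 0.1,
) -> list[WalkSpan]:
    """Straight-walk spans per segment, with turn frames excluded.

    The whole-skeleton mean position is projected onto the dominant
    horizontal travel axis (principal axis of its x-z trajectory).  Maximal
    runs of frames whose projected speed keeps one sign and exceeds
    ``speed_floor`` (m/s) are straight walks; frames within ``trim_radius``
    original-frame-index units of a direction-reversal extremum are
    excluded.  Runs shorter than ``min_span`` frames are discarded.
    """
    spans: list[WalkSpan] = []
    for k in range(rec.n_segments):
        traj = _mean_trajectory(rec, k)
        horiz = traj[:, [0, 2]] - traj[:, [0, 2]].mean(axis=0)
        cov = horiz.T @ horiz
        _, vecs = np.linalg.eigh(cov)
        axis = vecs[:, -1]  # dominant horizontal direction
        p = horiz @ axis
        t = rec.frame_indices[k] / rec.fps
        v = np.gradient(p, t)
        sign = np.where(np.abs(v) >= speed_floor, np.sign(v), 0.0)

        runs = _sign_runs(sign)
        runs = _trim_reversals(runs, p, rec.frame_indices[k], trim_radius)
        for start, stop in runs:
            if stop - start >= min_span:
                spans.append(WalkSpan(segment=k, start=start, stop=stop))
        if not any(s.segment == k for s in spans):
            log.warning("segment %d: no straight-walk span found", k + 1)
    return spans


def _sign_runs(sign: np.ndarray) -> list[tuple[int, int, float]]:
    """Maximal runs of constant non-zero sign as (start, stop, sign)."""
    runs = []
    start = None
    cur = 0.0
    for i, s in enumerate(sign):
        if s != 0 and s == cur:
            continue
        if start is not None and cur != 0:
            runs.append((start, i, cur))
        start, cur = (i, s) if s != 0 else (None, 0.0)
    if start is not None and cur != 0:
        runs.append((start, len(sign), cur))
    return runs


def _trim_reversals(
    runs: list[tuple[int, int, float]],
    p: np.ndarray,
    frame_idx: np.ndarray,
    trim_radius: int,
) -> list[tuple[int, int]]:
    """Exclude frames near the extremum between opposite-sign runs."""
    trimmed = [[a, b] for a, b, _ in runs]
    for i in range(len(runs) - 1):
        a, b, s1 = runs[i]
        c, d, s2 = runs[i + 1]
        if s1 == s2:
            continue
        gap = slice(b - 1, c + 1)
        rev = (b - 1) + (
            int(np.argmax(p[gap])) if s1 > 0 else int(np.argmin(p[gap]))
        )
        rev_frame = frame_idx[rev]
        # pull back the end of the left run / start of the right run
        while trimmed[i][1] > trimmed[i][0] and (
            abs(frame_idx[trimmed[i][1] - 1] - rev_frame) <= trim_radius
        ):
            trimmed[i][1] -= 1
        while trimmed[i + 1][0] < trimmed[i + 1][1] and (
            abs(frame_idx[trimmed[i + 1][0]] - rev_frame) <= trim_radius
        ):
            trimmed[i + 1][0] += 1
    return [(a, b) for a, b in trimmed if b > a]


def walking_distance(rec: SkeletonRecording, span: WalkSpan) -> float:
    """Displacement of the whole-skeleton mean over a span (metres)."""
    if len(span) < 2:
        raise ValueError("span shorter than 2 frames")
    traj = _mean_trajectory(rec, span.segment)
    return float(
        np.linalg.norm(traj[span.stop - 1] - traj[span.start])
    )


@dataclass
class SegmentFeatures:
    """Gait features of one straight-walk span."""

    segment: int
    step_count: int
    distance_m: float
    sl_m: float
    sl_norm: float
    gv_mps: float
    valid: bool = True


@dataclass
class SubjectFeatures:
    """Per-subject gait features: means over valid walk spans."""

    subject_id: str
    group: str | None
    leg_length_m: float
    leg_asymmetry_m: float
    sl_m: float
    sl_norm: float
    gv_mps: float
    n_segments_valid: int
    n_segments_invalid: int
    segments: list[SegmentFeatures] = field(default_factory=list)


def segment_features(
    rec: SkeletonRecording,
    span: WalkSpan,
    peaks: np.ndarray,
    leg_length: float,
) -> SegmentFeatures:
    """Features of one span given its step peaks (positions in the segment).

    The span is clipped to [first peak, last peak]; stride length is the
    walking distance over that range divided by the step count, and gait
    velocity divides by the elapsed time from original frame indices.
    """
    peaks = np.asarray(peaks, dtype=int)
    if len(peaks) < 2:
        raise ValueError("need >= 2 step peaks for segment features")
    first, last = int(peaks[0]), int(peaks[-1])
    clipped = WalkSpan(segment=span.segment, start=first, stop=last + 1)
    dist = walking_distance(rec, clipped)
    idx = rec.frame_indices[span.segment]
    dt = (idx[last] - idx[first]) / rec.fps
    if dt <= 0:
        raise ValueError("zero time difference between first and last peak")
    sl = dist / len(peaks)
    return SegmentFeatures(
        segment=span.segment,
        step_count=int(len(peaks)),
        distance_m=dist,
        sl_m=sl,
        sl_norm=sl / leg_length,
        gv_mps=dist / dt,
    )


def subject_features(
    subject_id: str,
    group: str | None,
    leg: LegLengthEstimate,
    segments: list[SegmentFeatures],
    n_invalid: int = 0,
) -> SubjectFeatures:
    """Arithmetic means of the per-span features over valid spans."""
    valid = [s for s in segments if s.valid]
    if not valid:
        raise ValueError(f"subject {subject_id}: no valid walk segments")
    return SubjectFeatures(
        subject_id=subject_id,
        group=group,
        leg_length_m=leg.mean,
        leg_asymmetry_m=leg.asymmetry,
        sl_m=float(np.mean([s.sl_m for s in valid])),
        sl_norm=float(np.mean([s.sl_norm for s in valid])),
        gv_mps=float(np.mean([s.gv_mps for s in valid])),
        n_segments_valid=len(valid),
        n_segments_invalid=n_invalid,
        segments=segments,
    )


def extract_features(
    rec: SkeletonRecording,
    k_sd: float = 1.0,
    scale: str = "mad",
    sg_order: int = 2,
    sg_half_window: int = 12,
    min_prominence: float = 0.05,
    min_separation: int = 10,
    trim_radius: int = 15,
    min_span: int = 30,
) -> SubjectFeatures:
    """Full feature-extraction pipeline for one subject's recording.

    Order of operations: COM outlier rejection on raw frames; leg-length
    estimation on the retained unsmoothed frames (low-pass filtering biases
    swing-phase joint positions); Savitzky-Golay smoothing; walk-span
    identification with turn rejection; step detection on the inter-foot
    distance; stride length and gait velocity per span; subject-level
    means.
    """
    from .preprocess import SavitzkyGolaySpec, preprocess

    retained, smoothed, _ = preprocess(
        rec, k_sd=k_sd, scale=scale,
        sg=SavitzkyGolaySpec(order=sg_order, half_window=sg_half_window),
    )
    leg = estimate_leg_lengths(retained)
    spans = detect_walk_spans(
        smoothed, trim_radius=trim_radius, min_span=min_span
    )
    dist = foot_distance(smoothed)
    segs: list[SegmentFeatures] = []
    n_invalid = 0
    for span in spans:
        series = dist[span.segment][span.start:span.stop]
        peaks = detect_steps(series, min_prominence, min_separation) + span.start
        if len(peaks) < 2:
            n_invalid += 1
            log.warning(
                "subject %s segment %d: <2 step peaks, span invalid",
                rec.subject_id, span.segment + 1,
            )
            continue
        segs.append(segment_features(smoothed, span, peaks, leg.mean))
    n_invalid += smoothed.n_segments - len({s.segment for s in spans})
    return subject_features(
        rec.subject_id, rec.group_label, leg, segs, n_invalid
    )


def feature_table(subjects: list[SubjectFeatures]):
    """Feature table with one row per subject (pandas DataFrame)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "leg_length_m": s.leg_length_m,
                "leg_asymmetry_m": s.leg_asymmetry_m,
                "sl_m": s.sl_m,
                "sl_norm": s.sl_norm,
                "gv_mps": s.gv_mps,
                "n_segments_valid": s.n_segments_valid,
            }
            for s in subjects
        ]
    )
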