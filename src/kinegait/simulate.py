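"""Synthetic skeleton walking recordings with known ground truth.

The generator emulates the study protocol: each subject performs five
straight walks of ~4 m along the sensor depth axis (back and forth),
recorded at 30 fps with 20 joints per frame, with turning intervals at the
segment boundaries, isotropic sensor noise, and occasional gross-error
frames that displace the whole skeleton in depth.

Kinematic model (deliberately non-biofidelic, but geometrically exact):
the pelvis advances at constant speed; the two ankles oscillate in
antiphase about the pelvis along the travel axis, so the inter-foot
distance attains one maximum per step; knees are placed by two-link
inverse kinematics so the configured thigh and shank lengths hold exactly
in every frame; the upper body rides rigidly on the pelvis.  Stance/swing
asymmetry, arm swing and ground contact are not modelled.

Ground truth is computed from the generator's closed form (peak times,
retention-band arithmetic on its own clean depth trace), independent of
the analysis pipeline: the recorded ``true`` stride length is the value an
ideal noise-free measurement of distance(first step, last step)/steps
would return, and cohort generation calibrates the per-step advance so
this ideal value matches the drawn cohort target.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .skeleton import SkeletonRecording

log = logging.getLogger(__name__)

MAD_TO_SD = 1.4826022185056018
_IK_MARGIN = 0.98  # fraction of full leg extension usable by the ankle offset


# -- specifications ------------------------------------------------------


@dataclass
class WalkSpec:
    """Parameters of one simulated subject's recording."""

    thigh_left: float = 0.3925
    shank_left: float = 0.3925
    thigh_right: float = 0.3925
    shank_right: float = 0.3925
    step_advance: float = 0.54  # pelvis advance per step [m]
    gait_velocity: float = 0.81  # [m/s]
    fps: float = 30.0
    n_segments: int = 5
    path_length: float = 4.0  # [m]
    turn_frames: int = 20
    phase: float = 0.3  # foot-oscillation phase at walk start [rad]
    noise_sd: float = 0.005  # isotropic per-joint noise SD [m]
    noise_model: str = "gauss"  # or "uniform" for the +-40 mm sensor band
    outlier_rate: float = 0.01  # per-frame gross-error probability
    outlier_magnitude: float | None = None  # [m]; None = 8x clean band
    seed: int = 0
    start_depth: float = 1.5  # [m]
    hip_half_width: float = 0.05
    ankle_height: float = 0.08
    subject_id: str = "sim"
    group_label: str | None = None

    @property
    def leg_left(self) -> float:
        return self.thigh_left + self.shank_left

    @property
    def leg_right(self) -> float:
        return self.thigh_right + self.shank_right

    @property
    def leg_mean(self) -> float:
        return 0.5 * (self.leg_left + self.leg_right)

    @property
    def step_frequency(self) -> float:
        return self.gait_velocity / self.step_advance  # steps per second

    def validate(self) -> None:
        for name in (
            "thigh_left", "shank_left", "thigh_right", "shank_right",
            "step_advance", "gait_velocity", "fps", "path_length",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0 or not (0 <= self.outlier_rate < 1):
            raise ValueError("invalid noise or outlier parameters")
        if self.n_segments < 1 or self.turn_frames < 0:
            raise ValueError("invalid segment/turn configuration")
        leg_min = min(self.leg_left, self.leg_right)
        if self.step_advance >= 2.0 * leg_min:
            raise ValueError(
                f"step length {self.step_advance:.3f} m >= 2x leg length "
                f"{leg_min:.3f} m is non-physical"
            )
        if 0.5 * self.step_advance >= _IK_MARGIN * leg_min:
            raise ValueError("step length too large for the leg geometry")


@dataclass
class WalkTruth:
    """Ideal-measurement ground truth accompanying a simulated recording."""

    sl_m: float
    gv_mps: float
    leg_left_m: float
    leg_right_m: float
    leg_mean_m: float
    step_counts: list[int]
    per_segment_sl: list[float]
    outlier_frames: list[tuple[int, int]]  # (segment, frame position)
    step_advance_m: float
    edge_margin_frames: int


# -- kinematics ----------------------------------------------------------


def _leg_chain(spec: WalkSpec, side: str, z_p, delta, direction):
    """Hip/knee/ankle/foot positions for one leg, vectorised over frames.

    ``delta`` is the signed ankle offset from the pelvis along z.  The knee
    is placed by two-link inverse kinematics in the sagittal plane, so the
    thigh and shank lengths are exact in every frame.
    """
    a = spec.thigh_left if side == "left" else spec.thigh_right
    b = spec.shank_left if side == "left" else spec.shank_right
    x = -spec.hip_half_width if side == "left" else spec.hip_half_width
    leg_min = min(spec.leg_left, spec.leg_right)
    delta_max = 0.5 * spec.step_advance
    g = math.sqrt((_IK_MARGIN * leg_min) ** 2 - delta_max**2)
    hip_y = spec.ankle_height + g

    n = len(z_p)
    hip = np.column_stack([np.full(n, x), np.full(n, hip_y), z_p])
    ankle = np.column_stack(
        [np.full(n, x), np.full(n, spec.ankle_height), z_p + delta]
    )
    dy = spec.ankle_height - hip_y  # constant, negative
    d = np.sqrt(dy**2 + delta**2)
    cos_a = np.clip((a**2 + d**2 - b**2) / (2 * a * d), -1.0, 1.0)
    sin_a = np.sqrt(1.0 - cos_a**2)
    uy, uz = dy / d, delta / d
    # unit vector perpendicular to the hip->ankle chord, tilted forward
    py, pz = direction * uz, -direction * uy
    knee = hip + a * np.column_stack(
        [np.zeros(n), uy * cos_a + py * sin_a, uz * cos_a + pz * sin_a]
    )
    foot = ankle + np.array([0.0, -0.04, 0.12 * direction])
    return hip, knee, ankle, foot


def _postures(spec: WalkSpec, z_p, delta, sway, direction) -> np.ndarray:
    """Frames (n, 20, 3) for pelvis depths ``z_p`` and ankle offsets ``delta``."""
    n = len(z_p)
    leg_min = min(spec.leg_left, spec.leg_right)
    g = math.sqrt((_IK_MARGIN * leg_min) ** 2 - (0.5 * spec.step_advance) ** 2)
    hip_y = spec.ankle_height + g

    frames = np.zeros((n, 20, 3))

    def put(idx, x, y, z):
        frames[:, idx - 1, 0] = x
        frames[:, idx - 1, 1] = y
        frames[:, idx - 1, 2] = z

    put(1, 0.0, hip_y + 0.10, z_p)   # hip centre
    put(2, 0.0, hip_y + 0.35, z_p)   # spine
    put(3, 0.0, hip_y + 0.55, z_p)   # shoulder centre
    put(4, 0.0, hip_y + 0.75, z_p)   # head
    for side, sgn, js in (("left", -1, (5, 6, 7, 8)), ("right", 1, (9, 10, 11, 12))):
        put(js[0], sgn * 0.18, hip_y + 0.50, z_p)  # shoulder
        put(js[1], sgn * 0.22, hip_y + 0.28, z_p)  # elbow
        put(js[2], sgn * 0.22, hip_y + 0.08, z_p)  # wrist
        put(js[3], sgn * 0.22, hip_y + 0.00, z_p)  # hand
    for side, js, dlt in (("left", (13, 14, 15, 16), delta), ("right", (17, 18, 19, 20), -delta)):
        hip, knee, ankle, foot = _leg_chain(spec, side, z_p, dlt, direction)
        frames[:, js[0] - 1] = hip
        frames[:, js[1] - 1] = knee
        frames[:, js[2] - 1] = ankle
        frames[:, js[3] - 1] = foot
    frames[:, :, 0] += sway[:, None]
    return frames


@dataclass
class _SegmentPlan:
    lead: int
    n_walk: int
    direction: int
    clean_z: np.ndarray  # pelvis depth incl. outlier displacement
    t_walk: np.ndarray  # walk-frame times [s]


def _plan_segment(spec: WalkSpec, k: int) -> _SegmentPlan:
    direction = 1 if k % 2 == 0 else -1
    z_start = spec.start_depth if direction == 1 else spec.start_depth + spec.path_length
    n_walk = int(round(spec.path_length / spec.gait_velocity * spec.fps)) + 1
    lead = spec.turn_frames // 2
    tail = spec.turn_frames - lead
    t_walk = np.arange(n_walk) / spec.fps
    z_walk = z_start + direction * spec.gait_velocity * t_walk
    clean_z = np.concatenate(
        [np.full(lead, z_walk[0]), z_walk, np.full(tail, z_walk[-1])]
    )
    return _SegmentPlan(
        lead=lead, n_walk=n_walk, direction=direction,
        clean_z=clean_z, t_walk=t_walk,
    )


def _segment_frames(spec: WalkSpec, plan: _SegmentPlan) -> np.ndarray:
    """Noise-free frames of one segment (turn-in, walk, turn-out)."""
    omega = math.pi * spec.step_frequency
    delta_walk = 0.5 * spec.step_advance * np.sin(omega * plan.t_walk + spec.phase)
    tail = len(plan.clean_z) - plan.lead - plan.n_walk
    # turn frames freeze the adjacent walk posture, with lateral sway
    delta = np.concatenate(
        [np.full(plan.lead, delta_walk[0]), delta_walk, np.full(tail, delta_walk[-1])]
    )
    z_all = plan.clean_z
    sway = np.zeros(len(z_all))
    t_lead = np.arange(plan.lead) / spec.fps
    t_tail = np.arange(tail) / spec.fps
    sway[:plan.lead] = 0.04 * np.sin(2 * np.pi * 1.2 * t_lead)
    sway[plan.lead + plan.n_walk:] = 0.04 * np.sin(2 * np.pi * 1.2 * t_tail)
    return _postures(spec, z_all, delta, sway, plan.direction)


# -- ideal (ground-truth) measurement ------------------------------------


def _retained_mask(z: np.ndarray, k_sd: float = 1.0) -> np.ndarray:
    med = np.median(z)
    s = MAD_TO_SD * np.median(np.abs(z - med))
    if s == 0:
        return np.ones(len(z), dtype=bool)
    return np.abs(z - med) <= k_sd * s


def _ideal_measurement(
    spec: WalkSpec,
    plans: list[_SegmentPlan],
    k_sd: float = 1.0,
    z_override: list[np.ndarray] | None = None,
):
    """Closed-form ideal measurement per segment on the clean depth trace."""
    f_step = spec.step_frequency
    results = []
    for ki, plan in enumerate(plans):
        z = z_override[ki] if z_override is not None else plan.clean_z
        mask = _retained_mask(z, k_sd)
        walk = np.arange(plan.lead, plan.lead + plan.n_walk)
        ret = walk[mask[walk]]
        if len(ret) < 3:
            results.append(None)
            continue
        # dropping an isolated frame does not break the walk span: the
        # retained walk frames act as one concatenated monotone series
        retained = set(int(r) for r in ret)
        t_end = plan.t_walk[-1]
        peaks = []
        margin = np.inf  # distance of any step extremum to the band edges
        i = 0
        while True:
            tau = (i + 0.5 - spec.phase / math.pi) / f_step
            if tau > t_end:
                break
            if tau >= 0:
                frame = plan.lead + int(round(tau * spec.fps))
                # a countable maximum needs retained frames strictly on
                # both sides; the peak survives if any frame within one of
                # the ideal peak time is retained
                near = [f for f in (frame, frame - 1, frame + 1) if f in retained]
                if near and ret[0] < near[0] < ret[-1]:
                    peaks.append(near[0])
                    margin = min(margin, near[0] - ret[0], ret[-1] - near[0])
                else:
                    # uncounted extremum: how far outside the edges is it?
                    margin = min(
                        margin, max(ret[0] - frame, frame - ret[-1], 0)
                    )
            i += 1
        if len(peaks) < 2:
            results.append(None)
            continue
        p = len(peaks)
        dframes = peaks[-1] - peaks[0]
        sl = spec.gait_velocity * (dframes / spec.fps) / p
        results.append({"P": p, "sl": sl, "margin": int(margin)})
    return results


# -- public generator API ------------------------------------------------


def simulate_walk(spec: WalkSpec) -> tuple[SkeletonRecording, WalkTruth]:
    """Simulate one subject's recording and its ground-truth record."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    plans = [_plan_segment(spec, k) for k in range(spec.n_segments)]

    # gross-error frames: whole-skeleton depth displacement, drawn first so
    # that outlier placement is independent of the noise realisation
    outliers: list[tuple[int, int, float]] = []
    z_disp = [plan.clean_z.copy() for plan in plans]
    for k, plan in enumerate(plans):
        n = len(plan.clean_z)
        hits = np.flatnonzero(rng.random(n) < spec.outlier_rate)
        if spec.outlier_magnitude is None:
            med = np.median(plan.clean_z)
            band = MAD_TO_SD * np.median(np.abs(plan.clean_z - med))
            mag = 8.0 * max(band, 0.05)
        else:
            mag = spec.outlier_magnitude
        for j in hits:
            sign = 1.0 if rng.random() < 0.5 else -1.0
            outliers.append((k, int(j), sign * mag))
            z_disp[k][j] += sign * mag

    ideal = _ideal_measurement(spec, plans, z_override=z_disp)

    segments = []
    for k, plan in enumerate(plans):
        frames = _segment_frames(spec, plan)
        # apply the gross-error depth displacement to every joint
        for kk, j, dz in outliers:
            if kk == k:
                frames[j, :, 2] += dz
        if spec.noise_sd > 0 and spec.noise_model == "gauss":
            frames = frames + rng.normal(0.0, spec.noise_sd, frames.shape)
        elif spec.noise_model == "uniform":
            frames = frames + rng.uniform(-0.04, 0.04, frames.shape)
        elif spec.noise_model != "gauss":
            raise ValueError(f"unknown noise model {spec.noise_model!r}")
        segments.append(frames)

    rec = SkeletonRecording(
        segments=segments,
        fps=spec.fps,
        subject_id=spec.subject_id,
        group_label=spec.group_label,
    )
    valid = [r for r in ideal if r is not None]
    if not valid:
        raise ValueError("no segment yields a measurable walk; check the spec")
    truth = WalkTruth(
        sl_m=float(np.mean([r["sl"] for r in valid])),
        gv_mps=spec.gait_velocity,
        leg_left_m=spec.leg_left,
        leg_right_m=spec.leg_right,
        leg_mean_m=spec.leg_mean,
        step_counts=[r["P"] if r else 0 for r in ideal],
        per_segment_sl=[r["sl"] if r else float("nan") for r in ideal],
        outlier_frames=[(k, j) for k, j, _ in outliers],
        step_advance_m=spec.step_advance,
        edge_margin_frames=int(min(r["margin"] for r in valid)),
    )
    return rec, truth


def calibrated_walk_spec(
    target_sl: float,
    target_gv: float,
    leg_length: float = 0.785,
    asymmetry: float = 0.0,
    **kwargs,
) -> WalkSpec:
    """Build a WalkSpec whose ideal measured SL/GV match the targets.

    The measured stride length is distance(first peak, last peak)/steps,
    i.e. ``step_advance * (P-1)/P`` for P counted maxima, so the per-step
    advance is calibrated iteratively against the generator's closed-form
    ideal measurement.  The walk phase is then nudged so that no counted
    step peak sits within a few frames of the retention-band edge, keeping
    the ideal step count stable under sensor noise.
    """
    left = leg_length + 0.5 * asymmetry
    right = leg_length - 0.5 * asymmetry
    base = dict(
        thigh_left=left / 2, shank_left=left / 2,
        thigh_right=right / 2, shank_right=right / 2,
        gait_velocity=target_gv,
    )
    base.update(kwargs)

    def ideal_sl(step, phase):
        spec = WalkSpec(step_advance=step, phase=phase, **base)
        spec.validate()
        plans = [_plan_segment(spec, k) for k in range(spec.n_segments)]
        res = _ideal_measurement(spec, plans)
        valid = [r for r in res if r is not None]
        if not valid:
            raise ValueError("walk too short to count steps; check targets")
        sl = float(np.mean([r["sl"] for r in valid]))
        margin = min(r["margin"] for r in valid)
        return sl, margin, spec

    phase = base.pop("phase", 0.3)
    step_cap = 1.9 * min(left, right) * _IK_MARGIN / 2.0 * 2.0  # validate() guards anyway
    step = target_sl
    best_step = None  # (|sl - target|, step)
    for _ in range(10):
        sl, _, _ = ideal_sl(step, phase)
        err = abs(sl - target_sl)
        if best_step is None or err < best_step[0]:
            best_step = (err, step)
        if err < 1e-9:
            break
        # frame rounding quantises the ideal SL, so the fixed-point
        # iteration may cycle between step-count regimes; keep the best
        step = min(step * target_sl / sl, step_cap)
    step = best_step[1]
    # keep every step extremum clear of the retention-band edges (counted
    # ones inside, uncounted ones outside) so the ideal step count is
    # stable under sensor noise and occasional gross-error frames
    best = None
    for cand in (phase, *np.linspace(0.0, math.pi, 13, endpoint=False)):
        sl, margin, cand_spec = ideal_sl(step, cand)
        score = (min(margin, 8), -abs(sl - target_sl))
        if best is None or score > best[0]:
            best = (score, cand_spec)
        if margin >= 8:
            break
    return best[1]


# -- cohorts -------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Per-group cohort parameters: subject count and Normal(mean, SD)."""

    n: int
    sl_mean: float
    sl_sd: float
    gv_mean: float
    gv_sd: float
    leg_mean: float
    leg_sd: float

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if min(self.sl_sd, self.gv_sd, self.leg_sd) < 0:
            raise ValueError("SDs must be non-negative")
        if min(self.sl_mean, self.gv_mean, self.leg_mean) <= 0:
            raise ValueError("means must be positive")


@dataclass
class CohortSpec:
    """Cohort layout; defaults mirror the study's three groups."""

    groups: dict = field(default_factory=lambda: {
        "PD": GroupSpec(18, 0.38, 0.07, 0.61, 0.12, 0.785, 0.034),
        "NORM": GroupSpec(18, 0.54, 0.06, 0.81, 0.15, 0.783, 0.027),
        "STUD": GroupSpec(15, 0.61, 0.04, 1.05, 0.15, 0.792, 0.009),
    })
    asymmetry_sd: float = 0.005  # |N(0, sd)| left-right leg difference
    cadence_range: tuple = (0.6, 2.6)  # physiological walking, steps/s
    walk_kwargs: dict = field(default_factory=dict)

    def validate(self) -> None:
        if not self.groups:
            raise ValueError("cohort has no groups")
        for g in self.groups.values():
            g.validate()


def default_cohort(**overrides) -> CohortSpec:
    spec = CohortSpec(**overrides)
    spec.validate()
    return spec


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, retries: int = 100
) -> float:
    """Normal draw truncated to [0.1, 1.5] x mean (physical plausibility)."""
    lo, hi = 0.1 * mean, 1.5 * mean
    for _ in range(retries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ValueError(f"no draw in [{lo:.3g}, {hi:.3g}] after {retries} tries")


@dataclass
class SimulatedSubject:
    subject_id: str
    group: str
    recording: SkeletonRecording | None
    truth: WalkTruth | None
    drawn_sl: float
    drawn_gv: float
    drawn_leg: float


@dataclass
class Cohort:
    subjects: list[SimulatedSubject]

    @property
    def truth_table(self) -> pd.DataFrame:
        rows = []
        for s in self.subjects:
            t = s.truth
            rows.append({
                "subject_id": s.subject_id,
                "group": s.group,
                "true_sl_m": t.sl_m if t else s.drawn_sl,
                "true_gv_mps": t.gv_mps if t else s.drawn_gv,
                "true_leg_m": t.leg_mean_m if t else s.drawn_leg,
                "true_leg_asym_m": (t.leg_left_m - t.leg_right_m) if t else 0.0,
                "n_outlier_frames": len(t.outlier_frames) if t else 0,
            })
        return pd.DataFrame(rows)

    @property
    def feature_table(self) -> pd.DataFrame:
        """Ideal features per subject (no sensor simulation)."""
        return pd.DataFrame([
            {
                "subject_id": s.subject_id,
                "group": s.group,
                "sl_m": s.truth.sl_m if s.truth else s.drawn_sl,
                "gv_mps": s.truth.gv_mps if s.truth else s.drawn_gv,
                "leg_length_m": s.truth.leg_mean_m if s.truth else s.drawn_leg,
            }
            for s in self.subjects
        ])


def simulate_cohort(
    spec: CohortSpec | None = None,
    seed: int = 0,
    mode: str = "recordings",
) -> Cohort:
    """Draw a labelled cohort; reproducible for a given seed.

    ``mode="recordings"`` simulates full skeleton recordings per subject
    (per-step advance calibrated so the ideal measured stride length
    equals the drawn value); ``mode="features"`` skips the kinematic
    simulation and returns the drawn feature values only, for
    classifier-level experiments.
    """
    spec = spec or default_cohort()
    spec.validate()
    if mode not in ("recordings", "features"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    subjects: list[SimulatedSubject] = []
    for group, g in spec.groups.items():
        for i in range(g.n):
            sid = f"{group.lower()}{i + 1:03d}"
            if mode == "recordings":
                # joint draw with a physiological cadence constraint: gv/sl
                # is the step rate, and independent marginals occasionally
                # pair a short stride with a fast walk that no walking
                # subject produces (and that the kinematic model cannot
                # realise); feature-only draws keep the pure marginals
                lo, hi = spec.cadence_range
                for _ in range(100):
                    sl = _truncated_normal(rng, g.sl_mean, g.sl_sd)
                    gv = _truncated_normal(rng, g.gv_mean, g.gv_sd)
                    if lo <= gv / sl <= hi:
                        break
                else:
                    raise ValueError("no physiological (sl, gv) draw found")
            else:
                sl = _truncated_normal(rng, g.sl_mean, g.sl_sd)
                gv = _truncated_normal(rng, g.gv_mean, g.gv_sd)
            leg = _truncated_normal(rng, g.leg_mean, g.leg_sd)
            asym = abs(rng.normal(0.0, spec.asymmetry_sd))
            child_seed = int(rng.integers(0, 2**31))
            rec = truth = None
            if mode == "recordings":
                wspec = calibrated_walk_spec(
                    sl, gv, leg_length=leg, asymmetry=asym,
                    seed=child_seed, subject_id=sid, group_label=group,
                    **spec.walk_kwargs,
                )
                rec, truth = simulate_walk(wspec)
            subjects.append(SimulatedSubject(
                subject_id=sid, group=group, recording=rec, truth=truth,
                drawn_sl=sl, drawn_gv=gv, drawn_leg=leg,
            ))
    return Cohort(subjects=subjects)


def inject_outliers(
    rec: SkeletonRecording,
    frames,
    magnitude: float,
    truth: WalkTruth | None = None,
) -> SkeletonRecording:
    """Displace the listed frames' joints along z by ``magnitude`` metres.

    ``frames`` is a sequence of (segment, frame) position pairs (0-based),
    or plain frame positions for a single-segment recording.  Updates the
    truth record's outlier list when given.  Magnitude 0 is a no-op copy.
    """
    out = rec.copy()
    norm: list[tuple[int, int]] = []
    for f in frames:
        k, j = (0, int(f)) if np.isscalar(f) else (int(f[0]), int(f[1]))
        if not (0 <= k < out.n_segments):
            raise IndexError(f"segment {k} out of range")
        if not (0 <= j < len(out.segments[k])):
            raise IndexError(f"frame {j} out of range in segment {k}")
        norm.append((k, j))
    for k, j in norm:
        out.segments[k][j, :, 2] += magnitude
    if truth is not None and magnitude != 0:
        truth.outlier_frames = sorted(set(truth.outlier_frames) | set(norm))
    return out
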