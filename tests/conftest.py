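"""Shared fixtures: small programmatically generated recordings."""

from __future__ import annotations

import numpy as np
import pytest

from kinegait import SkeletonRecording, calibrated_walk_spec, simulate_walk


def base_posture() -> np.ndarray:
    """A plausible standing posture: 20 joints, metres, z ~ 2.5 m depth."""
    p = np.zeros((20, 3))
    z = 2.5
    hip_y = 0.85
    p[0] = (0.00, hip_y + 0.10, z)   # hip centre
    p[1] = (0.00, hip_y + 0.35, z)   # spine
    p[2] = (0.00, hip_y + 0.55, z)   # shoulder centre
    p[3] = (0.00, hip_y + 0.75, z)   # head
    for sgn, js in ((-1, (4, 5, 6, 7)), (1, (8, 9, 10, 11))):
        p[js[0]] = (sgn * 0.18, hip_y + 0.50, z)
        p[js[1]] = (sgn * 0.22, hip_y + 0.28, z)
        p[js[2]] = (sgn * 0.22, hip_y + 0.08, z)
        p[js[3]] = (sgn * 0.22, hip_y + 0.00, z)
    for sgn, js in ((-1, (12, 13, 14, 15)), (1, (16, 17, 18, 19))):
        p[js[0]] = (sgn * 0.08, hip_y, z)          # hip
        p[js[1]] = (sgn * 0.08, hip_y - 0.40, z)   # knee
        p[js[2]] = (sgn * 0.08, hip_y - 0.80, z)   # ankle
        p[js[3]] = (sgn * 0.08, hip_y - 0.84, z + 0.12)  # foot
    return p


def standing_recording(
    n_frames: int = 120, jitter: float = 1e-4, seed: int = 0
) -> SkeletonRecording:
    """One segment of a (nearly) motionless subject."""
    rng = np.random.default_rng(seed)
    frames = np.tile(base_posture(), (n_frames, 1, 1))
    if jitter:
        frames = frames + rng.normal(0, jitter, frames.shape)
    return SkeletonRecording(segments=[frames], subject_id="stand")


def translating_recording(z_offsets: np.ndarray) -> SkeletonRecording:
    """Rigid whole-body translation along z following ``z_offsets``."""
    frames = np.tile(base_posture(), (len(z_offsets), 1, 1))
    frames[:, :, 2] += np.asarray(z_offsets, dtype=float)[:, None]
    return SkeletonRecording(segments=[frames], subject_id="translate")


@pytest.fixture(scope="session")
def clean_walk():
    """Noise-free, outlier-free calibrated walk (controls preset)."""
    spec = calibrated_walk_spec(
        0.54, 0.81, leg_length=0.785, seed=7, noise_sd=0.0, outlier_rate=0.0
    )
    rec, truth = simulate_walk(spec)
    return spec, rec, truth


@pytest.fixture(scope="session")
def noisy_walk():
    """5 mm sensor noise, occasional gross-error frames."""
    spec = calibrated_walk_spec(
        0.54, 0.81, leg_length=0.785, seed=7, noise_sd=0.005, outlier_rate=0.01
    )
    rec, truth = simulate_walk(spec)
    return spec, rec, truth


@pytest.fixture()
def standing():
    return standing_recording()
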