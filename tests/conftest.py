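import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from filmgaze import (
    FrameGaze,
    ScreenGeometry,
    ShotIndex,
    SyntheticCohortConfig,
    generate_cohort,
    resample_to_frames,
)

settings.register_profile(
    "fixed",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("fixed")


@pytest.fixture(scope="session")
def geometry():
    """NTSC-video viewing geometry: 720x480 px, 21.42x16.10 deg, 30 fps."""
    return ScreenGeometry(720, 480, 21.42, 16.10, 30.0)


@pytest.fixture(scope="session")
def six_shots():
    """Six 1-second shots (180 frames at 30 fps) — compact test clip."""
    return ShotIndex((i + 1, i * 30, (i + 1) * 30) for i in range(6))


def make_cohort_config(sigma_deg, seed, n_viewers=8, shots=None, **kw):
    shots = shots or ShotIndex((i + 1, i * 30, (i + 1) * 30) for i in range(6))
    return SyntheticCohortConfig(
        shots=shots,
        n_viewers=n_viewers,
        synchrony_sigma_deg=sigma_deg,
        seed=seed,
        **kw,
    )


def make_frame_gaze(sigma_deg, seed, n_viewers=8, shots=None, **kw):
    """Synthetic cohort resampled to frames — the pipeline's working currency."""
    gs = generate_cohort(make_cohort_config(sigma_deg, seed, n_viewers, shots, **kw))
    return resample_to_frames(gs)


def random_frame_gaze(geometry, n_participants, n_frames, seed, p_valid=0.9):
    """Small random FrameGaze for oracle-equivalence checks."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, geometry.width_px, (n_participants, n_frames))
    y = rng.uniform(0, geometry.height_px, (n_participants, n_frames))
    valid = rng.random((n_participants, n_frames)) < p_valid
    # every participant keeps at least one valid frame
    for p in range(n_participants):
        if not valid[p].any():
            valid[p, rng.integers(n_frames)] = True
    x[~valid] = np.nan
    y[~valid] = np.nan
    parts = [f"p{i}" for i in range(n_participants)]
    return FrameGaze(geometry, parts, x, y, valid)
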