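"""Shared fixtures: toy linear systems, a mid-sized seeded system, a cohort study."""

from __future__ import annotations

import numpy as np
import pytest

import megres as m
from megres.config import StudyConfig
from megres.pipeline import run_study


def random_spd(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric positive-definite matrix (exactly symmetric)."""
    a = rng.normal(size=(n, n))
    c = a @ a.T + n * np.eye(n)
    return 0.5 * (c + c.T)


def make_noise(matrix: np.ndarray, n_averages: int = 1) -> m.NoiseCovariance:
    return m.NoiseCovariance(matrix=matrix, n_samples_used=matrix.shape[0] + 1,
                             n_averages=n_averages)


def line_source_space(spacing_cm: float = 1.0, n: int = 3) -> m.SourceSpace:
    """Collinear sources spaced along x, for hand-checkable metric arithmetic."""
    positions = np.zeros((n, 3))
    positions[:, 0] = spacing_cm / 100.0 * np.arange(n)
    positions[:, 2] = 0.01  # keep strictly inside the conductor
    orientations = np.tile([0.0, 0.0, 1.0], (n, 1))
    radii = np.linalg.norm(positions, axis=1)
    return m.SourceSpace(
        positions=positions,
        orientations=orientations,
        depth=0.09 - radii,
        conductor_radius=0.09,
    )


def random_system(seed: int, n_ch: int = 8, n_src: int = 20):
    """Random leadfield + SPD covariance + folded source space of matching size."""
    rng = np.random.default_rng(seed)
    src = m.make_source_space(n_src, 0.09, 0.03, 6, seed=seed)
    L = m.Leadfield(matrix=rng.normal(size=(n_ch, n_src)))
    noise = make_noise(random_spd(rng, n_ch))
    return L, noise, src


@pytest.fixture(scope="session")
def helmet306():
    """Full 306-channel helmet (102 magnetometers + 204 planar gradiometers)."""
    return m.make_sensor_array(102, 204, 0.12, seed=1)


@pytest.fixture(scope="session")
def physical_system(helmet306):
    """306-channel helmet, 400-source folded shell, leadfield and covariance."""
    src = m.make_source_space(400, 0.09, 0.03, 6, seed=2)
    L = m.build_leadfield(helmet306, src)
    cov = m.simulate_noise_covariance(helmet306, L, n_trials=146,
                                      baseline_duration=0.2, sampling_rate=250.0,
                                      brain_noise_fraction=0.5, seed=5)
    return helmet306, src, L, cov


@pytest.fixture(scope="session")
def cohort_study():
    """Seventeen-subject cohort study at 500 sources, all methods and modes."""
    config = StudyConfig(n_subjects=17, n_sources=500, master_seed=7,
                         jitter_scale=0.002)
    return run_study(config, write=False)
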