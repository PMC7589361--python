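import numpy as np
import pytest

from recline.data import Episode
from recline.synthetic import SimulationConfig, simulate_dataset


def make_episode(
    samples,
    *,
    subject="S1",
    site="chest",
    posture="supine",
    rate=25.0,
):
    return Episode(
        subject_id=subject,
        body_site=site,
        posture=posture,
        sampling_rate_hz=rate,
        samples=np.asarray(samples, dtype=float),
    )


def constant_episode(vec, n, **kw):
    return make_episode(np.tile(np.asarray(vec, dtype=float), (n, 1)), **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def noise_free_chest():
    """Zero-noise chest dataset: samples equal the orientation table."""
    cfg = SimulationConfig(
        seed=7,
        n_subjects=4,
        episodes_per_posture=1,
        sites=("chest",),
        sampling_rate_hz=20.0,
        jitter_sd=0.0,
        subject_rotation_sd_deg=0.0,
        movement_burst_rate_per_min=0.0,
    )
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_chest():
    """Default-noise chest dataset at reduced scale for fast model tests."""
    cfg = SimulationConfig(
        seed=21,
        n_subjects=6,
        episodes_per_posture=1,
        sites=("chest",),
        sampling_rate_hz=15.0,
        duration_mean_s=8.0,
        duration_sd_s=1.5,
    )
    return simulate_dataset(cfg)
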