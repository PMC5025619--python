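import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from plaquemark.caga import CAGAConfig
from plaquemark.features import build_feature_matrix, extract_pixel_vector
from plaquemark.phantom import PhantomConfig, generate_dataset
from plaquemark.pipeline import ExperimentConfig
from plaquemark.voting import VotingConfig

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def tiny_phantom_config(**overrides) -> PhantomConfig:
    """A fast, small phantom for unit tests (12 slices, ~150 in-mask pixels)."""
    defaults = dict(
        n_ad_subjects=3,
        n_ctl_subjects=3,
        slices_per_subject=2,
        image_size=32,
        brain_shape=(6.0, 8.0),
        plaque_count_per_slice=2,
        plaque_radius=1.5,
        plaque_position_jitter=0.5,
        noise_sigma=7.5,
        seed=7,
    )
    defaults.update(overrides)
    return PhantomConfig(**defaults)


def tiny_experiment_config(**overrides) -> ExperimentConfig:
    defaults = dict(
        phantom=tiny_phantom_config(),
        caga=CAGAConfig(population_size=10, elite_count=10, max_iterations=5, seed=0),
        voting=VotingConfig(k=3, t_select=2),
        n_split_repeats=2,
        test_composition=(3, 3),
        master_seed=5,
    )
    defaults.update(overrides)
    return ExperimentConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_dataset():
    return generate_dataset(tiny_phantom_config())


@pytest.fixture(scope="session")
def tiny_matrix(tiny_dataset):
    images, _ = tiny_dataset
    vectors = [extract_pixel_vector(im) for im in images]
    matrix = build_feature_matrix(vectors, [im.label for im in images])
    return vectors, matrix
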