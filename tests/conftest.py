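import numpy as np
import pandas as pd
import pytest

from extrurtd.rtd_core import TracerSeries
from extrurtd.texture_synth import SynthDatasetSpec, generate_dataset, generate_fixture_images


@pytest.fixture
def pulse_series() -> TracerSeries:
    """Single-segment pulse: all mass at t=10 of {0, 10, 20}."""
    return TracerSeries(np.array([0.0, 10.0, 20.0]), np.array([0.0, 1.0, 0.0]))


@pytest.fixture
def plateau_series() -> TracerSeries:
    return TracerSeries(
        np.array([0.0, 10.0, 20.0, 30.0]), np.array([0.0, 2.0, 2.0, 0.0])
    )


@pytest.fixture(scope="session")
def clean_dataset() -> pd.DataFrame:
    """118-row noiseless synthetic feature/texture table."""
    return generate_dataset(SynthDatasetSpec(n_samples=118, noise_sd=0.0, seed=11))


@pytest.fixture(scope="session")
def noisy_dataset() -> pd.DataFrame:
    return generate_dataset(SynthDatasetSpec(n_samples=118, noise_sd=0.5, seed=12))


@pytest.fixture(scope="session")
def fixture_images(tmp_path_factory):
    """Small directory of flat + checkerboard tiles with analytic truth."""
    out = tmp_path_factory.mktemp("tiles")
    truth = generate_fixture_images(out, n_flat=3, n_checker=1, size=(64, 48), seed=3)
    return out, truth


def random_series(rng: np.random.Generator, n: int = 30) -> TracerSeries:
    """Helper for property tests: positive-mass series on an uneven grid."""
    times = np.cumsum(rng.uniform(1.0, 15.0, n))
    conc = rng.uniform(0.0, 0.4, n)
    conc[rng.integers(0, n)] += 0.1  # guarantee mass
    return TracerSeries(times, conc)
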