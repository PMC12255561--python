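import numpy as np
import pytest

from fairasl import (
    PhantomSpec,
    RespirationModel,
    build_phantom,
    fit_series,
    plan_motion_free_tis,
    simulate_series,
)


@pytest.fixture(scope="session")
def model():
    return RespirationModel()


@pytest.fixture(scope="session")
def schedule14(model):
    return plan_motion_free_tis(model, 14, 100, 5500)


@pytest.fixture(scope="session")
def small_spec():
    # reduced grid keeps per-test fit time low while preserving the topology
    # (5 lobes, vessels, muscle, background)
    return PhantomSpec(shape=(48, 48), seed=0)


@pytest.fixture(scope="session")
def small_truth(small_spec):
    return build_phantom(small_spec)


@pytest.fixture(scope="session")
def clean_series_small(small_truth, schedule14):
    return simulate_series(small_truth, schedule14, noise_sigma=0.0)


@pytest.fixture(scope="session")
def clean_fits_small(clean_series_small):
    return {
        mode: fit_series(clean_series_small, mode)
        for mode in ("label", "control")
    }


@pytest.fixture(scope="session")
def noisy_series_small(small_truth, schedule14):
    return simulate_series(small_truth, schedule14, noise_sigma=0.02, seed=11)
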