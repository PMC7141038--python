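import numpy as np
import pytest

from spheromigrate import SpheroidParams, generate_spheroid_stack

MIDPOINT = (200.0 + 20.0) / 2  # fixed threshold between default fg/bg levels


def small_params(**overrides) -> SpheroidParams:
    """Compact, fast noise-free geometry used throughout the unit tests."""
    fields = dict(
        shape=(10, 64, 64),
        core_radius=4.0,
        n_sprouts=3,
        sprout_length_mean=12.0,
        sprout_length_sd=2.0,
        sprout_width=3.0,
        n_single=5,
        single_radius=2.0,
        single_dist_range=(20.0, 26.0),
        noise_sd=0.0,
        seed=7,
    )
    fields.update(overrides)
    return SpheroidParams(**fields)


@pytest.fixture(scope="session")
def clean_stack_and_truth():
    return generate_spheroid_stack(small_params())


@pytest.fixture()
def rng():
    return np.random.default_rng(20260927)
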