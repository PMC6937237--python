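import numpy as np
import pytest

from rgpipe import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Small, fast cohort with a clear texture signal for integration tests."""
    cfg = SyntheticConfig(
        n_patients=12,
        class_proportions=(1 / 3, 1 / 3, 1 / 3),
        texture_effect=3.0,
        age_effect=8.0,
        volume_shape=(32, 32, 20),
        seed=11,
    )
    return cfg, generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
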