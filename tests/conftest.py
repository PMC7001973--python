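import numpy as np
import pytest

from clawcurve.simulate import default_group_specs, generate_extant, generate_fossils


@pytest.fixture(scope="session")
def dataset():
    """Default four-group synthetic extant dataset, 30 claws per group."""
    return generate_extant(seed=12345)


@pytest.fixture(scope="session")
def big_dataset():
    """Larger synthetic sample for calibration-style checks."""
    return generate_extant(default_group_specs(n_per_group=120), seed=54321)


@pytest.fixture(scope="session")
def fossil_sample():
    fossils, truths = generate_fossils(n_per_category=8, sheath_missing_prob=0.5, seed=777)
    return fossils, truths


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
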