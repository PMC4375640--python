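import numpy as np
import pytest

from connmvpa import SyntheticSpec, generate_dataset, load_region_table


@pytest.fixture(scope="session")
def aal116():
    return load_region_table()


@pytest.fixture(scope="session")
def tiny_study():
    """Small separable two-group study used across test modules."""
    spec = SyntheticSpec(
        n_regions=12, group_sizes={"patient": 10, "control": 10},
        n_planted=4, delta=3.5, density=0.5, seed=7,
    )
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def three_group_study():
    spec = SyntheticSpec(
        n_regions=20, group_sizes={"left": 10, "right": 10, "control": 12},
        n_planted=6, delta=3.0, density=0.4, seed=11,
    )
    return generate_dataset(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
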