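import numpy as np
import pytest

from submem import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete cohort shared by read-only tests."""
    spec = CohortSpec(
        n_subjects=6,
        n_items=12,
        n_scrambled=4,
        grid_shape=(10, 10, 6),
        n_networks=3,
        n_linked_networks=1,
        seed=42,
    )
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
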