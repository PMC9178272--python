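import numpy as np
import pytest

from ymi.synthetic import PopulationSpec, generate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but fully featured synthetic cohort shared across tests.

    5 genotypes × 2 conditions × 2 sexes, 25 flies per cell, modest
    activity so sequence simulation stays cheap.
    """
    spec = PopulationSpec(
        n_flies_per_group=25,
        genotypes=tuple(f"line{i:02d}" for i in range(1, 6)),
        conditions=("normal", "5htppotato25"),
        sexes=("female", "male"),
        turns_mean=80.0,
        seed=7,
    )
    return generate_cohort(spec)
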