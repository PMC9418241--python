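import numpy as np
import pytest

from epibayes.simulate import SyntheticSpec, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Well-separated 3-class cohort used by training and pipeline tests."""
    spec = SyntheticSpec(
        n_classes=3,
        samples_per_class=(40, 40, 40),
        n_genes=20,
        n_informative=5,
        mean_shift=4.0,
        noise_sd=1.0,
        seed=11,
    )
    return spec, generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
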