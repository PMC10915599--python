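import numpy as np
import pytest

from mocogcn import TrainConfig, generate_cohort, hide_labels


@pytest.fixture(scope="session")
def small_cohort():
    """Separable toy cohort: 20+20 samples, 30 species (5 planted), 10 exposures."""
    return generate_cohort(
        n_case=20, n_control=20, d_species=30, d_exposome=10,
        n_inf_species=5, n_inf_exposome=2,
        species_effect=3.0, exposure_effect=0.3, seed=1,
    )


@pytest.fixture(scope="session")
def small_config():
    """Training budget for toy cohorts: enough to converge, fast to run."""
    return TrainConfig(k=4, pretrain_epochs=50, joint_epochs=30,
                       max_rounds=25, seed=3)


@pytest.fixture(scope="session")
def half_labeled(small_cohort):
    return hide_labels(small_cohort, 0.5, seed=2)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
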