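import numpy as np
import pytest

from junctionzone import TrialConfig, fit_normative, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """Desk-scale trial: 5 eyes/arm on a coarse 100x100 grid."""
    return TrialConfig(n_per_arm=5, pixel_pitch_deg=0.2, n_normative=12, seed=42)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def norm_model(small_cohort):
    return fit_normative(small_cohort.normative.maps, small_cohort.normative.ages)


@pytest.fixture()
def rng():
    return np.random.default_rng(20220425)
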