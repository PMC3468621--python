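import numpy as np
import pytest

from illposed.synthetic_cohort import (
    CohortConfig,
    VolumeGrid,
    default_effect_region,
    make_template,
    simulate_cohort,
)


@pytest.fixture(scope="session")
def grid16():
    return VolumeGrid(dims=(16, 16, 16))


@pytest.fixture(scope="session")
def template16(grid16):
    return make_template(grid16, seed=11)


@pytest.fixture(scope="session")
def effect_region16(template16):
    return default_effect_region(template16, fraction=0.5)


@pytest.fixture(scope="session")
def cohort_cfg16(effect_region16):
    return CohortConfig(
        n_cn=20,
        n_ad=20,
        effect_region=effect_region16,
        effect_size=1.0,
        noise_sd=0.25,
        smoothing_fwhm_vox=1.0,
        seed=101,
    )


@pytest.fixture(scope="session")
def cohort16(template16, cohort_cfg16):
    return simulate_cohort(template16, cohort_cfg16)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
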