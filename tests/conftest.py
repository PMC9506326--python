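import numpy as np
import pytest

from hydrohaw import Sex
from hydrohaw.cohort import CohortConfig, cohort_to_frame, make_study


@pytest.fixture(scope="session")
def male_study():
    """A small male derivation/validation study at study-sized cohorts."""
    exp_cfg = CohortConfig(sex=Sex.MALE, n=44, seed=2024, group="exp")
    val_cfg = CohortConfig(sex=Sex.MALE, n=21, seed=2025, group="val")
    exp, val, truth = make_study(exp_cfg, val_cfg)
    return cohort_to_frame(exp), cohort_to_frame(val), truth


@pytest.fixture
def rng():
    return np.random.default_rng(17)
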