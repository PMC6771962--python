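import numpy as np
import pytest

from rfduq import Metric, reference_values as ref
from rfduq.calibration import fit_loglog
from rfduq.synthetic_data import (
    default_tsh_params,
    generate_tsh_cohort,
    population_fit,
)


@pytest.fixture(scope="session")
def tcdd_params():
    return default_tsh_params()


@pytest.fixture(scope="session")
def teq_params():
    return default_tsh_params(metric=Metric.TEQ)


@pytest.fixture(scope="session")
def population_fits(tcdd_params, teq_params):
    """Fixed-design calibration fits for both exposure metrics."""
    return {
        Metric.TCDD: population_fit(tcdd_params),
        Metric.TEQ: population_fit(teq_params),
    }


@pytest.fixture(scope="session")
def sampled_fit(tcdd_params):
    pairs, _ = generate_tsh_cohort(tcdd_params, seed=11)
    return fit_loglog(pairs)


@pytest.fixture(scope="session")
def anchor():
    return ref.ANCHOR


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
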