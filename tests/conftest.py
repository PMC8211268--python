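import numpy as np
import pandas as pd
import pytest

from mammosim.constants import DENSITY_CATS, PERF_AGE_BANDS, STAGES, SUBTYPES
from mammosim.fixtures import make_default_parameters
from mammosim.population import AVERAGE_RISK, Woman
from mammosim.screening import PerformanceTable


@pytest.fixture(scope="session")
def default_params():
    return make_default_parameters("hazard_reduction", seed=1)


@pytest.fixture(scope="session")
def cure_params():
    return make_default_parameters("cure_fraction", seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_woman(
    wid=0,
    birth_year=1970,
    death_age=90.0,
    density="b",
    risk_multiplier=1.0,
):
    return Woman(
        id=wid,
        birth_year=birth_year,
        other_cause_death_age=death_age,
        density_at={40: density, 50: density, 65: density},
        risk_multiplier=risk_multiplier,
    )


@pytest.fixture
def woman():
    return make_woman()


def constant_incidence_params(rate_per_100k, base_params):
    """Copy of the default ParameterSet with a flat incidence table."""
    import copy

    p = copy.copy(base_params)
    tbl = base_params.incidence_table
    p.incidence_table = pd.DataFrame(
        np.full(tbl.shape, float(rate_per_100k)), index=tbl.index, columns=tbl.columns
    )
    return p


@pytest.fixture
def flat_performance():
    """Interval/first/density-independent performance (for paired-schedule
    monotonicity checks, where shared draws must decide identically)."""
    return PerformanceTable.constant(0.8, 0.9)
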