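import numpy as np
import pytest

from orcurve import ScenarioConfig, assemble_cohort, draw_base

SEED = 11

N_UNIT = 100_000  # moderate cohorts for distributional unit tests
N_FULL = 1_000_000  # full-size cohorts for the acceptance properties


@pytest.fixture(scope="session")
def base_unit():
    """Shared base draws (covariates, inclusion, error quantiles) at
    moderate size; assembled into scenario cohorts by the tests."""
    return draw_base(ScenarioConfig(n=N_UNIT, seed=SEED))


@pytest.fixture(scope="session")
def base_full():
    """Full-size shared base draws for the acceptance-scale checks."""
    return draw_base(ScenarioConfig(n=N_FULL, seed=SEED))


def assemble(base, **kwargs):
    return assemble_cohort(base, base.config.replace(**kwargs))


@pytest.fixture(scope="session")
def linear_strong_unit(base_unit):
    """Linear shape, strong effect, moderate error, at unit-test size."""
    return assemble(base_unit, shape="linear", beta1=0.5, sigma2_w1=0.25)
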