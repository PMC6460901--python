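import numpy as np
import pytest

from dtsmed import DesignCondition, build_design, simulate_dataset
from dtsmed.simulator import MediationParams, baseline_logit


@pytest.fixture(scope="session")
def design():
    return build_design()


@pytest.fixture(scope="session")
def design_index(design):
    """Lookup from (J, n, a, b_or, c_or, h0) to the design cell."""
    return {(c.J, c.n, c.a, c.b_or, c.c_or, c.h0): c for c in design}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_params(a=0.39, b_or=2.0, c_or=1.0, h0=0.2, J=8, **kw) -> MediationParams:
    return MediationParams(
        a=a, b_or=b_or, c_or=c_or, beta02=baseline_logit(h0), J=J, **kw
    )


@pytest.fixture(scope="session")
def medium_dataset():
    """One n=500 dataset with moderate effects, shared across read-only tests."""
    cond = DesignCondition(id=0, J=8, n=500, a=0.39, b_or=2.0, c_or=1.5, h0=0.2)
    return simulate_dataset(cond, np.random.SeedSequence([9, 0, 1]))
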