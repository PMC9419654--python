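import math

import numpy as np
import pytest

from msldiff import (InitialLaw, PolynomialCoefficients, ProcessParams,
                     case_params, make_case_panel, simulate_paths)

# reference configuration used throughout: the non-monotone cubic curve
BETA_REF = (0.1, -0.009, 0.0002)
ETA_REF = math.exp(-1)
SIGMA_REF = 0.01


@pytest.fixture(scope="session")
def params_ref() -> ProcessParams:
    return ProcessParams(eta=ETA_REF,
                         beta=PolynomialCoefficients(BETA_REF),
                         sigma2=SIGMA_REF ** 2)


@pytest.fixture(scope="session")
def case1_panel():
    """Moderate-size panel from the reference process (50 paths, 201 times)."""
    return make_case_panel(1, n_paths=50, n_times=201, seed=3)


@pytest.fixture(scope="session")
def small_panel(params_ref):
    """Small ragged-friendly panel for fast unit tests."""
    times = np.linspace(0.0, 50.0, 26)
    return simulate_paths(params_ref, InitialLaw.degenerate(5.0), times,
                          n_paths=8, seed=11)


@pytest.fixture(scope="session")
def lognormal_init_panel(params_ref):
    """Panel with a genuinely lognormal initial state."""
    times = np.linspace(0.0, 50.0, 26)
    return simulate_paths(params_ref, InitialLaw.lognormal(math.log(5.0), 0.02),
                          times, n_paths=12, seed=19)
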