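import numpy as np
import pytest

from gbmwave import GrowthDeathModel
from gbmwave.pde import comparison_grid

ACCEPTANCE_RHO_HATS = np.arange(0.5, 5.01, 0.5)


@pytest.fixture(scope="session")
def linear_model():
    return GrowthDeathModel.from_preset("linear")


@pytest.fixture(scope="session")
def reference_model():
    return GrowthDeathModel()  # sigmoidal birth, cubic concave death


def closed_form_p(rho_hat):
    """Analytic profile for linear responses g(w)=w, delta(w)=1-w:
    p(w) = (1-w)(1+1/rho_hat) + ln(w)/rho_hat."""

    def p(w):
        w = np.asarray(w, dtype=float)
        return (1.0 - w) * (1.0 + 1.0 / rho_hat) + np.log(w) / rho_hat

    return p


@pytest.fixture(scope="session")
def fig5_grid(reference_model):
    """Approximation-vs-simulation sweep used by several acceptance checks.

    One PDE run per rho_hat in 0.5..5 step 0.5, with speed-scaled domains.
    """
    return comparison_grid(ACCEPTANCE_RHO_HATS, reference_model)
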