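import numpy as np
import pytest

from trisurv import FamilySpec, ModelSpec, ParameterVector


@pytest.fixture
def exp_exp_model():
    """Exponential-exponential model without covariates."""
    return ModelSpec(FamilySpec("exponential"), FamilySpec("exponential"))


@pytest.fixture
def exp_exp_psi(exp_exp_model):
    """Low-incidence rates typical of adenoma surveillance."""
    return ParameterVector(exp_exp_model, np.array([0.03]), np.array([0.04]))


@pytest.fixture
def weib_weib_model():
    return ModelSpec(FamilySpec("weibull"), FamilySpec("weibull"))


@pytest.fixture
def weib_weib_psi(weib_weib_model):
    """Weibull-Weibull generating values from the simulation grid (M13)."""
    return ParameterVector(weib_weib_model,
                           np.array([1.5, 23.0]), np.array([0.8, 28.0]))


@pytest.fixture
def final_model_spec():
    """Structure of the published final model: Weibull X with an
    adenoma-type covariate, covariate-free Weibull Y."""
    return ModelSpec(FamilySpec("weibull", ("at",)), FamilySpec("weibull"))


@pytest.fixture
def final_model_psi(final_model_spec):
    """Published final-model estimates on the working scale:
    log shape1, intercept, adenoma-type coefficient; log shape2, log scale2."""
    working = np.array([-1.646, 12.561, 1.081, -2.153, 18.087])
    return ParameterVector.from_working(final_model_spec, working)


def exp_exp_conv_closed_form(lam1, lam2, a, b):
    """Closed-form int_a^b lam1 e^{-lam1 x} e^{-lam2 (b-x)} dx.

    This equals the AA-branch probability integrand for the
    exponential-exponential model; series branch at lam1 == lam2.
    """
    d = lam1 - lam2
    if abs(d) < 1e-8:
        # limit: lam1 (b - a) e^{-lam1 b} with first-order series correction
        mid = np.exp(-lam2 * b)
        return lam1 * mid * (b - a) * (1.0 - 0.5 * d * (a + b)) \
            + lam1 * mid * d ** 2 * (b ** 3 - a ** 3) / 6.0
    return lam1 * np.exp(-lam2 * b) * (np.exp(-d * a) - np.exp(-d * b)) / d
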