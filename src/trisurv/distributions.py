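"""Parametric proportional-hazards time-to-event families.

Three baseline families are supported for each transition time:

* ``exponential`` — constant hazard ``lam``;
* ``weibull`` — cumulative hazard ``(t / theta) ** kappa``;
* ``gompertz`` — hazard ``lam * exp(gamma * t)``.

Covariates act multiplicatively on the hazard (proportional hazards): with
coefficient vector ``c`` and covariates ``w`` the cumulative hazard is
``H0(t) * exp(c @ w)``.  When a family carries covariates, its scale-type
baseline parameter is reported as a log-scale *intercept*: for the
exponential the hazard is ``exp(a0 + c @ w)`` (so ``lam = exp(a0)``), for
the Weibull ``theta = exp(a0)`` so that ``H(t|w) = (t/exp(a0))**kappa *
exp(c @ w)``, and for the Gompertz the baseline rate is ``exp(a0)``.  Under
this parameterization ``exp(c_j)`` is the constant hazard ratio for a unit
increase in covariate ``j``.

Estimation happens on a *working* scale: positive parameters (rates, shapes,
scales) through their natural logarithm, the Gompertz shape and regression
coefficients unconstrained.  ``to_working``/``from_working`` are mutually
inverse.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FamilySpec",
    "cumulative",
    "density",
    "survival",
    "hazard",
    "cumulative_hazard",
    "inverse_cumulative_hazard",
    "hazard_multiplier",
    "to_working",
    "from_working",
]

_FAMILIES = ("exponential", "weibull", "gompertz")
_N_BASELINE = {"exponential": 1, "weibull": 2, "gompertz": 2}


@dataclass(frozen=True)
class FamilySpec:
    """Specification of one transition-time distribution.

    Parameters
    ----------
    family : {"exponential", "weibull", "gompertz"}
        Baseline hazard family.
    covariates : tuple of str
        Names of covariate columns whose coefficients enter the hazard
        multiplicatively.  Empty tuple means no covariates.
    """

    family: str
    covariates: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; choose from {_FAMILIES}")
        object.__setattr__(self, "covariates", tuple(self.covariates))

    @property
    def has_covariates(self) -> bool:
        return len(self.covariates) > 0

    @property
    def n_baseline(self) -> int:
        return _N_BASELINE[self.family]

    @property
    def n_params(self) -> int:
        return self.n_baseline + len(self.covariates)

    def param_names(self, prefix: str = "", working: bool = True) -> list[str]:
        """Parameter labels, in storage order."""
        if self.family == "exponential":
            base = ["intercept"] if self.has_covariates else (
                ["log_rate"] if working else ["rate"])
        elif self.family == "weibull":
            scale = "intercept" if self.has_covariates else (
                "log_scale" if working else "scale")
            base = ["log_shape" if working else "shape", scale]
        else:  # gompertz
            rate = "intercept" if self.has_covariates else (
                "log_rate" if working else "rate")
            base = [rate, "shape"]
        return [prefix + b for b in base] + [prefix + c for c in self.covariates]


def _check_params(spec: FamilySpec, params: np.ndarray) -> np.ndarray:
    params = np.asarray(params, dtype=float)
    if params.shape != (spec.n_params,):
        raise ValueError(
            f"expected {spec.n_params} parameters for {spec.family} with "
            f"{len(spec.covariates)} covariate(s), got shape {params.shape}")
    if spec.family == "exponential":
        if params[0] <= 0:
            raise ValueError("exponential rate must be positive")
    elif spec.family == "weibull":
        if params[0] <= 0 or params[1] <= 0:
            raise ValueError("weibull shape and scale must be positive")
    else:
        if params[0] <= 0:
            raise ValueError("gompertz baseline rate must be positive")
    return params


def _split(spec: FamilySpec, params: np.ndarray):
    return params[: spec.n_baseline], params[spec.n_baseline:]


def hazard_multiplier(coefs, w) -> float:
    """Proportional-hazards multiplier ``exp(coefs @ w)``.

    ``coefs`` excludes the intercept.  Equals 1 for empty coefficients or
    a zero covariate vector.
    """
    coefs = np.atleast_1d(np.asarray(coefs, dtype=float))
    w = np.atleast_1d(np.asarray(w, dtype=float))
    if coefs.size == 0:
        return 1.0
    if coefs.shape != w.shape:
        raise ValueError(f"coefficient/covariate length mismatch: {coefs.shape} vs {w.shape}")
    return float(np.exp(coefs @ w))


def _baseline_cumhaz(spec: FamilySpec, base: np.ndarray, t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if spec.family == "exponential":
        return base[0] * t
    if spec.family == "weibull":
        kappa, theta = base
        return (t / theta) ** kappa
    lam, gamma = base
    if gamma == 0.0:
        return lam * t
    return lam * np.expm1(gamma * t) / gamma


def _baseline_hazard(spec: FamilySpec, base: np.ndarray, t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    if spec.family == "exponential":
        return np.broadcast_to(base[0], t.shape).astype(float) if t.shape else float(base[0])
    if spec.family == "weibull":
        kappa, theta = base
        with np.errstate(divide="ignore"):
            return (kappa / theta) * (t / theta) ** (kappa - 1.0)
    lam, gamma = base
    return lam * np.exp(gamma * t)


def _baseline_cumhaz_inv(spec: FamilySpec, base: np.ndarray, s):
    """Inverse of the baseline cumulative hazard (s >= 0)."""
    s = np.asarray(s, dtype=float)
    if spec.family == "exponential":
        return s / base[0]
    if spec.family == "weibull":
        kappa, theta = base
        return theta * s ** (1.0 / kappa)
    lam, gamma = base
    if gamma == 0.0:
        return s / lam
    with np.errstate(invalid="ignore"):
        arg = gamma * s / lam
        out = np.log1p(arg) / gamma
    # improper gompertz (gamma < 0): hazard integrates to lam/|gamma|;
    # larger s is never reached
    return np.where(np.isnan(out), np.inf, out) if out.ndim else (
        np.inf if np.isnan(out) else float(out))


def cumulative_hazard(spec: FamilySpec, params, t, w=()):
    """Covariate-conditional cumulative hazard H(t|w)."""
    params = _check_params(spec, params)
    base, coefs = _split(spec, params)
    return _baseline_cumhaz(spec, base, t) * hazard_multiplier(coefs, w)


def inverse_cumulative_hazard(spec: FamilySpec, params, s, w=()):
    """Solve H(t|w) = s for t."""
    params = _check_params(spec, params)
    base, coefs = _split(spec, params)
    return _baseline_cumhaz_inv(spec, base, np.asarray(s, float) / hazard_multiplier(coefs, w))


def cumulative(spec: FamilySpec, params, t, w=()):
    """CDF F(t|w) = 1 - exp(-H(t|w))."""
    return -np.expm1(-cumulative_hazard(spec, params, t, w))


def survival(spec: FamilySpec, params, t, w=()):
    """Survival function 1 - F(t|w)."""
    return np.exp(-cumulative_hazard(spec, params, t, w))


def density(spec: FamilySpec, params, t, w=()):
    """PDF f(t|w) = h(t|w) exp(-H(t|w)), per year."""
    params = _check_params(spec, params)
    base, coefs = _split(spec, params)
    m = hazard_multiplier(coefs, w)
    return _baseline_hazard(spec, base, t) * m * np.exp(-_baseline_cumhaz(spec, base, t) * m)


def hazard(spec: FamilySpec, params, t, w=()):
    """Hazard function h(t|w)."""
    params = _check_params(spec, params)
    base, coefs = _split(spec, params)
    return _baseline_hazard(spec, base, t) * hazard_multiplier(coefs, w)


def to_working(spec: FamilySpec, params) -> np.ndarray:
    """Map natural-scale parameters to the unconstrained working scale."""
    params = _check_params(spec, params)
    base, coefs = _split(spec, params)
    if spec.family == "gompertz":
        wbase = np.array([np.log(base[0]), base[1]])
    else:
        wbase = np.log(base)
    return np.concatenate([wbase, coefs])


def from_working(spec: FamilySpec, working) -> np.ndarray:
    """Inverse of :func:`to_working`."""
    working = np.asarray(working, dtype=float)
    if working.shape != (spec.n_params,):
        raise ValueError(f"expected {spec.n_params} working parameters, got {working.shape}")
    base, coefs = _split(spec, working)
    if spec.family == "gompertz":
        nbase = np.array([np.exp(base[0]), base[1]])
    else:
        nbase = np.exp(base)
    return np.concatenate([nbase, coefs])


def check_proper(spec: FamilySpec, params) -> bool:
    """Return True when F(t) -> 1 as t -> inf; warn otherwise.

    Only the Gompertz with negative shape is improper (a fraction
    ``exp(-lam/|gamma|)`` never transitions).
    """
    params = _check_params(spec, params)
    if spec.family == "gompertz" and params[1] < 0:
        lam, gamma = params[0], params[1]
        limit = -np.expm1(lam / gamma)
        warnings.warn(
            f"gompertz with negative shape is improper: F(inf) = {limit:.4f} < 1",
            UserWarning, stacklevel=2)
        return False
    return True
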