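"""Maximum-likelihood fitting of the progressive three-state model.

The public surface follows the statsmodels idiom: :class:`ThreeStateModel`
is built from a record-layout DataFrame and a pair of
:class:`~trisurv.distributions.FamilySpec` objects; ``fit()`` maximizes the
joint log-likelihood on the working (log) scale and returns a
:class:`ThreeStateResults` carrying estimates, standard errors from the
inverse observed information, Wald intervals, information criteria and
convergence diagnostics.

A run is *successful* when the optimizer converged and the negative Hessian
at the optimum is positive definite; a fit that converges to a point where
the Hessian fails the Cholesky test is reported with ``hessian_pd = False``
(false convergence) rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.tools import numdiff

from .distributions import FamilySpec
from .likelihood import (
    ModelSpec,
    ParameterVector,
    loglik_vector,
    records_to_frame,
    validate_records,
)

__all__ = [
    "ThreeStateModel",
    "ThreeStateResults",
    "backward_stepwise",
    "information_criteria",
    "transform_estimate",
]


def information_criteria(loglik: float, k: int, n: int) -> tuple[float, float]:
    """(AIC, BIC) = (2k - 2*loglik, k*log(n) - 2*loglik)."""
    if k < 1 or n < 1:
        raise ValueError("need k >= 1 and n >= 1")
    return 2.0 * k - 2.0 * loglik, k * np.log(n) - 2.0 * loglik


class ThreeStateModel:
    """Progressive three-state model for interval-censored surveillance data.

    Parameters
    ----------
    records : pandas.DataFrame or iterable of SurveillanceRecord
        One row per individual: ``subject_id, v_prev, v_last, delta_aa,
        delta_crc`` plus any covariate columns referenced by the specs.
    spec_x, spec_y : FamilySpec
        Distribution families for the first (AF -> AA) and second
        (AA -> CRC) transition times.
    n_nodes : int
        Gauss-Legendre nodes for the convolution integral inside the
        vectorized log-likelihood.

    Examples
    --------
    >>> spec = FamilySpec("exponential")
    >>> model = ThreeStateModel(records, spec_x=spec, spec_y=spec)
    >>> res = model.fit()
    >>> res.params_natural
    """

    def __init__(self, records, spec_x: FamilySpec, spec_y: FamilySpec,
                 n_nodes: int = 48):
        if not isinstance(records, pd.DataFrame):
            records = records_to_frame(list(records))
        self.spec = ModelSpec(spec_x, spec_y)
        self.records = validate_records(records.reset_index(drop=True),
                                        self.spec.covariate_names)
        if len(self.records) == 0:
            raise ValueError("need at least one record")
        self.n_nodes = n_nodes

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec_x: FamilySpec,
                       spec_y: FamilySpec, **kw) -> "ThreeStateModel":
        return cls(df, spec_x, spec_y, **kw)

    # -- likelihood ---------------------------------------------------------
    @property
    def nobs(self) -> int:
        return len(self.records)

    @property
    def k_params(self) -> int:
        return self.spec.n_params

    @property
    def param_names(self) -> list[str]:
        return self.spec.param_names(working=True)

    def loglike(self, working) -> float:
        """Joint log-likelihood at a working-scale parameter vector."""
        return float(np.sum(loglik_vector(self.spec, working, self.records,
                                          n_nodes=self.n_nodes)))

    def _negloglike(self, working) -> float:
        ll = self.loglike(working)
        return 1e12 if not np.isfinite(ll) else -ll

    # -- starting values ----------------------------------------------------
    def default_start(self) -> np.ndarray:
        """Crude method-of-moments start on the working scale.

        The first-transition rate starts at events / person-time of the
        observable first transition; Weibull/Gompertz shapes start at the
        exponential submodel; covariate coefficients start at zero.
        """
        df = self.records
        n_aa = int(df["delta_aa"].sum())
        n_crc = int(df["delta_crc"].sum())
        n_events = n_aa + n_crc
        persontime = float(df["v_last"].sum())
        rate_x = max(n_events, 0.5) / max(persontime, 1e-8)
        ev = df[(df.delta_aa == 1) | (df.delta_crc == 1)]
        gap_time = float((ev["v_last"] - ev["v_prev"]).sum()) / 2.0
        rate_y = max(n_crc, 0.5) / max(gap_time + 1e-8, 1e-8)

        def block(spec: FamilySpec, rate: float) -> list[float]:
            log_rate = np.log(rate)
            if spec.family == "exponential":
                base = [log_rate]
            elif spec.family == "weibull":
                base = [0.0, -log_rate]  # shape 1, scale 1/rate
            else:
                base = [log_rate, 0.0]
            return base + [0.0] * len(spec.covariates)

        return np.array(block(self.spec.spec_x, rate_x)
                        + block(self.spec.spec_y, rate_y))

    # -- fitting ------------------------------------------------------------
    def fit(self, start=None, n_starts: int = 1, seed=None,
            maxiter: int = 10000, ftol: float = 1e-8) -> "ThreeStateResults":
        """Maximize the joint log-likelihood.

        Parameters
        ----------
        start : array-like, optional
            Working-scale starting values; default from
            :meth:`default_start`.
        n_starts : int
            Number of starting points.  The first is ``start``; subsequent
            ones jitter it with N(0, 0.5^2) noise on the working scale.
            The best converged optimum is returned.
        seed : int, optional
            Seed for the jitter stream (required for reproducible
            multi-start).
        """
        if start is None:
            start = self.default_start()
        start = np.atleast_1d(np.asarray(start, dtype=float))
        if start.shape != (self.k_params,):
            raise ValueError(
                f"start has shape {start.shape}, expected ({self.k_params},)")
        rng = np.random.default_rng(seed)

        best = None
        messages: list[str] = []
        n_used = 0
        for j in range(max(int(n_starts), 1)):
            x0 = start if j == 0 else start + rng.normal(0.0, 0.5, size=start.shape)
            n_used += 1
            try:
                opt = optimize.minimize(
                    self._negloglike, x0, method="L-BFGS-B",
                    options={"maxiter": maxiter, "ftol": ftol, "maxfun": 10 * maxiter})
            except Exception as exc:  # optimizer blow-up counts as a failed start
                messages.append(f"start {j}: {exc}")
                continue
            ll = -opt.fun
            ok = bool(opt.success) and bool(np.isfinite(ll))
            if not ok:
                messages.append(f"start {j}: {opt.message}")
            if best is None or (ok and not best[2]) or (
                    ok == best[2] and ll > best[1]):
                best = (opt, ll, ok)

        if best is None:
            k = self.k_params
            return ThreeStateResults(
                model=self, params=start, llf=-np.inf,
                cov=np.full((k, k), np.nan), bse=np.full(k, np.nan),
                aic=np.nan, bic=np.nan, converged=False, hessian_pd=False,
                n_starts_used=n_used, messages=messages)
        opt, llf, converged = best
        cov, se, hessian_pd = self._covariance(opt.x, messages)
        aic, bic = information_criteria(llf, self.k_params, self.nobs)
        return ThreeStateResults(
            model=self, params=np.asarray(opt.x, float), llf=llf,
            cov=cov, bse=se, aic=aic, bic=bic,
            converged=converged, hessian_pd=hessian_pd,
            n_starts_used=n_used, messages=messages)

    def _covariance(self, working, messages):
        """Inverse negative Hessian (central finite differences)."""
        k = self.k_params
        try:
            hess = numdiff.approx_hess3(np.asarray(working, float), self.loglike)
            neg = -hess
            np.linalg.cholesky(neg)  # PD check == the false-convergence criterion
            cov = np.linalg.inv(neg)
            cov = 0.5 * (cov + cov.T)
            se = np.sqrt(np.diag(cov))
            if not np.all(np.isfinite(se)):
                raise np.linalg.LinAlgError("non-finite standard errors")
            return cov, se, True
        except (np.linalg.LinAlgError, ValueError) as exc:
            messages.append(f"hessian not positive definite: {exc}")
            return np.full((k, k), np.nan), np.full(k, np.nan), False


@dataclass
class ThreeStateResults:
    """Estimates, uncertainty and diagnostics from :meth:`ThreeStateModel.fit`."""

    model: ThreeStateModel
    params: np.ndarray          # working scale
    llf: float
    cov: np.ndarray             # working scale
    bse: np.ndarray
    aic: float
    bic: float
    converged: bool
    hessian_pd: bool
    n_starts_used: int
    messages: list = field(default_factory=list)

    # -- views --------------------------------------------------------------
    @property
    def success(self) -> bool:
        """Successful run: optimizer converged and Hessian positive definite."""
        return self.converged and self.hessian_pd

    @property
    def names(self) -> list[str]:
        return self.model.param_names

    @property
    def psi(self) -> ParameterVector:
        return ParameterVector.from_working(self.model.spec, self.params)

    @property
    def params_series(self) -> pd.Series:
        return pd.Series(self.params, index=self.names)

    @property
    def params_natural(self) -> pd.Series:
        return self.psi.as_series(working=False)

    @property
    def nobs(self) -> int:
        return self.model.nobs

    @property
    def df_model(self) -> int:
        return self.model.k_params

    @property
    def tvalues(self) -> pd.Series:
        return pd.Series(self.params / self.bse, index=self.names)

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.names)

    def cov_params(self) -> pd.DataFrame:
        return pd.DataFrame(self.cov, index=self.names, columns=self.names)

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Working-scale Wald intervals, estimate +/- z * SE."""
        if not self.hessian_pd:
            raise ValueError("confidence intervals require a positive-definite Hessian")
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        lo = self.params - z * self.bse
        hi = self.params + z * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi}, index=self.names)

    def wald_ci(self, level: float = 0.95) -> pd.DataFrame:
        return self.conf_int(alpha=1.0 - level)

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Progressive three-state model (interval-censored ML)",
            "=" * 64,
            f"X (AF->AA): {spec.spec_x.family}"
            + (f" | covariates: {', '.join(spec.spec_x.covariates)}"
               if spec.spec_x.has_covariates else ""),
            f"Y (AA->CRC): {spec.spec_y.family}"
            + (f" | covariates: {', '.join(spec.spec_y.covariates)}"
               if spec.spec_y.has_covariates else ""),
            f"n = {self.nobs}   log-likelihood = {self.llf:.3f}   "
            f"AIC = {self.aic:.2f}   BIC = {self.bic:.2f}",
            f"converged = {self.converged}   hessian PD = {self.hessian_pd}   "
            f"starts = {self.n_starts_used}",
            "-" * 64,
        ]
        if self.hessian_pd:
            ci = self.conf_int()
            tab = pd.DataFrame({
                "estimate": self.params, "se": self.bse,
                "z": self.tvalues, "P>|z|": self.pvalues,
                "[0.025": ci["lower"], "0.975]": ci["upper"]},
                index=self.names)
        else:
            tab = pd.DataFrame({"estimate": self.params}, index=self.names)
        lines.append(tab.to_string(float_format=lambda v: f"{v:10.4f}"))
        lines.append("=" * 64)
        return "\n".join(lines)

    # -- post-estimation conveniences (see trisurv.postestimation) ----------
    def hazard_ratio(self, name: str, level: float = 0.95):
        """exp(coefficient) with the working-scale CI mapped through exp."""
        return transform_estimate(self, np.exp, monotone_of=name, level=level)

    def cumulative_incidence_first(self, t_grid, w=(), **kw):
        from .postestimation import cumulative_incidence_first
        return cumulative_incidence_first(self.model.spec, self.psi, t_grid, w, **kw)

    def cumulative_incidence_second(self, t_grid, w=(), **kw):
        from .postestimation import cumulative_incidence_second
        return cumulative_incidence_second(self.model.spec, self.psi, t_grid, w, **kw)

    def truncated_mean_second(self, horizon: float = 50.0, w=()):
        from .postestimation import truncated_mean_second
        return truncated_mean_second(self.model.spec, self.psi, horizon, w)


def transform_estimate(res: ThreeStateResults, func, monotone_of: str | None = None,
                       grad=None, level: float = 0.95):
    """Point estimate and CI for a function of the fitted parameters.

    Parameters
    ----------
    func : callable
        Either a scalar map applied to one working-scale parameter (when
        ``monotone_of`` names it; the CI endpoints are mapped directly,
        valid for monotone maps), or a function of the full working vector
        (delta-method CI; ``grad`` optional, numeric otherwise).

    Returns
    -------
    (estimate, lower, upper)
    """
    if monotone_of is not None:
        idx = res.names.index(monotone_of)
        ci = res.conf_int(alpha=1.0 - level)
        lo, hi = func(ci.iloc[idx, 0]), func(ci.iloc[idx, 1])
        return (float(func(res.params[idx])),
                float(min(lo, hi)), float(max(lo, hi)))
    est = float(func(res.params))
    if grad is None:
        g = numdiff.approx_fprime(res.params, lambda p: np.atleast_1d(func(p)),
                                  centered=True).ravel()
    else:
        g = np.asarray(grad(res.params), dtype=float)
    if g.shape != res.params.shape:
        raise ValueError("gradient shape mismatch; supply grad for vector maps")
    se = float(np.sqrt(g @ res.cov @ g))
    z = stats.norm.ppf(0.5 + level / 2.0)
    return est, est - z * se, est + z * se


def backward_stepwise(records, spec_x: FamilySpec, spec_y: FamilySpec,
                      alpha: float = 0.05, **fit_kw):
    """Backward elimination of covariates by Wald p-value.

    Starting from the full model, repeatedly drop the covariate coefficient
    with the largest p-value above ``alpha`` (baseline parameters and
    intercepts are never dropped) and refit, until every remaining
    coefficient is significant.

    Returns
    -------
    (final ThreeStateModel, final ThreeStateResults, trace DataFrame)
    """
    trace_rows = []
    step = 0
    while True:
        model = ThreeStateModel(records, spec_x, spec_y)
        res = model.fit(**fit_kw)
        if not res.success:
            trace_rows.append({"step": step, "action": "stopped: fit failed",
                               "dropped": None, "p_value": np.nan,
                               "aic": res.aic})
            return model, res, pd.DataFrame(trace_rows)
        cand = [n for n in res.names
                if n.split(":", 1)[1] in spec_x.covariates and n.startswith("x:")
                or n.split(":", 1)[1] in spec_y.covariates and n.startswith("y:")]
        if not cand:
            break
        pv = res.pvalues[cand]
        worst = pv.idxmax()
        if pv[worst] <= alpha:
            break
        side, covname = worst.split(":", 1)
        if side == "x":
            spec_x = FamilySpec(spec_x.family,
                                tuple(c for c in spec_x.covariates if c != covname))
        else:
            spec_y = FamilySpec(spec_y.family,
                                tuple(c for c in spec_y.covariates if c != covname))
        trace_rows.append({"step": step, "action": "drop", "dropped": worst,
                           "p_value": float(pv[worst]), "aic": res.aic})
        step += 1
    trace_rows.append({"step": step, "action": "final", "dropped": None,
                       "p_value": np.nan, "aic": res.aic})
    return model, res, pd.DataFrame(trace_rows)
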