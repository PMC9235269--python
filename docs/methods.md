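# Methods

## Disease process and observation scheme

The package models an irreversible three-state pathway: adenoma-free (AF,
including non-advanced adenomas) → advanced adenoma (AA) → colorectal
cancer (CRC). Sojourn times are `X` (AF→AA) and `Y` (AA→CRC), `Z = X + Y`;
`X` and `Y` are independent given baseline covariates. Assumptions
inherited from the surveillance setting:

- everyone starts AF at time zero (post-polypectomy baseline);
- adenomas do not regress and every CRC passes through AA;
- the surveillance test is perfect (no missed lesions);
- visit schedules are independent of the disease process;
- covariates are fixed at baseline.

Each individual is reduced to one record `(v_prev, v_last, Δ_AA, Δ_CRC)`:
right-censored (no event by the last visit), interval-censored AA or CRC on
`(v_prev, v_last]`, with `v_prev = 0` encoding left-censoring at the first
visit. Detection of AA censors the pathway, so `Y` enters the likelihood
only through the convolution `∫ f(x) G(v_last − x) dx` that splits event
mass between the AA and CRC branches. Exact event times are outside the
observation scheme and are rejected as invalid input rather than
approximated.

## Parametric families and parameterization

Baseline families per transition: exponential (rate λ), Weibull
(cumulative hazard `(t/θ)^κ`), Gompertz (hazard `λ e^{γt}`). Covariates
act proportionally on the hazard. With covariates the scale-type baseline
parameter becomes a log-scale intercept: exponential hazard
`exp(a0 + c·w)`; Weibull `H(t|w) = (t / e^{a0})^κ · e^{c·w}` (so
`θ = e^{a0}` and `e^{c}` is a constant hazard ratio); Gompertz baseline
rate `e^{a0}`. This parameterization was chosen because it reproduces all
published desk-checkable quantities of the final surveillance model
(cumulative incidences, hazard ratio, truncated mean) exactly.

Estimation happens on a working scale: natural log for rates, shapes and
scales; Gompertz shape `γ` and regression coefficients unconstrained. A
negative Gompertz shape gives an improper distribution (a fraction never
transitions); it is allowed but flagged with a warning
(`distributions.check_proper`).

## Likelihood evaluation

All event-branch probabilities are computed after the change of variable
`s = H_x(x|w)` (the cumulative hazard of `X`), under which
`f(x) dx = e^{-s} ds` and the integrand `e^{-s} G_y(v_last − x(s))` is
smooth for every supported family — this removes the integrable density
singularity of Weibull shapes below one at interval endpoints.

- Scalar API (`prob_interval_aa/crc`): adaptive Gauss–Kronrod quadrature
  (absolute tolerance 1e−12, 200 subdivisions) with a fixed 64-node
  Gauss–Legendre fallback if the adaptive routine reports difficulty.
- Fitting path (`loglik_vector`): one fixed Gauss–Legendre rule (48 nodes
  by default, configurable) broadcast across all event records, which
  agrees with the adaptive path to ~1e−6 per record and makes a full
  cohort evaluation a few milliseconds.
- The integration range is capped at `s ≤ s_a + 40`: beyond it `e^{-s}`
  carries less than `e^{-40}` of the branch mass, and stretching a fixed
  rule over an arbitrarily long range (which occurs under extreme hazard
  multipliers) would otherwise starve the region that actually carries
  mass. The truncated remainder is reassigned to the AA branch so the
  outcome probabilities still partition the survival mass exactly.

Branch probabilities are floored at 1e−300 before logging; a record whose
probability underflows contributes −∞ (never NaN) and poisons the fit
visibly instead of being dropped.

## Maximization and inference

L-BFGS-B on the working scale with numerical gradients, relative function
tolerance 1e−8, iteration cap 10 000. Default starts: first-transition
rate from event count / person-time, second-transition rate from CRC count
/ half the summed event-interval widths, shapes at 1 (the exponential
submodel), coefficients at 0. Multi-start jitters the start with
N(0, 0.5²) working-scale noise from a seeded generator and keeps the best
converged optimum.

Standard errors come from inverting the negative Hessian obtained by
central finite differences (`statsmodels.tools.numdiff.approx_hess3`). A
fit counts as **successful** only when the optimizer converged *and* the
Cholesky factorization of the negative Hessian succeeds; false convergence
(non-PD information) is reported, not raised. Wald intervals are
constructed on the working scale; monotone transforms (hazard ratios,
natural-scale shapes) map the interval endpoints, other transforms use the
delta method. `AIC = 2k − 2ℓ`, `BIC = k log n − 2ℓ` with `k` parameters
and `n` individuals. Backward stepwise selection repeatedly removes the
covariate coefficient with the largest Wald p-value above the threshold
(default 5%); baseline parameters and intercepts are never candidates.

## Cohort simulator

The generator emulates the adenoma-surveillance observation process:
covariates `w ~ N(0,1)`; latent times by inverse-cumulative-hazard
sampling `T = H₀^{-1}(E / e^{c·w})`, `E ~ Exp(1)`; up to `m_max = 4` visit
times iid Uniform(a, b), sorted (the order-statistics reading of "visits
drawn uniformly over the follow-up window"); and the detection rule: the
first visit at or after `X` detects CRC if `Z` has also been passed,
otherwise AA, on the interval back to the previous visit (time 0 for the
first). One `SeedSequence` per scenario is split into covariate, latent
and visit sub-streams so each component is independently reproducible.

`SCENARIO_TRUTHS` carries the published generating values for the
15 grid models whose low-CRC-setting truths are printed (M16's were not
published; users supply their own). The follow-up windows are *not* part
of the published grid, so `calibrate_window` finds (a, b) by two-stage
grid search minimizing the squared deviation of pilot-cohort state
proportions (default pilot n = 20 000) from the target composition —
(55, 40, 5)% AF/AA/CRC for the low-CRC setting, (30, 40, 30)% for the
high-CRC one. Calibration is best-effort: for some models (e.g.
exponential X with a sharply rising Weibull Y) no window under four
uniform visits reaches 5% CRC with 40% AA, and the function returns the
closest composition with a warning. The frozen windows used in the tests
((3, 24) for M1/M5, (0.5, 21.5) for M9, (2, 20) for M13, (4, 30) for M2)
come from this calibration.

What the simulator does **not** emulate about real surveillance data:
informative or guideline-driven visit timing, missed lesions, competing
mortality, more than `m_max` visits (real cohorts reach 30+; the record
layout absorbs any visit count, but the generator does not produce them),
and non-normal covariates. Passing tests therefore demonstrate internal
consistency of likelihood and simulator and estimator calibration under
the stated design — not robustness to those real-data features.

## Monte-Carlo evaluation

`run_monte_carlo` derives one child seed per run, simulates, refits, and
summarizes **successful** runs only (convergence + PD Hessian), mirroring
how the published study's success-rate table treats failures. Performance
measures use the standard formulas (RMSE; relative bias in percent;
CV = sample SD / true value; empirical coverage of ψ̂ ± 1.96·SE; average
width 3.92·SE). Values are summarized on the scale the grid states its
truths: shapes/scales/rates natural (delta-method SEs), intercepts and
coefficients on the estimation scale. Coverage is computed from the
working-scale interval by default (`ci_scale="working"`), matching how the
model itself reports CIs; this equals the coverage of the asymmetric
back-transformed interval for positive parameters. The symmetric
reporting-scale alternative (`ci_scale="report"`) typically differs by
under one coverage point for the grid models.

The test suite runs the expensive coverage checks at reduced replication
(N_sim = 200–250, cohort sizes 1000–5000) and compares against the
published coverages with three-Monte-Carlo-SE tolerances; these sizes are
the package's chosen trade-off between discrimination and runtime (the
full published grid is 1000 replications per cell).

## Post-estimation

- Cumulative incidence: `F_X(t|w)` and `G_Y(t)` evaluated from the fitted
  (or any supplied) parameter vector — the same code path as the
  distribution layer.
- Right-truncated mean `E[Y | Y ≤ T] = θ γ(1 + 1/κ, (T/θ)^κ) / F_Y(T)`
  via the lower incomplete gamma (exponential as κ = 1), cross-checked in
  tests against numeric integration of `t·g(t)/G(T)` to 1e−6 relative. A
  PH multiplier rescales the Weibull scale by `m^{-1/κ}`.
- Bootstrap bands: individuals resampled with replacement, each replicate
  refit starting from the original optimum, pointwise percentile bands
  over converged replicates; failed replicates are counted and more than
  50% failures abort. (The published analysis does not state its bootstrap
  variant; cohort-level resampling with percentile bands is this package's
  choice.)
- NPMLE: own Turnbull self-consistency EM (equivalence-class intervals,
  mass-change tolerance 1e−8), restricted — as in the published
  goodness-of-fit figure — to individuals observed to develop AA, using
  their `(v_prev, v_last]` intervals. Cross-checked in tests against a
  brute-force simplex maximization and against the independent lifelines
  implementation on tie-free data (conventions for tied endpoints differ:
  lifelines treats intervals as closed).

## Numerical edge cases and tie-breaks

- `λ₁ = λ₂` in the exponential–exponential convolution: production code
  always integrates numerically; the closed form (with a series branch at
  the removable singularity) lives in the test suite as an oracle only.
- Visit-time ties (probability zero, possible through rounding) are nudged
  by one ulp to keep schedules strictly increasing.
- Zero-width intervals (`v_prev = v_last`) are invalid input everywhere.
- Degenerate targets in window calibration (e.g. 100% AF) return the
  boundary best effort with a warning.

## Known limitations

Single progressive pathway (no competing risks, no cure fraction, no
X–Y dependence); time-fixed covariates; no misclassification; Gompertz `Y`
is excluded from the truncated-mean formula (no closed incomplete-gamma
form); profile-likelihood or bootstrap CIs for derived quantities other
than curves are not provided.
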