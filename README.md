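# trisurv

Joint maximum-likelihood estimation of the two transition-time
distributions in a **progressive three-state disease model** — adenoma-free
(AF) → advanced adenoma (AA) → colorectal cancer (CRC) — from
interval-censored surveillance (panel) data.

## The problem

Post-polypectomy surveillance observes each individual only at a handful of
endoscopy visits. Worse, the moment an advanced adenoma is detected it is
removed, which closes the pathway to cancer: the sojourn time *Y* from AA
to CRC is **never directly observed** in any individual. Yet *Y* is exactly
the quantity screening programs need — it drives the choice of surveillance
intervals and is a key input to microsimulation models of CRC prevention.

`trisurv` is for biostatisticians and screening modellers who want to
infer both sojourn-time distributions from such data.

## The model

Let *X* be the AF→AA time, *Y* the AA→CRC time, *Z = X + Y*, with CDFs
*F* and *G* and density *f* for *X*. Each individual contributes one
censoring interval (*v*<sub>m−1</sub>, *v*<sub>m</sub>] (with
*v*<sub>m−1</sub> = 0 for left-censoring) and event indicators
Δ<sub>AA</sub>, Δ<sub>CRC</sub>. The three possible outcomes have
probabilities

- still AF at the last visit: Pr(X > v<sub>m</sub>) = 1 − F(v<sub>m</sub>),
- AA found, no CRC: F(v<sub>m</sub>) − F(v<sub>m−1</sub>) −
  ∫<sub>v<sub>m−1</sub></sub><sup>v<sub>m</sub></sup> f(x) G(v<sub>m</sub> − x) dx,
- CRC found: ∫<sub>v<sub>m−1</sub></sub><sup>v<sub>m</sub></sup> f(x) G(v<sub>m</sub> − x) dx,

and the joint log-likelihood ℓ(ψ) = Σ<sub>i</sub> log ℒ<sub>i</sub>(ψ) is
maximized over the parameters of both distributions simultaneously. The
convolution term is what lets the unobservable *Y* be identified from the
split between AA and CRC detections.

Each transition time may be exponential, Weibull or Gompertz, with
proportional-hazards covariate effects: H(t | w) = H₀(t) · exp(c·w), so
exp(c) is a hazard ratio. With covariates the scale-type parameter is
reported as a log-scale intercept (Weibull: H(t|w) = (t/e^{a₀})^κ e^{a₁w}).
Estimation is on the log scale for positive parameters; standard errors
come from the inverse observed information, and AIC/BIC support model
selection across the 16-model exponential/Weibull grid.

The package also ships the matching **cohort simulator** (latent times,
uniform visit schedules, censoring-at-detection observation rule, window
calibration to target AF/AA/CRC compositions), a **Monte-Carlo evaluation
engine** (success rates, RMSE, relative bias, CV, empirical coverage,
average CI width), and post-estimation tools (cumulative-incidence curves,
bootstrap bands, right-truncated Weibull mean, Turnbull NPMLE
goodness-of-fit comparison, hazard ratios, backward stepwise selection).

## Worked example

Simulate a cohort of 2000 individuals under Weibull–Weibull truth
(shape 1.5 / scale 23 years for AF→AA; shape 0.8 / scale 28 for AA→CRC),
observe it through up to four uniform visits on (2, 20] years, and refit:

```python
from trisurv import FamilySpec, ThreeStateModel, make_scenario, generate_cohort

scenario = make_scenario("M13", n=2000, window=(2.0, 20.0))
records, _ = generate_cohort(scenario, seed=1)

model = ThreeStateModel(records,
                        spec_x=FamilySpec("weibull"),
                        spec_y=FamilySpec("weibull"))
res = model.fit(n_starts=3, seed=0)
print(res.summary())
```

```
Progressive three-state model (interval-censored ML)
================================================================
X (AF->AA): weibull
Y (AA->CRC): weibull
n = 2000   log-likelihood = -2605.623   AIC = 5219.25   BIC = 5241.65
converged = True   hessian PD = True   starts = 3
----------------------------------------------------------------
              estimate         se          z      P>|z|     [0.025     0.975]
x:log_shape     0.4064     0.0371    10.9497     0.0000     0.3337     0.4792
x:log_scale     3.1812     0.0282   112.8144     0.0000     3.1259     3.2365
y:log_shape    -0.2773     0.2605    -1.0645     0.2871    -0.7879     0.2333
y:log_scale     3.6764     0.6467     5.6851     0.0000     2.4089     4.9438
================================================================
```

The observable first transition is estimated tightly (shape 1.50, scale
24.1 vs the true 1.5 / 23); the latent second transition is recovered with
honest, much wider uncertainty (shape 0.76 vs true 0.8; the scale CI is
wide because CRC events are rare). Downstream quantities:

```python
curve = res.cumulative_incidence_second([5.0, 15.0])
res.truncated_mean_second(50.0)
```

```
CRC risk at 5y / 15y since AA onset: 18.8% / 38.1%
mean years to CRC within 50y of AA onset: 16.63
```

A command line mirrors the library: `trisurv simulate | fit | mc |
predict | convert` (see `trisurv --help`).

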