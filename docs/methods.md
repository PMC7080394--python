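# Methods

This note documents the statistical procedures implemented in `prepost`,
the choices made where the methods literature leaves details open, and
what the simulation benchmark does and does not establish.

## Data model

A `PanelDataset` is a balanced n × T panel: outcomes `Y_it`, optional
time-varying covariates `X_it` (a time-invariant covariate is stored by
repetition), a binary group flag, and the last pre-treatment period t′.
Treatment adoption is *block*: every treated unit is exposed in every
period t > t′. Staggered adoption is rejected at validation, because all
four estimators as implemented assume a single adoption date. Periods are
re-indexed to consecutive 1-based integers on load; "post" is the set
{t : t > t′}. The container requires at least one treated and one control
unit; each estimator imposes its own stronger minima (SC needs ≥ 2 donors,
cluster-robust inference ≥ 2 units).

No variance-stabilizing transformation is applied to outcomes: the methods
are defined on the outcome scale supplied, and proportions (the typical
application) are analyzed untransformed.

## Difference-in-differences

`fit_did` estimates Y_it = X_it'β + α_i + γ_t + τ D_it + ε_it by the
two-way within transformation, which on a balanced panel is numerically
identical to the dummy-variable regression (asserted in the tests against
a statsmodels oracle at 1e-8 relative). Covariates whose within variation
is numerically zero (e.g. time-invariant ones, collinear with the unit
effects) are dropped with a warning. Per-post-period effects come from an
event-study variant with one treated × period interaction per post period;
with covariates present their unweighted mean can differ from the pooled τ̂
in the last few digits, and the pooled coefficient is what `att` reports.

Inference is the CR1 cluster-robust sandwich with clusters = units:
unit-level score sums, finite-sample factor G/(G−1)·(N−1)/(N−K), K counted
as all coefficients of the dummy-variable parameterization. The
pre-trends diagnostic (`parallel_trends_test`) is a cluster-robust Wald
chi-square test that all treated-group × pre-period interactions are zero
in a two-way FE regression restricted to t ≤ t′; the test form is the most
common applied specification, adopted because the literature this package
follows reports such p-values without defining the regression.

## Synthetic control

Treated units are first averaged into a single pseudo-unit (`average_treated`).
Donor weights solve

    min_W (X₁ − X₀W)' V (X₁ − X₀W),  W ≥ 0, ΣW = 1,

where X₁, X₀ hold all t′ pre-period outcomes (no auxiliary covariates:
once every pre-period outcome is a predictor, covariates cannot change the
optimum). The QP is solved by non-negative least squares on an augmented
system with a heavily penalized ones-row enforcing the sum constraint;
the solution was cross-checked against SLSQP and a 20 000-iteration
Frank-Wolfe run (agreement to 1e-10 in the objective). The outer search
over the predictor-importance diagonal V is a multi-start Nelder-Mead on a
softmax parameterization (equal weights plus random restarts, improvements
only). When the predictors are exactly the pre-period outcomes and the
outer criterion is the pre-period MSPE, equal V already attains the global
outer optimum — the V-weighted inner solution can never beat the direct
unweighted minimizer on the unweighted criterion — so the search is a
safeguard for non-default predictor sets, not a workhorse.

**Effect definition.** Per-period gaps are τ̂_t = Y₁t − Σ w_j Y_jt. By
default (`adjust_pre_gap=True`) the mean *pre-period* gap is subtracted
from each post-period gap before averaging into the ATT. With a perfect
pre-fit the adjustment is exactly zero; with an imperfect fit (treated
unit outside the donor hull) it removes the level component of the misfit
that would otherwise be booked as treatment effect. This is how the
estimator is deployed in practice with multiple averaged treated units,
where exact pre-period balance is rare; the textbook raw-gap variant is
available via the flag.

Placebo inference casts each control unit in turn as pseudo-treated
(donors = remaining controls, the true treated excluded) and ranks the
treated unit's post/pre RMSPE ratio: p = (1 + #{placebo ≥ treated})/(1 + J).
RMSPE ratios use raw gaps. Ties count against the treated unit, and no
placebo is excluded for poor pre-fit (an exclusion would add an arbitrary
threshold); a zero pre-RMSPE placebo gets ratio +∞ with a warning. Under
exchangeability the p-value is uniform on {1/(J+1), …, 1}, verified by
simulation in the tests.

## Interactive fixed effects

`fit_ife` estimates Y_it = X_it'β + α_i + γ_t + F_t'μ_i (+ τ D_it) + ε_it
by alternating least squares: (a) given the common component, β (and τ)
and the additive effects by two-way within OLS; (b) given the regression
part, the R leading principal components of the working residual. Each
step is an exact partial minimization, so the sum of squared residuals is
monotonically non-increasing (asserted in the tests). The working residual
is re-demeaned into the additive effects before every SVD so that the
additive/interactive split is unique; identification is F'F/T = I_R with
M'M diagonal, and only the product F μ' matters downstream — the fitted
common component is invariant (1e-6) to orthogonally rotated
initializations. Initialization is deterministic: β from two-way FE OLS,
factors from the SVD of its residual. Convergence: relative change in the
coefficients and in the common component below 1e-8, cap 1000 iterations;
non-convergence returns the last iterate with `converged=False` and a
warning. With R = 0 the estimator reproduces DiD exactly.

The factor count is chosen by cross-validation targeting counterfactual
prediction for the treated units: for each candidate R ≤ R_max (default 5,
requiring R_max + 1 pre-periods), the factor model is fit to the *control*
units over all periods; each treated pre-period is held out in turn,
treated loadings are projected from the remaining pre-periods, and the
held-out outcomes are scored. Ties break toward smaller R. The
`estimate_ife_att` standard errors are cluster-robust over units treating
the estimated factors as known regressors — a deliberate understatement
that mirrors common reporting practice.

Caveat: with a homogeneous τ and a spurious factor (more factors than the
data support) under heterogeneous effects, the alternation can be erratic
— the factor competes with the treatment dummy for the treated-post block.
The CV guard (which selects R from control-side fit quality) avoids this
in practice, but fixed-R fits under effect heterogeneity should be treated
with caution.

## Generalized synthetic control

`fit_gsc` follows the three-step counterfactual construction: (1) fit the
interactive FE model to controls only, over the entire sample period;
(2) for each treated unit, regress its adjusted pre-period outcomes on
[1, F_pre] — the intercept absorbs the additive unit effect, the slopes
are the loadings (requires t′ ≥ R + 1); (3) build Ŷ⁰_it for every period
and read off per-unit, per-period effects on the post block. Because no
treated post-period data enter the fit, effect heterogeneity cannot bias
the counterfactual — on paired simulated panels differing only in the
effect draw, the GSC error is identical to machine precision.

**Bias correction.** When the factor signal is weak relative to the noise,
estimation error in F̂ attenuates the projected treated loadings and the
counterfactual under-extrapolates, overstating the effect (in the
nonparallel-trends benchmark scenario, substituting the true factor
direction removes the entire +0.11 mean bias). `estimate_gsc_att`
therefore applies a parametric-bootstrap bias correction by default: 50
panels are simulated from the fitted treatment-free model (true effect
zero), the pipeline is re-run on each, and the mean spurious ATT is
subtracted. On noiseless or strong-factor data the correction is
numerically zero; `bias_correction=0` disables it.

**Bootstrap inference.** Outcomes are rebuilt as model-implied
treatment-free paths plus whole residual *series* resampled with
replacement from the control pool (whole series to preserve within-unit
serial dependence), with the estimated effects re-added on treated post
cells; the fit/projection pipeline is re-run on each of B draws with the
factor count fixed at the original choice (re-running the CV inside every
draw would re-select on noise and multiply the cost for no inferential
gain). se = SD of the B ATT draws; the 95% CI is att ± 1.96·se (percentile
CI behind a flag) and the p-value is two-sided normal. The procedure is
validated by its operating characteristics: on parallel-trends panels the
nominal 95% CI covers the true ATT between 92% and 98% of the time in the
test suite's 500-panel simulation.

## Simulation benchmark

`generate_panel` draws panels from

    Y_it = X_it β + μ_i1 + λ_1t + λ_2t μ_i2 + λ_3t μ_i3 + D_it τ_it + ε_it

with X_i, μ_i1, μ_i2, μ_i3 iid standard normal (independent components:
the loading correlation structure is a genuinely open detail, and
independence is the neutral choice), λ_1t ~ U(0, 5),
X_it = 0.5·X_i + 0.5·N(0,1), ε_it ~ N(0,1) (optional AR(1) via `ar1_rho`),
β = 1, 62 treated / 49 control units, 22 periods with the last 4
post-treatment. Treated-group means of μ_i1, μ_i2, μ_i3 are shifted +2 SD.
Scenarios: **A** λ_2t = λ_3t = 0 (parallel trends); **B** λ_2t = 0.2t,
λ_3t = 0.1t (note the two trend terms are proportional, so the interactive
structure beyond the additive effects is rank one); **C** trends as in B
but with *no* treated-group mean shifts, the time-invariant X_i as
covariate, and a random 25% of controls (round(0.25·49) = 12 units) with
μ_2, μ_3 raised +4 SD — the raised controls lie above the averaged treated
unit and the rest around it, so it sits inside the donor hull; **D** B
plus an additive +2 shock on treated post cells only; **E** B with 10
treated vs 100 controls. Effects: homogeneous τ = 1, or heterogeneous
τ_i = 1 + (μ_i1 − its treated-group mean), population mean 1 either way.

Scenario C deliberately removes *all* group imbalance in the latent
loadings, not only the trend components: it is defined as the setting
without the features that defeat the synthetic control, and a level
imbalance alone would keep the averaged treated unit outside the donor
hull. A consequence worth knowing: the DiD bias in C comes from the raised
control subset (differential trend slope 0.3·(0 − 4·12/49) ≈ −0.29), so it
has the opposite sign to scenario B's.

Shorter pre-windows (T_pre ∈ {6, 9, 12, 18}) keep the *most recent*
pre-periods of the full 22-period horizon, so the trend terms retain
absolute time. This convention is pinned by a closed-form oracle: the
expected DiD estimate under scenario B is 1 + 0.6·(mean post t − mean pre
t) = 7.6, 5.8, 4.9, 4.0 for the four windows, which only holds under
most-recent-window truncation.

`run_study` applies every requested method to the same panels (replicate r
seeded `base_seed + r`; all randomness flows from the one seed), never
drops failures silently (a key with > 5% failures is flagged invalid), and
`summarize` reports mean % bias (the true effect is 1, so % of the true
effect), the mean squared error against the *per-replicate sample* ATT,
its square root, and Monte Carlo standard errors on both scales. The
benchmark's headline error table is on the squared scale.

Problem sizes: the shipped acceptance script runs 500 replicates per cell
(a few minutes total on one CPU); the test suite uses 100–300 replicates
per cell with tolerances of three combined Monte Carlo standard errors.

### What the generator does and does not emulate

The DGP reproduces the benchmark's structure — factor-driven confounding,
group imbalance, hull geometry, post-period shocks — with Gaussian
idiosyncratic noise, exact balance, and block adoption. Real
hospital-quarter proportions additionally feature bounded outcomes,
heteroskedasticity from varying denominators, staggered or fuzzy policy
exposure, and serially correlated shocks beyond AR(1). Passing the
benchmark therefore shows the estimators are implemented correctly and
behave as theory predicts under the assumed model; it does not certify
performance under misspecification the generator cannot produce.

## Known limitations

- Only block adoption; no staggered designs.
- IFE standard errors ignore factor-estimation uncertainty.
- The SC placebo p-value is discrete (granularity 1/(J+1)) and the V
  search is a heuristic outside the all-pre-outcomes configuration.
- GSC's remaining weak-factor variance is irreducible at these sample
  sizes: its bias correction removes the systematic component but the
  factor-direction noise stays in the counterfactual.
- The parametric bootstrap resamples whole control residual series; with
  strong cross-sectional dependence in the residuals its standard errors
  would be optimistic.
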