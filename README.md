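# prepost

Estimators of the average treatment effect on the treated (ATT) for
**controlled pre-post panel designs** — the setting of a typical health
policy evaluation, where a group of units (e.g. hospitals) is exposed to a
policy from some date onward while a comparison group never is, and a
balanced panel of outcomes is observed before and after adoption.

Four estimators are implemented behind a common interface, together with a
Monte Carlo harness that benchmarks them against each other:

| method | idea | inference |
|---|---|---|
| `did` | two-way fixed effects difference-in-differences | cluster-robust (CR1) over units |
| `sc`  | synthetic control: simplex-weighted donors matched on all pre-period outcomes, treated units averaged into one | in-space placebo tests (post/pre RMSPE ratio rank) |
| `ife` | interactive fixed effects by iterative principal components, factor count by cross-validation | cluster-robust over units |
| `gsc` | generalized synthetic control: factor model fit on controls only, per-treated-unit loadings projected from pre-periods, counterfactual per unit and period | parametric bootstrap |

## The model

All four target E(τ_it | D_it = 1) over the post-adoption periods t > t′,
where observed outcomes follow a linear factor model

    Y_it = X_it' β + λ_t' μ_i + D_it τ_it + ε_it,

with unit loadings μ_i on latent time-varying factors λ_t. DiD is the
special case λ_t' μ_i = μ_i + λ_t (parallel trends); SC replaces the model
by a convex donor combination matched on pre-period outcomes; IFE estimates
the factors jointly on all units with a homogeneous effect coefficient; GSC
estimates β and λ_t on controls only, projects each treated unit's μ_i
from its pre-period fit, and reads off per-unit effects
τ̂_it = Y_it − Ŷ⁰_it — which keeps it consistent under heterogeneous
effects, where IFE is not.

## Worked example

Estimate all four methods on a panel CSV (long format: one row per
unit-period). The demo panel below is simulated with nonparallel trends
and a true ATT of 1:

```python
from prepost import ScenarioConfig, generate_panel, write_panel
panel = generate_panel(ScenarioConfig.from_label("B1", T_pre=12, T_total=16), 42).panel
write_panel(panel, "demo_panel.csv", {"covariates": ["x1"]})
```

with `mapping.yaml` naming the columns and the last pre-treatment period:

```yaml
unit: unit
time: time
outcome: outcome
treated: treated
covariates: [x1]
last_pre: 12
```

then

```bash
prepost estimate --method did,sc,ife,gsc --data demo_panel.csv \
    --config mapping.yaml --bootstrap 500 --seed 7 --out results
```

prints

```
ATT estimates by method
==========================================================
method      estimate        se   p-value  95% CI
did           5.6042    0.3698    0.0000  (4.8712, 6.3371)
sc            4.4402         -    0.5000  -
ife           1.0828    0.0799    0.0000  (0.9246, 1.2411)
gsc           0.8936    0.3649    0.0143  (0.1785, 1.6088)
```

The true effect is 1. DiD is badly biased because the groups' trends
diverge; SC is biased because the averaged treated unit lies outside the
donor convex hull; the factor-model methods recover the effect. Per-method
CSVs (`att_<method>.csv`, per-period effects, donor weights, GSC
counterfactual paths) and the plain-text report land in `results/`.

The Monte Carlo grid behind such comparisons is driven the same way:

```bash
prepost compare --scenario A1,B1,C1,D1 --tpre 6,9,12,18 \
    --methods did,sc,ife,gsc --reps 500 --seed 20100401 --out comparison.csv
```

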