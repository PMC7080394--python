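import numpy as np
import pytest

from conftest import factor_panel
from prepost.did import fit_did
from prepost.gsc import (
    estimate_gsc_att,
    fit_controls,
    fit_gsc,
    parametric_bootstrap,
    project_loadings,
)
from prepost.panel import panel_from_arrays
from prepost.simulation import ScenarioConfig, generate_panel


def test_noiseless_controls_fit_exactly():
    panel, _ = factor_panel(R=2, noise=0.0, seed=4)
    fit = fit_controls(panel, R=2)
    np.testing.assert_allclose(fit.residuals, 0.0, atol=1e-8)


def test_factors_span_entire_sample_period():
    panel, _ = factor_panel(R=2, noise=0.2, seed=4, T=12, t_pre=8)
    fit = fit_controls(panel, R=2)
    assert fit.factors.shape == (12, 2)
    assert fit.time_effects.shape == (12,)


def test_noiseless_treated_loadings_recovered_and_delta_att():
    """Treated units generated from the control model: loadings identified
    exactly with zero noise, and an additive post effect is recovered."""
    delta = 1.7
    panel, truth = factor_panel(n_treated=3, n_control=14, T=12, t_pre=8,
                                R=2, noise=0.0, effect=delta, seed=9)
    g = fit_gsc(panel, R=2)
    # common components (rotation-invariant) agree on the treated block
    tr = panel.treated
    true_cc = truth["M"][tr] @ truth["F"].T
    est_cc = (g.treated_intercepts[:, None]
              + g.treated_loadings @ g.control_fit.factors.T)
    offset_adjusted = est_cc + g.control_fit.time_effects + g.control_fit.intercept
    model_treated = (true_cc + truth["alpha"][tr][:, None]
                     + truth["gamma"][None, :])
    np.testing.assert_allclose(offset_adjusted, model_treated, atol=1e-6)
    assert g.att == pytest.approx(delta, abs=1e-6)
    np.testing.assert_allclose(g.effects, delta, atol=1e-6)
    assert g.pre_gap_mean == pytest.approx(0.0, abs=1e-8)


def test_projection_matches_least_squares_oracle():
    panel, _ = factor_panel(n_treated=2, n_control=12, T=10, t_pre=7, R=2,
                            noise=0.8, seed=6)
    cf = fit_controls(panel, R=2)
    tr = panel.treated
    t_pre = panel.last_pre
    a, mu = project_loadings(panel.outcome[tr][:, :t_pre], None, cf)
    # closed form: per-unit OLS of adjusted outcome on [1, F_pre]
    Fb = np.column_stack([np.ones(t_pre), cf.factors[:t_pre]])
    y_adj = (panel.outcome[tr][:, :t_pre] - cf.time_effects[:t_pre]
             - cf.intercept)
    beta_hat = np.linalg.solve(Fb.T @ Fb, Fb.T @ y_adj.T)
    np.testing.assert_allclose(a, beta_hat[0], atol=1e-8)
    np.testing.assert_allclose(mu, beta_hat[1:].T, atol=1e-8)


def test_projection_underdetermined_error():
    panel, _ = factor_panel(T=10, t_pre=7, R=2, noise=0.5, seed=6)
    cf = fit_controls(panel, R=2)
    with pytest.raises(ValueError, match="R \\+ 1"):
        project_loadings(panel.outcome[panel.treated][:, :2], None, cf)


def test_r_zero_reduces_to_additive_counterfactual():
    panel, _ = factor_panel(R=1, noise=0.5, seed=8)
    g = fit_gsc(panel, R=0)
    assert g.treated_loadings.shape[1] == 0
    cf = g.control_fit
    tr = panel.treated
    t_pre = panel.last_pre
    y_adj = panel.outcome[tr][:, :t_pre] - cf.time_effects[:t_pre] - cf.intercept
    np.testing.assert_allclose(g.treated_intercepts, y_adj.mean(axis=1),
                               atol=1e-10)


def test_gsc_matches_did_on_parallel_trends_no_noise():
    rng = np.random.default_rng(2)
    n, T, t_pre = 12, 8, 5
    treated = np.zeros(n, dtype=bool)
    treated[:3] = True
    Y = rng.standard_normal(n)[:, None] + rng.standard_normal(T)[None, :]
    D = np.outer(treated, np.arange(1, T + 1) > t_pre)
    Y = Y + 1.3 * D
    panel = panel_from_arrays(Y, treated, t_pre)
    g_att = fit_gsc(panel, R=0).att
    d_att = fit_did(panel, inference=False).att
    assert g_att == pytest.approx(d_att, abs=1e-8)
    assert g_att == pytest.approx(1.3, abs=1e-8)


def test_effect_heterogeneity_shift_invariance():
    """Recentering per-unit effect heterogeneity (add c to the effect source,
    remove c from realized post outcomes) leaves the GSC att unchanged, since
    effects are estimated per unit from an unchanged counterfactual."""
    sp1 = generate_panel(ScenarioConfig.from_label("B1", T_pre=8), 42)
    sp2 = generate_panel(ScenarioConfig.from_label("B2", T_pre=8), 42)
    # same draws; outcomes differ only by the tau heterogeneity in post cells
    e1 = fit_gsc(sp1.panel, R=1)
    e2 = fit_gsc(sp2.panel, R=1)
    err1 = e1.att - sp1.true_att
    err2 = e2.att - sp2.true_att
    assert err1 == pytest.approx(err2, abs=1e-10)


def test_pre_period_pseudo_att_near_zero_on_model_data():
    panel, _ = factor_panel(n_treated=6, n_control=20, T=14, t_pre=10, R=2,
                            noise=0.5, effect=1.0, seed=13)
    g = fit_gsc(panel, R=2)
    assert abs(g.pre_gap_mean) < 0.2


def test_bootstrap_deterministic_and_valid():
    panel, _ = factor_panel(n_treated=4, n_control=15, T=10, t_pre=7, R=1,
                            noise=0.5, effect=1.0, seed=10)
    g = fit_gsc(panel, R=1)
    b1 = parametric_bootstrap(panel, g, B=25, seed=123)
    b2 = parametric_bootstrap(panel, g, B=25, seed=123)
    np.testing.assert_array_equal(b1.draws, b2.draws)
    assert b1.se == pytest.approx(np.std(b1.draws, ddof=1))
    assert 0.0 <= b1.p_value <= 1.0
    assert b1.ci_low <= g.att <= b1.ci_high
    b3 = parametric_bootstrap(panel, g, B=25, seed=124)
    assert not np.array_equal(b1.draws, b3.draws)


def test_bootstrap_rejects_tiny_b():
    panel, _ = factor_panel(R=1, noise=0.5, seed=10)
    g = fit_gsc(panel, R=1)
    with pytest.raises(ValueError, match="B >= 2"):
        parametric_bootstrap(panel, g, B=1, seed=0)


def test_estimate_gsc_att_interface():
    panel, _ = factor_panel(n_treated=4, n_control=15, T=10, t_pre=7, R=1,
                            noise=0.5, effect=2.0, seed=11)
    res = estimate_gsc_att(panel, R=1, B=30, seed=5)
    assert res.method == "gsc"
    assert res.inference_method == "bootstrap"
    assert res.att == pytest.approx(2.0, abs=0.8)
    assert res.att == pytest.approx(res.att_by_period.mean(), abs=1e-10)
    assert res.diagnostics["effects"].shape == (4, 3)
    perc = estimate_gsc_att(panel, R=1, B=30, seed=5, ci="percentile")
    assert perc.ci_low <= perc.ci_high
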