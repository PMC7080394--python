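import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prepost.panel import panel_from_arrays
from prepost.sc import (
    estimate_sc_att,
    optimize_predictor_weights,
    placebo_inference,
    solve_donor_weights,
)


def _grid_simplex_minimum(x1, X0, v, step=0.001):
    """Brute-force oracle: scan the simplex grid (2-3 donors only)."""
    J = X0.shape[1]
    best, best_w = np.inf, None
    grid = np.arange(0.0, 1.0 + step / 2, step)
    for combo in itertools.product(grid, repeat=J - 1):
        last = 1.0 - sum(combo)
        if last < -1e-12:
            continue
        w = np.array(combo + (max(last, 0.0),))
        r = x1 - X0 @ w
        obj = r @ (v * r)
        if obj < best:
            best, best_w = obj, w
    return best, best_w


def _objective(x1, X0, v, w):
    r = x1 - X0 @ w
    return r @ (v * r)


def test_exact_donor_match_gets_full_weight():
    X0 = np.array([[1.0, 4.0], [2.0, 5.0], [3.0, 6.0]])
    w = solve_donor_weights(X0[:, 1], X0, np.ones(3))
    np.testing.assert_allclose(w, [0.0, 1.0], atol=1e-8)


def test_scalar_midpoint_interpolation():
    w = solve_donor_weights(np.array([1.5]), np.array([[1.0, 2.0]]), np.array([1.0]))
    np.testing.assert_allclose(w, [0.5, 0.5], atol=1e-8)


def test_boundary_solution_matches_grid_oracle():
    x1, X0, v = np.array([5.0]), np.array([[1.0, 2.0]]), np.array([1.0])
    w = solve_donor_weights(x1, X0, v)
    np.testing.assert_allclose(w, [0.0, 1.0], atol=1e-8)
    assert _objective(x1, X0, v, w) == pytest.approx(9.0, abs=1e-8)
    best, best_w = _grid_simplex_minimum(x1, X0, v)
    assert _objective(x1, X0, v, w) <= best + 1e-8


@pytest.mark.parametrize("seed", range(4))
def test_three_donor_qp_matches_grid_oracle(seed):
    rng = np.random.default_rng(seed)
    m, J = 4, 3
    X0 = rng.standard_normal((m, J))
    x1 = rng.standard_normal(m)
    v = rng.uniform(0.2, 1.0, m)
    w = solve_donor_weights(x1, X0, v)
    best, _ = _grid_simplex_minimum(x1, X0, v, step=0.002)
    assert _objective(x1, X0, v, w) <= best + 1e-4


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_weights_always_on_simplex_and_beat_vertices(seed):
    rng = np.random.default_rng(seed)
    m = rng.integers(1, 6)
    J = rng.integers(2, 8)
    X0 = rng.standard_normal((m, J)) * rng.uniform(0.5, 3)
    x1 = rng.standard_normal(m)
    v = rng.uniform(0.1, 1.0, m)
    w = solve_donor_weights(x1, X0, v)
    assert np.all(w >= 0) and np.all(w <= 1 + 1e-9)
    assert w.sum() == pytest.approx(1.0, abs=1e-6)
    obj = _objective(x1, X0, v, w)
    for j in range(J):
        e = np.zeros(J)
        e[j] = 1.0
        assert obj <= _objective(x1, X0, v, e) + 1e-8


def test_degenerate_predictor_weights_rejected():
    with pytest.raises(ValueError):
        solve_donor_weights(np.array([1.0]), np.array([[1.0, 2.0]]),
                            np.array([0.0]))


def test_single_pre_period_insufficient():
    panel = panel_from_arrays([[0.0, 1.0], [0.0, 0.0], [1.0, 1.0]], [1, 0, 0], 1)
    with pytest.raises(ValueError, match="2 pre"):
        optimize_predictor_weights(panel)


def test_perfect_donor_zero_pre_rmspe_and_delta_att():
    """Treated path equals one donor pre and post, with a level shift post."""
    t = np.arange(1, 9, dtype=float)
    donor = np.sin(t) + t
    other = np.cos(t) - 0.5 * t
    delta = 2.5
    treated = donor.copy()
    treated[5:] += delta
    panel = panel_from_arrays(np.vstack([treated, donor, other]), [1, 0, 0], 5)
    sw = optimize_predictor_weights(panel)
    assert sw.pre_rmspe == pytest.approx(0.0, abs=1e-6)
    res = estimate_sc_att(panel, inference=False)
    assert res.att == pytest.approx(delta, abs=1e-6)
    # the adjustment subtracts a zero pre-gap here, so raw gaps agree
    raw = estimate_sc_att(panel, inference=False, adjust_pre_gap=False)
    assert raw.att == pytest.approx(delta, abs=1e-6)


def test_outer_search_never_worse_than_equal_weights(noisy_panel):
    sw = optimize_predictor_weights(noisy_panel, n_restarts=2)
    from prepost.panel import average_treated
    from prepost.sc import _pre_mspe

    pav = average_treated(noisy_panel)
    pre = ~pav.is_post
    x1 = pav.outcome[pav.treated][0, pre]
    X0 = pav.outcome[~pav.treated][:, pre].T
    m = len(x1)
    w_eq = solve_donor_weights(x1, X0, np.full(m, 1 / m))
    assert sw.pre_rmspe**2 <= _pre_mspe(pav, w_eq) + 1e-12
    assert sw.predictor_weights.sum() == pytest.approx(1.0)
    assert np.all(sw.predictor_weights >= 0)


def test_synthetic_path_bounded_by_donor_envelope(noisy_panel):
    res = estimate_sc_att(noisy_panel, inference=False)
    w = res.diagnostics["donor_weights"]
    donors = noisy_panel.outcome[~noisy_panel.treated]
    synth = w @ donors
    assert np.all(synth <= donors.max(axis=0) + 1e-9)
    assert np.all(synth >= donors.min(axis=0) - 1e-9)


def test_att_invariant_to_donor_relabeling(noisy_panel, rng):
    base = estimate_sc_att(noisy_panel, inference=False).att
    ctrl = np.flatnonzero(~noisy_panel.treated)
    perm = rng.permutation(ctrl)
    order = np.concatenate([np.flatnonzero(noisy_panel.treated), perm])
    shuffled = panel_from_arrays(noisy_panel.outcome[order],
                                 noisy_panel.treated[order],
                                 noisy_panel.last_pre,
                                 noisy_panel.covariates[order])
    assert estimate_sc_att(shuffled, inference=False).att == pytest.approx(
        base, abs=1e-6)


def _placebo_panel(treated_effect, seed=3, J=5, T=8, t_pre=6):
    rng = np.random.default_rng(seed)
    Y = rng.standard_normal((J + 1, T))
    Y[0, t_pre:] += treated_effect
    return panel_from_arrays(Y, [1] + [0] * J, t_pre)


def test_placebo_rank_p_value_extremes():
    # huge treated effect -> treated ratio strictly largest -> p = 1/(J+1)
    strong = _placebo_panel(50.0)
    dist = placebo_inference(strong)
    assert dist.treated_statistic > dist.unit_statistics.max()
    assert dist.p_value == pytest.approx(1 / 6)
    # p = 1 requires every placebo ratio >= treated ratio
    weak = _placebo_panel(0.0)
    d2 = placebo_inference(weak)
    rank = 1 + np.sum(d2.unit_statistics >= d2.treated_statistic)
    assert d2.p_value == pytest.approx(rank / 6)
    assert 0.0 < d2.p_value <= 1.0


def test_placebo_p_uniform_under_exchangeability():
    """With the treated label assigned at random and no effect, the placebo
    p-value is uniform on {1/(J+1), ..., 1}."""
    J = 9
    reps = 150
    pvals = []
    rng = np.random.default_rng(99)
    for _ in range(reps):
        Y = rng.standard_normal((J + 1, 9))
        panel = panel_from_arrays(Y, [1] + [0] * J, 6)
        pvals.append(estimate_sc_att(panel, maxiter=15).p_value)
    pvals = np.asarray(pvals)
    levels = np.arange(1, J + 2) / (J + 1)
    # mean of uniform on the grid is (J+2)/(2(J+1)); check first two moments
    assert pvals.mean() == pytest.approx(levels.mean(), abs=3 * 0.29 / np.sqrt(reps))
    counts = np.array([(np.abs(pvals - lv) < 1e-9).sum() for lv in levels])
    assert counts.sum() == reps
    # chi-square goodness of fit against the discrete uniform
    expected = reps / (J + 1)
    chi2 = ((counts - expected) ** 2 / expected).sum()
    from scipy.stats import chi2 as chi2_dist

    assert chi2_dist.sf(chi2, J) > 1e-4
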