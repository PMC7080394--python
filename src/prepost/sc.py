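"""Synthetic control estimation for the averaged treated unit.

The treated units are collapsed into a single pseudo-unit; a synthetic
control is the convex combination of donor (control) units that best
reproduces the pseudo-unit's pre-treatment outcome path.  Donor weights W
solve the simplex-constrained quadratic program

    min_W (X1 - X0 W)' V (X1 - X0 W),   W >= 0,  sum(W) = 1,

where the predictor matrices X1, X0 hold all pre-treatment outcomes and V
is a diagonal predictor-importance weighting.  V is chosen by a nested
multi-start search minimizing the pre-treatment mean squared prediction
error of the implied synthetic unit.  When the predictors are exactly the
pre-period outcomes this outer criterion is itself the equal-V objective,
so the equal-weights start is already optimal; random restarts guard the
general case and only improvements are ever accepted.

Inference is by in-space placebo tests: each control unit in turn is cast
as pseudo-treated and the post/pre RMSPE ratio of the true treated unit is
ranked within the placebo distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy.optimize import minimize, nnls

from .panel import ATTResult, PanelDataset, average_treated

__all__ = [
    "SCWeights",
    "PlaceboDistribution",
    "solve_donor_weights",
    "optimize_predictor_weights",
    "estimate_sc_att",
    "placebo_inference",
]


class SCSolverError(RuntimeError):
    """The donor-weight quadratic program failed to converge."""


@dataclass
class SCWeights:
    donor_weights: np.ndarray      # (J,), on the unit simplex
    predictor_weights: np.ndarray  # (m,), nonnegative, sums to 1
    predictors_treated: np.ndarray   # X1, (m,)
    predictors_controls: np.ndarray  # X0, (m, J)
    pre_rmspe: float


@dataclass
class PlaceboDistribution:
    unit_statistics: np.ndarray  # post/pre RMSPE ratios of placebo runs
    treated_statistic: float
    p_value: float


def solve_donor_weights(
    predictors_treated: np.ndarray,
    predictors_controls: np.ndarray,
    predictor_weights: np.ndarray,
    *,
    tol: float = 1e-12,
) -> np.ndarray:
    """Solve the V-weighted donor QP over the unit simplex.

    Returns the weight vector W minimizing ``(X1 - X0 W)' V (X1 - X0 W)``
    subject to ``W >= 0`` and ``sum(W) = 1``, via non-negative least
    squares with the sum constraint enforced by a heavy penalty row.
    """
    x1 = np.asarray(predictors_treated, dtype=float).ravel()
    X0 = np.asarray(predictors_controls, dtype=float)
    v = np.asarray(predictor_weights, dtype=float).ravel()
    m, J = X0.shape
    if J < 2:
        raise ValueError("need at least 2 donors")
    if len(x1) != m or len(v) != m:
        raise ValueError("predictor dimensions disagree")
    if np.any(v < 0) or v.sum() <= 0:
        raise ValueError("predictor weights must be nonnegative with positive sum")
    v = v / v.sum()

    # Least-squares-over-simplex via non-negative least squares on an
    # augmented system: a heavily weighted ones-row enforces sum(w) = 1
    # (violation is O(objective / penalty^2), far below solver precision).
    sq = np.sqrt(v)
    A = sq[:, None] * X0
    b = sq * x1
    penalty = 1e5 * max(np.linalg.norm(A), 1.0)
    A_aug = np.vstack([A, np.full(J, penalty)])
    b_aug = np.concatenate([b, [penalty]])
    try:
        w, _ = nnls(A_aug, b_aug)
    except RuntimeError as exc:  # active-set iteration cap
        raise SCSolverError(f"donor QP failed: {exc}") from exc
    s = w.sum()
    if abs(s - 1.0) > 1e-6:
        raise SCSolverError(f"donor weights sum to {s:.6g}, not 1")
    return w / s


def _pre_mspe(panel_avg: PanelDataset, w: np.ndarray) -> float:
    """Mean squared pre-period discrepancy treated vs synthetic unit."""
    pre = ~panel_avg.is_post
    y1 = panel_avg.outcome[panel_avg.treated][0, pre]
    Y0 = panel_avg.outcome[~panel_avg.treated][:, pre]
    gap = y1 - w @ Y0
    return float(np.mean(gap**2))


def optimize_predictor_weights(
    panel: PanelDataset,
    *,
    n_restarts: int = 1,
    maxiter: int = 40,
    seed: int = 0,
) -> SCWeights:
    """Nested (V, W) optimization on the averaged treated unit.

    Predictors are the ``t'`` pre-period outcomes.  The outer search runs
    Nelder-Mead over a softmax parameterization of the diagonal V, starting
    from equal weights plus ``n_restarts`` random Dirichlet starts; each
    candidate V is scored by the pre-period MSPE of the inner QP solution.
    A candidate is accepted only if it improves on the best found so far,
    so the result never does worse than equal V.
    """
    if panel.last_pre < 2:
        raise ValueError("predictor-weight optimization needs at least 2 pre-periods")
    pav = average_treated(panel)
    pre = ~pav.is_post
    x1 = pav.outcome[pav.treated][0, pre]
    X0 = pav.outcome[~pav.treated][:, pre].T  # (m, J)
    m = x1.shape[0]

    def score(v):
        w = solve_donor_weights(x1, X0, v)
        return _pre_mspe(pav, w), w

    v_eq = np.full(m, 1.0 / m)
    best_obj, best_w = score(v_eq)
    best_v = v_eq

    if m > 1:
        rng = np.random.default_rng(seed)
        starts = [np.zeros(m)]
        starts += [rng.standard_normal(m) for _ in range(n_restarts)]

        def nm_obj(z):
            ez = np.exp(z - z.max())
            return score(ez / ez.sum())[0]

        for z0 in starts:
            res = minimize(nm_obj, z0, method="Nelder-Mead",
                           options={"maxiter": maxiter, "xatol": 1e-3,
                                    "fatol": 1e-10})
            ez = np.exp(res.x - res.x.max())
            v_cand = ez / ez.sum()
            obj_cand, w_cand = score(v_cand)
            if obj_cand < best_obj - 1e-15:
                best_obj, best_w, best_v = obj_cand, w_cand, v_cand

    return SCWeights(
        donor_weights=best_w,
        predictor_weights=best_v,
        predictors_treated=x1,
        predictors_controls=X0,
        pre_rmspe=float(np.sqrt(best_obj)),
    )


def _sc_gaps(panel_avg: PanelDataset, w: np.ndarray) -> np.ndarray:
    """Treated-minus-synthetic gap at every period, shape (T,)."""
    y1 = panel_avg.outcome[panel_avg.treated][0]
    Y0 = panel_avg.outcome[~panel_avg.treated]
    return y1 - w @ Y0


def estimate_sc_att(
    panel: PanelDataset,
    *,
    adjust_pre_gap: bool = True,
    inference: bool = True,
    n_restarts: int = 1,
    maxiter: int = 40,
    seed: int = 0,
) -> ATTResult:
    """Synthetic control ATT: average post-period gap of the averaged treated
    unit versus its synthetic control; placebo-test p-value when requested.

    With ``adjust_pre_gap=True`` (default) the mean pre-treatment gap is
    subtracted from each post-period gap before averaging.  When the
    synthetic control reproduces the treated pre-period path exactly the
    adjustment is zero; when the treated unit lies outside the donor
    convex hull it removes the level component of the misfit that would
    otherwise carry straight into the effect estimate, matching how the
    estimator is deployed with multiple averaged treated units.  Set
    ``adjust_pre_gap=False`` for the textbook raw post-period gap.
    """
    pav = average_treated(panel)
    sw = optimize_predictor_weights(pav, n_restarts=n_restarts,
                                    maxiter=maxiter, seed=seed)
    gaps = _sc_gaps(pav, sw.donor_weights)
    post = pav.is_post
    pre_gap_mean = float(gaps[~post].mean())
    att_by_period = gaps[post] - (pre_gap_mean if adjust_pre_gap else 0.0)
    att = float(att_by_period.mean())
    diagnostics: dict[str, Any] = {
        "pre_rmspe": sw.pre_rmspe,
        "pre_gap_mean": pre_gap_mean,
        "raw_gaps": gaps,
        "donor_weights": sw.donor_weights,
        "predictor_weights": sw.predictor_weights,
    }
    result = ATTResult(
        method="sc",
        att=att,
        att_by_period=att_by_period,
        post_periods=pav.post_periods(),
        inference_method="placebo" if inference else None,
        diagnostics=diagnostics,
    )
    if inference:
        post_rmspe = float(np.sqrt(np.mean(gaps[post] ** 2)))
        dist = placebo_inference(
            panel, result, treated_ratio=_rmspe_ratio(post_rmspe, sw.pre_rmspe),
            n_restarts=n_restarts, maxiter=maxiter, seed=seed,
        )
        result.p_value = dist.p_value
        diagnostics["placebo"] = dist
    return result


def _rmspe_ratio(post_rmspe: float, pre_rmspe: float) -> float:
    if pre_rmspe == 0.0:
        if post_rmspe == 0.0:
            return 0.0
        warnings.warn("zero pre-treatment RMSPE; post/pre ratio set to +inf")
        return np.inf
    return post_rmspe / pre_rmspe


def placebo_inference(
    panel: PanelDataset,
    treated_result: ATTResult | None = None,
    *,
    treated_ratio: float | None = None,
    n_restarts: int = 1,
    maxiter: int = 40,
    seed: int = 0,
) -> PlaceboDistribution:
    """In-space placebo test for the synthetic control estimate.

    Each control unit is cast in turn as pseudo-treated (donors = remaining
    controls, true treated units excluded) and its post/pre RMSPE ratio is
    computed.  The p-value is the rank of the treated unit's ratio:
    ``p = (1 + #{placebo ratio >= treated ratio}) / (1 + #controls)``; ties
    count against the treated unit.
    """
    ctrl = np.flatnonzero(~panel.treated)
    J = len(ctrl)
    if J < 2:
        raise ValueError("placebo inference needs at least 2 control units")
    if treated_ratio is None:
        if treated_result is not None and "placebo" in treated_result.diagnostics:
            treated_ratio = treated_result.diagnostics["placebo"].treated_statistic
        else:
            pav = average_treated(panel)
            sw = optimize_predictor_weights(pav, n_restarts=n_restarts,
                                            maxiter=maxiter, seed=seed)
            gaps = _sc_gaps(pav, sw.donor_weights)
            post = pav.is_post
            treated_ratio = _rmspe_ratio(
                float(np.sqrt(np.mean(gaps[post] ** 2))), sw.pre_rmspe
            )

    ratios = np.empty(J)
    out_ctrl = panel.outcome[ctrl]
    cov_ctrl = panel.covariates[ctrl]
    post = panel.is_post
    for idx in range(J):
        order = np.concatenate([[idx], np.delete(np.arange(J), idx)])
        placebo = PanelDataset(
            unit_ids=panel.unit_ids[ctrl][order],
            time_ids=panel.time_ids,
            outcome=out_ctrl[order],
            covariates=cov_ctrl[order],
            treated=np.concatenate([[True], np.zeros(J - 1, dtype=bool)]),
            last_pre=panel.last_pre,
        )
        sw = optimize_predictor_weights(placebo, n_restarts=n_restarts,
                                        maxiter=maxiter, seed=seed)
        gaps = _sc_gaps(placebo, sw.donor_weights)
        ratios[idx] = _rmspe_ratio(
            float(np.sqrt(np.mean(gaps[post] ** 2))), sw.pre_rmspe
        )

    p = (1.0 + np.sum(ratios >= treated_ratio)) / (1.0 + J)
    return PlaceboDistribution(
        unit_statistics=ratios,
        treated_statistic=float(treated_ratio),
        p_value=float(p),
    )
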