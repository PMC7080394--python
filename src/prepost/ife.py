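"""Interactive fixed effects (IFE) estimation by iterative principal components.

The model is ``Y_it = X_it' beta + alpha_i + gamma_t + F_t' mu_i (+ D_it tau)
+ eps_it`` with R latent factors ``F_t`` and unit loadings ``mu_i`` on top
of additive two-way effects.  Estimation alternates between (a) extracting
the R leading principal components of the residual matrix (after removing
the regression part, additive effects, and, when present, the treatment
term) and (b) least squares for the slope coefficients.  Each step is an
exact partial minimization, so the sum of squared residuals is monotonically
non-increasing.

Identification: factors are normalized so that ``F'F / T = I_R`` and the
loadings cross-product ``M'M`` is diagonal; only the common component
``F mu'`` matters downstream, and it is invariant to this choice.

The number of factors is chosen by cross-validation: a factor model fit to
control units is scored by leave-one-pre-period-out prediction of the
treated units' pre-treatment outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Any

import numpy as np
from scipy import stats

from .panel import ATTResult, PanelDataset

__all__ = ["FactorModelFit", "CVResult", "fit_ife", "choose_factors_cv",
           "estimate_ife_att"]

_MAX_ITER = 1000
_TOL = 1e-8


@dataclass
class FactorModelFit:
    beta: np.ndarray          # slope coefficients on kept covariate columns
    tau: float | None         # homogeneous treatment coefficient (if requested)
    factors: np.ndarray       # (T, R), F'F/T = I
    loadings: np.ndarray      # (n, R), M'M diagonal
    unit_effects: np.ndarray  # (n,)
    time_effects: np.ndarray  # (T,)
    intercept: float
    residuals: np.ndarray     # (n, T)
    R: int
    converged: bool
    n_iter: int
    objective: float
    kept_covariates: np.ndarray

    @property
    def common_component(self) -> np.ndarray:
        """The (n, T) interactive part ``mu_i' F_t``."""
        return self.loadings @ self.factors.T

    def fitted(self, exposure: np.ndarray | None = None,
               covariates: np.ndarray | None = None) -> np.ndarray:
        out = (self.intercept + self.unit_effects[:, None]
               + self.time_effects[None, :] + self.common_component)
        if covariates is not None:
            idx = 0
            for j in np.flatnonzero(self.kept_covariates):
                out = out + self.beta[idx] * covariates[:, :, j]
                idx += 1
        if exposure is not None and self.tau is not None:
            out = out + self.tau * exposure
        return out


@dataclass
class CVResult:
    candidate_R: list[int]
    mspe: np.ndarray
    chosen_R: int


def _normalize_factors(C: np.ndarray, R: int):
    """Rank-R SVD of C with F'F/T = I, M'M diagonal; returns (M, F)."""
    T = C.shape[1]
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    F = np.sqrt(T) * Vt[:R].T
    M = U[:, :R] * s[:R] / np.sqrt(T)
    return M, F


def _two_way_decompose(W: np.ndarray):
    grand = W.mean()
    a = W.mean(axis=1) - grand
    g = W.mean(axis=0) - grand
    return grand, a, g, W - grand - a[:, None] - g[None, :]


def fit_ife(
    outcome: np.ndarray,
    covariates: np.ndarray | None,
    R: int,
    exposure: np.ndarray | None = None,
    *,
    two_way: bool = True,
    init_factors: np.ndarray | None = None,
    max_iter: int = _MAX_ITER,
    tol: float = _TOL,
) -> FactorModelFit:
    """Alternating least squares for the interactive fixed effects model.

    Parameters
    ----------
    outcome : (n, T) matrix.
    covariates : (n, T, k) array or None.
    R : number of interactive factors (``R <= min(n, T) - 1``).
    exposure : optional (n, T) treatment indicator; when given, a
        homogeneous coefficient ``tau`` is estimated jointly with beta.
    two_way : include additive unit and period effects (default).  With
        ``two_way=False`` and ``k = 0`` the fit is the plain rank-R
        principal components approximation.
    init_factors : optional (T, R) starting factor matrix (testing hook;
        the default initialization is the SVD of the two-way FE residual).
    """
    Y = np.asarray(outcome, dtype=float)
    n, T = Y.shape
    if covariates is None:
        covariates = np.empty((n, T, 0))
    k = covariates.shape[2]
    if R > min(n, T) - 1:
        raise ValueError(f"R={R} too large for an {n} x {T} panel")

    # collinearity screen: a covariate with no variation beyond the additive
    # effects cannot be identified once two-way effects are included
    keep = np.zeros(k, dtype=bool)
    cols = []
    for j in range(k):
        X = covariates[:, :, j]
        Xd = _two_way_decompose(X)[3] if two_way else X - X.mean()
        if np.sqrt(np.mean(Xd**2)) > 1e-10 * max(np.abs(X).max(), 1.0):
            keep[j] = True
            cols.append(X.ravel())
    if exposure is not None:
        cols.append(np.asarray(exposure, dtype=float).ravel())
    Zraw = np.column_stack(cols) if cols else np.empty((n * T, 0))
    p = Zraw.shape[1]

    def regression_step(C: np.ndarray):
        """LS for (coef, additive effects) given the common component C."""
        Y2 = Y - C
        if two_way:
            if p:
                Zd = np.column_stack(
                    [_two_way_decompose(Zraw[:, j].reshape(n, T))[3].ravel()
                     for j in range(p)]
                )
                coef, *_ = np.linalg.lstsq(Zd, _two_way_decompose(Y2)[3].ravel(),
                                           rcond=None)
            else:
                coef = np.empty(0)
            resid_mat = Y2 - (Zraw @ coef).reshape(n, T) if p else Y2
            grand, a, g, _ = _two_way_decompose(resid_mat)
        else:
            if p:
                coef, *_ = np.linalg.lstsq(Zraw, Y2.ravel(), rcond=None)
            else:
                coef = np.empty(0)
            grand, a, g = 0.0, np.zeros(n), np.zeros(T)
        return coef, grand, a, g

    # init: slopes from the additive model, factors from its residual SVD
    coef, grand, a, g = regression_step(np.zeros((n, T)))
    C = np.zeros((n, T))
    if R > 0:
        W = Y - (Zraw @ coef).reshape(n, T) if p else Y.copy()
        W = W - grand - a[:, None] - g[None, :]
        if init_factors is not None:
            F0 = np.asarray(init_factors, dtype=float)
            M0 = W @ F0 @ np.linalg.inv(F0.T @ F0)
            C = M0 @ F0.T
        else:
            M, F = _normalize_factors(W, R)
            C = M @ F.T

    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        coef_new, grand, a, g = regression_step(C)
        W = Y - (Zraw @ coef_new).reshape(n, T) if p else Y.copy()
        W = W - grand - a[:, None] - g[None, :]
        if two_way:
            # keep the factor part two-way-demeaned: any additive component
            # in the working residual belongs to the unit/time effects (this
            # makes the additive/interactive split unique)
            gd, ad, td, W = (*_two_way_decompose(W),)
            grand, a, g = grand + gd, a + ad, g + td
        if R > 0:
            M, F = _normalize_factors(W, R)
            C_new = M @ F.T
        else:
            M = np.empty((n, 0))
            F = np.empty((T, 0))
            C_new = np.zeros((n, T))
        resid = W - C_new
        obj = float(np.sum(resid**2))
        d_coef = (np.max(np.abs(coef_new - coef)) / (1 + np.max(np.abs(coef_new)))
                  if p else 0.0)
        d_C = np.max(np.abs(C_new - C)) / (1 + np.max(np.abs(C_new)))
        coef, C = coef_new, C_new
        if R == 0 or (d_coef < tol and d_C < tol):
            converged = True
            break
    else:
        warnings.warn("IFE alternation did not converge; returning last iterate")

    tau = None
    beta = coef
    if exposure is not None:
        tau = float(coef[-1])
        beta = coef[:-1]
    return FactorModelFit(
        beta=np.asarray(beta, dtype=float),
        tau=tau,
        factors=F,
        loadings=M,
        unit_effects=a,
        time_effects=g,
        intercept=grand,
        residuals=resid,
        R=R,
        converged=converged,
        n_iter=n_iter,
        objective=obj,
        kept_covariates=keep,
    )


def _project_on_factors(y_adj: np.ndarray, F_block: np.ndarray):
    """Per-unit LS of adjusted outcomes on [1, F] over a period block.

    y_adj: (m, q) adjusted outcomes for m units over q periods;
    F_block: (q, R).  Returns (intercepts (m,), loadings (m, R)).
    """
    q = F_block.shape[0]
    Xd = np.column_stack([np.ones(q), F_block])
    sol, *_ = np.linalg.lstsq(Xd, y_adj.T, rcond=None)
    return sol[0], sol[1:].T


def choose_factors_cv(panel: PanelDataset, R_max: int = 5) -> CVResult:
    """Select the factor count by leave-one-pre-period-out prediction.

    For each candidate R in 0..R_max the factor model is fit to the control
    units over all periods; then, for each pre-treatment period s in turn,
    treated-unit loadings are estimated from the remaining pre-periods and
    the held-out treated outcomes at s are predicted.  The chosen R
    minimizes the accumulated squared prediction error (ties broken toward
    smaller R).

    Requires ``t' >= R_max + 1`` so that every candidate leaves enough
    periods to identify the loadings.
    """
    t_pre = int(panel.last_pre)
    feasible = t_pre - 1  # need R + 1 pre-periods, one of which is held out
    if R_max + 1 > t_pre:
        raise ValueError(
            f"{t_pre} pre-periods support cross-validation only up to "
            f"R_max={max(feasible, 0)} (need R_max + 1 pre-periods)"
        )
    tr = panel.treated
    Yc = panel.outcome[~tr]
    Xc = panel.covariates[~tr]
    Yt = panel.outcome[tr]
    Xt = panel.covariates[tr]
    pre_idx = np.arange(t_pre)

    candidates = list(range(R_max + 1))
    mspe = np.empty(len(candidates))
    for R in candidates:
        fit = fit_ife(Yc, Xc, R)
        y_adj = Yt - fit.time_effects[None, :] - fit.intercept
        idx = 0
        for j in np.flatnonzero(fit.kept_covariates):
            y_adj = y_adj - fit.beta[idx] * Xt[:, :, j]
            idx += 1
        err = 0.0
        for s in pre_idx:
            rest = pre_idx[pre_idx != s]
            a_i, m_i = _project_on_factors(y_adj[:, rest], fit.factors[rest])
            pred = a_i + m_i @ fit.factors[s]
            err += float(np.sum((y_adj[:, s] - pred) ** 2))
        mspe[R] = err / (Yt.shape[0] * t_pre)
    chosen = int(np.argmin(mspe))  # argmin takes the first minimum: smaller R
    return CVResult(candidate_R=candidates, mspe=mspe, chosen_R=chosen)


def estimate_ife_att(
    panel: PanelDataset,
    R: int | str = "cv",
    *,
    R_max: int = 5,
    inference: bool = True,
) -> ATTResult:
    """ATT from the interactive FE model with a homogeneous effect coefficient.

    The model is fit on all units with the treatment term included;
    ``att = tau_hat``.  Standard errors are cluster-robust over units with
    the estimated factors treated as known regressors (factor-estimation
    uncertainty is ignored, a deliberate understatement matching common
    reporting practice).
    """
    cv: CVResult | None = None
    if R == "cv":
        cap = min(R_max, int(panel.last_pre) - 1)
        cv = choose_factors_cv(panel, R_max=cap)
        R_use = cv.chosen_R
    else:
        R_use = int(R)
    fit = fit_ife(panel.outcome, panel.covariates, R_use, panel.exposure)
    att = float(fit.tau)

    se = ci_low = ci_high = p = None
    if inference:
        se, p, ci_low, ci_high = _ife_cluster_inference(panel, fit)
    post = panel.post_periods()
    diagnostics: dict[str, Any] = {
        "R": R_use,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
    }
    if cv is not None:
        diagnostics["cv_mspe"] = cv.mspe
    return ATTResult(
        method="ife",
        att=att,
        att_by_period=np.full(len(post), att),
        post_periods=post,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        p_value=p,
        inference_method="cluster_robust" if inference else None,
        diagnostics=diagnostics,
    )


def _ife_cluster_inference(panel: PanelDataset, fit: FactorModelFit):
    """CR1 cluster-robust se for tau, conditioning on the estimated factors."""
    n, T = panel.outcome.shape
    D = panel.exposure
    # regressors: kept covariates, exposure; estimated common component and
    # additive effects are subtracted from the outcome
    cols = [panel.covariates[:, :, j].ravel()
            for j in np.flatnonzero(fit.kept_covariates)]
    cols.append(D.ravel())
    Z = np.column_stack(cols)
    yc = (panel.outcome - fit.common_component).ravel()
    # absorb additive two-way effects by demeaning everything
    def dm(v):
        M = v.reshape(n, T)
        return (M - M.mean(axis=1, keepdims=True)
                - M.mean(axis=0, keepdims=True) + M.mean()).ravel()
    Zd = np.column_stack([dm(Z[:, j]) for j in range(Z.shape[1])])
    yd = dm(yc)
    resid = yd - Zd @ np.concatenate([fit.beta, [fit.tau]])
    p_ = Zd.shape[1]
    bread = np.linalg.pinv(Zd.T @ Zd)
    scores = (Zd * resid[:, None]).reshape(n, T, p_).sum(axis=1)
    meat = scores.T @ scores
    N = n * T
    k_total = 1 + (n - 1) + (T - 1) + p_ + fit.R * (n + T)
    k_total = min(k_total, N - 1)
    c = (n / (n - 1)) * ((N - 1) / (N - k_total))
    V = c * bread @ meat @ bread
    se = float(np.sqrt(V[-1, -1]))
    df = n - 1
    t_stat = fit.tau / se if se > 0 else np.inf
    p = float(2 * stats.t.sf(abs(t_stat), df))
    tcrit = stats.t.ppf(0.975, df)
    return se, p, fit.tau - tcrit * se, fit.tau + tcrit * se
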