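"""Two-way fixed-effects difference-in-differences estimation.

The estimator regresses ``Y_it`` on covariates, unit effects, period
effects, and the block exposure indicator ``D_it``.  It is computed by the
within (two-way demeaning) transformation, which on a balanced panel is
numerically identical to the least-squares dummy-variable regression.
Inference is cluster-robust with clusters = units (CR1 small-sample
correction).  A joint Wald test of treated-group x pre-period interactions
provides a pre-trends diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .panel import ATTResult, PanelDataset

__all__ = ["DiDFit", "fit_did", "cluster_robust_vcov", "parallel_trends_test"]


class InferenceError(RuntimeError):
    """Raised when the requested variance estimator is undefined."""


@dataclass
class DiDFit:
    """Coefficients and effects of the two-way FE regression.

    Unit and time effects are normalized to each sum to zero; the grand
    mean is carried by ``intercept``.
    """

    beta: np.ndarray
    tau: float
    unit_effects: np.ndarray
    time_effects: np.ndarray
    intercept: float
    vcov: np.ndarray
    n_clusters: int
    kept_covariates: np.ndarray  # boolean mask over covariate columns
    residuals: np.ndarray  # (n, T)


def _two_way_demean(M: np.ndarray) -> np.ndarray:
    """Remove row means, column means, and add back the grand mean."""
    return M - M.mean(axis=1, keepdims=True) - M.mean(axis=0, keepdims=True) + M.mean()


def _build_within(panel: PanelDataset, extra: list[np.ndarray]):
    """Demean covariates + extra (n,T) regressors; drop collinear columns.

    Returns (Z, y, keep_cov) with Z of shape (n*T, p): kept covariate
    columns first, then the extra regressors.  A covariate whose within
    variation is numerically zero (e.g. time-invariant, absorbed by unit
    effects) is dropped.
    """
    n, T, k = panel.covariates.shape
    y = _two_way_demean(panel.outcome).ravel()
    cols, keep = [], np.zeros(k, dtype=bool)
    for j in range(k):
        X = panel.covariates[:, :, j]
        Xd = _two_way_demean(X)
        scale = max(np.abs(X).max(), 1.0)
        if np.sqrt(np.mean(Xd**2)) > 1e-10 * scale:
            keep[j] = True
            cols.append(Xd.ravel())
    for E in extra:
        cols.append(_two_way_demean(E).ravel())
    Z = np.column_stack(cols) if cols else np.empty((n * T, 0))
    return Z, y, keep


def _cluster_vcov(Z, resid, n_units, T, k_total):
    """CR1 sandwich: unit-level score sums, factor G/(G-1) * (N-1)/(N-K)."""
    G, N, p = n_units, n_units * T, Z.shape[1]
    if G < 2 or N - k_total <= 0:  # saturated model: no residual df
        return np.full((p, p), np.nan)
    bread = np.linalg.pinv(Z.T @ Z)
    scores = (Z * resid[:, None]).reshape(G, T, p).sum(axis=1)
    meat = scores.T @ scores
    c = (G / (G - 1)) * ((N - 1) / (N - k_total))
    return c * bread @ meat @ bread


def _fit_within(panel: PanelDataset, extra: list[np.ndarray]):
    """Two-way FE OLS of outcome on covariates + extra regressors."""
    n, T, k = panel.covariates.shape
    Z, y, keep = _build_within(panel, extra)
    if Z.shape[1] == 0:
        raise ValueError("no regressors after dropping collinear covariates")
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ coef
    # K of the dummy-variable parameterization: intercept + (n-1) + (T-1)
    # unit/time dummies + retained slope coefficients.
    k_total = 1 + (n - 1) + (T - 1) + Z.shape[1]
    vcov = _cluster_vcov(Z, resid, n, T, k_total) if n >= 2 else np.full((Z.shape[1],) * 2, np.nan)
    return coef, vcov, resid, keep, Z, y


def _effects_from_residual(panel, coef, keep, extra):
    """Recover sum-to-zero unit/time effects and the intercept."""
    n, T, _ = panel.covariates.shape
    R = panel.outcome.copy()
    idx = 0
    for j in np.flatnonzero(keep):
        R -= coef[idx] * panel.covariates[:, :, j]
        idx += 1
    for E in extra:
        R -= coef[idx] * E
        idx += 1
    grand = R.mean()
    unit_eff = R.mean(axis=1) - grand
    time_eff = R.mean(axis=0) - grand
    resid = R - grand - unit_eff[:, None] - time_eff[None, :]
    return unit_eff, time_eff, grand, resid


def fit_did_full(panel: PanelDataset) -> DiDFit:
    """Fit the two-way FE DiD regression and return the full coefficient set."""
    D = panel.exposure
    coef, vcov, _, keep, Z, y = _fit_within(panel, [D])
    unit_eff, time_eff, grand, resid = _effects_from_residual(panel, coef, keep, [D])
    return DiDFit(
        beta=coef[:-1],
        tau=float(coef[-1]),
        unit_effects=unit_eff,
        time_effects=time_eff,
        intercept=grand,
        vcov=vcov,
        n_clusters=panel.n_units,
        kept_covariates=keep,
        residuals=resid,
    )


def fit_did(panel: PanelDataset, *, inference: bool = True) -> ATTResult:
    """DiD estimate of the ATT with cluster-robust inference.

    The point estimate is the coefficient on ``D_it``; per-post-period
    effects come from an event-study variant with a separate interaction
    per post period (identical to the pooled estimate when there are no
    covariates).  With fewer than 2 units the point estimate is returned
    without standard errors.
    """
    fit = fit_did_full(panel)
    att = fit.tau
    post = panel.post_periods()
    # event-study: one treated x period indicator per post period
    dummies = [
        np.outer(panel.treated, (panel.time_ids == t).astype(float)) for t in post
    ]
    coef_es = _fit_within(panel, dummies)[0]
    n_keep = int(fit.kept_covariates.sum())
    att_by_period = coef_es[n_keep:]

    se = ci = p = None
    if inference:
        if panel.n_units < 2:
            raise InferenceError("cluster-robust inference needs at least 2 units")
        se = float(np.sqrt(fit.vcov[-1, -1]))
        df = fit.n_clusters - 1
        tcrit = stats.t.ppf(0.975, df)
        ci = (att - tcrit * se, att + tcrit * se)
        p = float(2 * stats.t.sf(abs(att / se), df)) if se > 0 else float(att == 0.0)
    return ATTResult(
        method="did",
        att=att,
        att_by_period=att_by_period,
        post_periods=post,
        se=se,
        ci_low=None if ci is None else ci[0],
        ci_high=None if ci is None else ci[1],
        p_value=p,
        inference_method="cluster_robust" if inference else None,
        diagnostics={"n_clusters": fit.n_clusters,
                     "dropped_covariates": int((~fit.kept_covariates).sum())},
    )


def cluster_robust_vcov(fit: DiDFit, panel: PanelDataset) -> np.ndarray:
    """Recompute the CR1 cluster-robust covariance of (beta, tau).

    Sandwich estimator with unit-level score sums and the finite-sample
    factor G/(G-1) * (N-1)/(N-K); K counts all coefficients of the
    dummy-variable parameterization.
    """
    if panel.n_units < 2:
        raise InferenceError("cluster-robust variance needs at least 2 clusters")
    Z, y, _ = _build_within(panel, [panel.exposure])
    coef = np.concatenate([fit.beta, [fit.tau]])
    resid = y - Z @ coef
    n, T = panel.outcome.shape
    k_total = 1 + (n - 1) + (T - 1) + Z.shape[1]
    return _cluster_vcov(Z, resid, n, T, k_total)


def parallel_trends_test(panel: PanelDataset) -> float:
    """Joint Wald test that pre-period group x time interactions are zero.

    Restricted to the pre-treatment periods, the outcome is regressed on
    unit effects, period effects, covariates, and treated-group x period
    indicators (first pre-period omitted as reference).  The statistic is
    the cluster-robust Wald chi-square on the interaction block; small
    p-values indicate diverging pre-trends.
    """
    t_pre = int(panel.last_pre)
    if t_pre < 3:
        raise ValueError("pre-trends test needs at least 3 pre-treatment periods")
    pre = ~panel.is_post
    from dataclasses import replace

    sub = replace(
        panel,
        time_ids=np.arange(1, t_pre + 1),
        outcome=panel.outcome[:, pre],
        covariates=panel.covariates[:, pre, :],
        last_pre=t_pre - 1,  # placeholder; exposure is unused here
        time_labels=None,
    )
    inter = [
        np.outer(panel.treated, (sub.time_ids == t).astype(float))
        for t in range(2, t_pre + 1)
    ]
    Z, y, keep = _build_within(sub, inter)
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ coef
    n = panel.n_units
    k_total = 1 + (n - 1) + (t_pre - 1) + Z.shape[1]
    V = _cluster_vcov(Z, resid, n, t_pre, k_total)
    q = len(inter)
    b = coef[-q:]
    Vq = V[-q:, -q:]
    W = float(b @ np.linalg.pinv(Vq) @ b)
    if not np.isfinite(W) or W < 0:
        W = 0.0
    return float(stats.chi2.sf(W, q))
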