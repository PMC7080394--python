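"""Balanced pre-post panel data model, validation, and I/O.

A :class:`PanelDataset` holds a balanced n x T panel of outcomes ``Y_it``,
optional time-varying covariates ``X_it``, and a binary treatment-group
flag ``D_i``.  Treatment adoption is simultaneous ("block"): every treated
unit is exposed in every period after the designated last pre-treatment
period ``t'``, so the exposure indicator is ``D_it = D_i * 1[t > t']``.
Staggered adoption is rejected by construction.

Periods are re-indexed to consecutive 1-based integers on load; the
post-treatment block is the half-open set ``{t : t > t'}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelDataset",
    "ATTResult",
    "PanelValidationError",
    "BalancedPanelError",
    "load_panel",
    "write_panel",
    "panel_from_arrays",
    "average_treated",
    "split_groups",
]


class PanelValidationError(ValueError):
    """A panel violates one of the structural invariants."""


class BalancedPanelError(PanelValidationError):
    """A (unit, period) cell is missing or non-finite."""


@dataclass(frozen=True)
class PanelDataset:
    """Balanced panel of outcomes, covariates, and block treatment exposure.

    Attributes
    ----------
    unit_ids : ndarray, shape (n,)
        Unit identifiers (any hashable labels).
    time_ids : ndarray, shape (T,)
        Consecutive 1-based integer period indices.
    outcome : ndarray, shape (n, T)
        Observed outcome ``Y_it``.
    covariates : ndarray, shape (n, T, k)
        Time-varying covariates ``X_it`` (``k >= 0``; a time-invariant
        covariate is stored by repetition across periods).
    treated : ndarray of bool, shape (n,)
        Treatment-group membership ``D_i``.
    last_pre : int
        The final pre-treatment period ``t'`` (1-based, ``1 <= t' < T``).
    time_labels : ndarray, shape (T,), optional
        Original period labels prior to re-indexing (kept for reporting).
    """

    unit_ids: np.ndarray
    time_ids: np.ndarray
    outcome: np.ndarray
    covariates: np.ndarray
    treated: np.ndarray
    last_pre: int
    time_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "unit_ids", np.asarray(self.unit_ids))
        object.__setattr__(self, "time_ids", np.asarray(self.time_ids, dtype=int))
        object.__setattr__(self, "outcome", np.asarray(self.outcome, dtype=float))
        cov = np.asarray(self.covariates, dtype=float)
        if cov.ndim == 2:  # allow (n, T) shorthand for k = 0
            cov = cov.reshape(cov.shape + (0,)) if cov.size == 0 else cov[:, :, None]
        object.__setattr__(self, "covariates", cov)
        object.__setattr__(self, "treated", np.asarray(self.treated, dtype=bool))
        self._validate()

    # -- structural invariants -------------------------------------------
    def _validate(self) -> None:
        n, T = self.outcome.shape
        if len(self.unit_ids) != n:
            raise PanelValidationError(
                f"{len(self.unit_ids)} unit ids for {n} outcome rows"
            )
        if len(self.time_ids) != T:
            raise PanelValidationError(
                f"{len(self.time_ids)} time ids for {T} outcome columns"
            )
        if not np.array_equal(self.time_ids, np.arange(1, T + 1)):
            raise PanelValidationError(
                "time_ids must be consecutive 1-based integers after loading"
            )
        if self.covariates.shape[:2] != (n, T):
            raise PanelValidationError(
                f"covariates shape {self.covariates.shape} incompatible with ({n}, {T})"
            )
        if not np.all(np.isfinite(self.outcome)):
            i, t = np.argwhere(~np.isfinite(self.outcome))[0]
            raise BalancedPanelError(
                f"non-finite outcome for unit {self.unit_ids[i]!r}, period {t + 1}"
            )
        if self.covariates.size and not np.all(np.isfinite(self.covariates)):
            i, t, _ = np.argwhere(~np.isfinite(self.covariates))[0]
            raise BalancedPanelError(
                f"non-finite covariate for unit {self.unit_ids[i]!r}, period {t + 1}"
            )
        if len(self.treated) != n:
            raise PanelValidationError("treated flag length mismatch")
        if not (1 <= self.last_pre < T):
            raise PanelValidationError(
                f"last pre-treatment period t'={self.last_pre} outside [1, {T - 1}]"
            )
        if self.n_treated < 1:
            raise PanelValidationError("panel needs at least one treated unit")
        # estimators impose their own donor/cluster minima (e.g. SC needs
        # >= 2 control units); the data container only needs a comparison group
        if self.n_control < 1:
            raise PanelValidationError("panel needs at least one control unit")

    # -- derived quantities ----------------------------------------------
    @property
    def n_units(self) -> int:
        return self.outcome.shape[0]

    @property
    def n_periods(self) -> int:
        return self.outcome.shape[1]

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[2]

    @property
    def n_treated(self) -> int:
        return int(self.treated.sum())

    @property
    def n_control(self) -> int:
        return int((~self.treated).sum())

    @property
    def is_post(self) -> np.ndarray:
        """Boolean period mask, shape (T,): True for t > t'."""
        return self.time_ids > self.last_pre

    @property
    def exposure(self) -> np.ndarray:
        """Block exposure matrix D_it = D_i * 1[t > t'], shape (n, T)."""
        return np.outer(self.treated, self.is_post).astype(float)

    def pre_periods(self) -> np.ndarray:
        return self.time_ids[~self.is_post]

    def post_periods(self) -> np.ndarray:
        return self.time_ids[self.is_post]

    def to_frame(self, mapping: Mapping[str, Any] | None = None) -> pd.DataFrame:
        """Long-format DataFrame, one row per (unit, period)."""
        m = dict(_DEFAULT_MAPPING)
        if mapping:
            m.update(mapping)
        n, T, k = self.covariates.shape
        labels = self.time_labels if self.time_labels is not None else self.time_ids
        data = {
            m["unit"]: np.repeat(self.unit_ids, T),
            m["time"]: np.tile(labels, n),
            m["outcome"]: self.outcome.ravel(),
            m["treated"]: np.repeat(self.treated.astype(int), T),
        }
        cov_names = m.get("covariates") or [f"x{j + 1}" for j in range(k)]
        for j, name in enumerate(cov_names):
            data[name] = self.covariates[:, :, j].ravel()
        return pd.DataFrame(data)


@dataclass
class ATTResult:
    """A method-tagged estimate of the average treatment effect on the treated.

    ``att`` is the mean of the per-post-period effects in ``att_by_period``;
    the inference fields are absent (None) when inference was not requested.
    """

    method: str
    att: float
    att_by_period: np.ndarray
    post_periods: np.ndarray
    se: float | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    p_value: float | None = None
    inference_method: str | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.att_by_period = np.asarray(self.att_by_period, dtype=float)
        self.post_periods = np.asarray(self.post_periods, dtype=int)
        if self.p_value is not None and not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")

    def summary_frame(self) -> pd.DataFrame:
        """One-row frame: method, att, se, ci_low, ci_high, p_value."""
        def _num(x):
            return np.nan if x is None else x

        return pd.DataFrame(
            [
                {
                    "method": self.method,
                    "att": self.att,
                    "se": _num(self.se),
                    "ci_low": _num(self.ci_low),
                    "ci_high": _num(self.ci_high),
                    "p_value": _num(self.p_value),
                    "inference": self.inference_method,
                }
            ]
        )

    def by_period_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"period": self.post_periods, "att": self.att_by_period}
        )


_DEFAULT_MAPPING: dict[str, Any] = {
    "unit": "unit",
    "time": "time",
    "outcome": "outcome",
    "treated": "treated",
    "covariates": [],
}


def panel_from_arrays(
    outcome: np.ndarray,
    treated: Sequence[int] | np.ndarray,
    last_pre: int,
    covariates: np.ndarray | None = None,
    unit_ids: Sequence[Any] | None = None,
) -> PanelDataset:
    """Build a validated panel directly from arrays (periods 1..T)."""
    outcome = np.asarray(outcome, dtype=float)
    n, T = outcome.shape
    if covariates is None:
        covariates = np.empty((n, T, 0))
    if unit_ids is None:
        unit_ids = np.arange(1, n + 1)
    return PanelDataset(
        unit_ids=np.asarray(unit_ids),
        time_ids=np.arange(1, T + 1),
        outcome=outcome,
        covariates=covariates,
        treated=np.asarray(treated),
        last_pre=int(last_pre),
    )


def load_panel(
    path,
    mapping: Mapping[str, Any],
    *,
    sep: str = ",",
) -> PanelDataset:
    """Read a long-format delimited file into a validated :class:`PanelDataset`.

    Parameters
    ----------
    path : path-like
        Delimited text file with one row per (unit, period).
    mapping : mapping
        Column-name map with keys ``unit``, ``time``, ``outcome``,
        ``treated``, optional ``covariates`` (list of column names), and
        ``last_pre`` — the *value* (original period label) of the final
        pre-treatment period.

    Raises
    ------
    BalancedPanelError
        If any (unit, period) combination is missing or duplicated.
    PanelValidationError
        If the treated flag is not binary or ``last_pre`` is out of range.
    """
    m = dict(mapping)
    df = pd.read_csv(path, sep=sep)
    for key in ("unit", "time", "outcome", "treated"):
        if key not in m:
            raise PanelValidationError(f"column mapping is missing the {key!r} key")
        if m[key] not in df.columns:
            raise PanelValidationError(
                f"column {m[key]!r} (mapped from {key!r}) not found in file"
            )
    cov_cols = list(m.get("covariates") or [])
    for c in cov_cols:
        if c not in df.columns:
            raise PanelValidationError(f"covariate column {c!r} not found in file")

    units = pd.unique(df[m["unit"]])
    times = np.sort(pd.unique(df[m["time"]]))
    n, T = len(units), len(times)

    counts = df.groupby([m["unit"], m["time"]], sort=False).size()
    if (counts > 1).any():
        u, t = counts[counts > 1].index[0]
        raise BalancedPanelError(f"duplicate row for unit {u!r}, period {t!r}")
    if len(counts) != n * T:
        have = set(counts.index)
        for u in units:
            for t in times:
                if (u, t) not in have:
                    raise BalancedPanelError(f"missing row for unit {u!r}, period {t!r}")

    uidx = pd.Categorical(df[m["unit"]], categories=units).codes
    tidx = np.searchsorted(times, df[m["time"]].to_numpy())
    outcome = np.full((n, T), np.nan)
    outcome[uidx, tidx] = df[m["outcome"]].to_numpy(dtype=float)
    covariates = np.full((n, T, len(cov_cols)), np.nan)
    for j, c in enumerate(cov_cols):
        covariates[uidx, tidx, j] = df[c].to_numpy(dtype=float)

    flag = np.full(n, -1.0)
    flag[uidx] = df[m["treated"]].to_numpy(dtype=float)
    if not np.all(np.isin(flag, (0.0, 1.0))):
        raise PanelValidationError("treated flag must be binary 0/1")
    per_unit = df.groupby(m["unit"], sort=False)[m["treated"]].nunique()
    if (per_unit > 1).any():
        u = per_unit[per_unit > 1].index[0]
        raise PanelValidationError(
            f"unit {u!r} changes treated flag over time; only block adoption is supported"
        )

    if "last_pre" not in m:
        raise PanelValidationError("column mapping must carry the 'last_pre' period value")
    where = np.flatnonzero(times == m["last_pre"])
    if len(where) == 0:
        raise PanelValidationError(
            f"last pre-treatment period {m['last_pre']!r} not among observed periods"
        )
    last_pre = int(where[0]) + 1  # re-indexed 1-based position

    return PanelDataset(
        unit_ids=np.asarray(units),
        time_ids=np.arange(1, T + 1),
        outcome=outcome,
        covariates=covariates,
        treated=flag.astype(bool),
        last_pre=last_pre,
        time_labels=times,
    )


def write_panel(
    panel: PanelDataset,
    path,
    mapping: Mapping[str, Any] | None = None,
    *,
    sep: str = ",",
) -> None:
    """Write a panel back to long-format delimited text (round-trips load_panel)."""
    panel.to_frame(mapping).to_csv(path, sep=sep, index=False)


def average_treated(panel: PanelDataset) -> PanelDataset:
    """Collapse all treated units into a single pseudo-unit by unweighted means.

    Outcomes and covariates of the pseudo-unit are the per-period means over
    treated units; control units are unchanged.  With one treated unit the
    panel is returned unchanged.
    """
    if panel.n_treated == 0:
        raise PanelValidationError("panel has no treated units to average")
    if panel.n_treated == 1:
        return panel
    tr = panel.treated
    out = np.vstack([panel.outcome[tr].mean(axis=0)[None, :], panel.outcome[~tr]])
    cov = np.concatenate(
        [panel.covariates[tr].mean(axis=0)[None], panel.covariates[~tr]], axis=0
    )
    ids = np.concatenate([np.asarray(["treated_avg"], dtype=object),
                          panel.unit_ids[~tr].astype(object)])
    flags = np.concatenate([[True], np.zeros(panel.n_control, dtype=bool)])
    return replace(
        panel,
        unit_ids=ids,
        outcome=out,
        covariates=cov,
        treated=flags,
    )


def split_groups(panel: PanelDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition into treated and control sub-frames over all T periods.

    Returns long-format DataFrames (the control group alone cannot form a
    valid :class:`PanelDataset`, which requires a treated unit).
    """
    df = panel.to_frame()
    tset = set(panel.unit_ids[panel.treated])
    is_tr = df["unit"].isin(tset)
    return df[is_tr].reset_index(drop=True), df[~is_tr].reset_index(drop=True)
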