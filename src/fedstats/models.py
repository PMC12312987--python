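"""Federated multivariate models without differential privacy.

Two estimators, both exactly equivalent to their centralized
counterparts because the likelihoods separate over sites:

* :func:`fed_ols` — linear regression via one round of sufficient
  statistics: each node ships (X'X, X'y, y'y, n), the coordinator solves
  the pooled normal equations.  Bit-for-bit the centralized least
  squares fit.

* :func:`fed_cox` — Cox proportional hazards stratified by center.
  Risk sets never cross nodes, so each node evaluates the gradient and
  Hessian of its own stratum's Breslow partial log-likelihood at the
  current coefficients and the coordinator runs Newton-Raphson on the
  sums.  Identical to a centralized stratified fit.

Neither message ever contains more than p-vectors and p x p matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortTable

__all__ = [
    "DesignSpec",
    "ModelFit",
    "RankDeficiencyError",
    "design_matrix",
    "fed_ols",
    "fed_cox",
    "cox_loglik_grad_hess",
    "significance_by_ci",
]

PERIOD_LEVELS = ("before", "after")


class RankDeficiencyError(np.linalg.LinAlgError):
    pass


@dataclass(frozen=True)
class DesignSpec:
    """Response, covariates and reference levels for dummy coding.

    Categorical covariates are reference-coded: one indicator per
    non-reference level.  By default the reference for ``period`` is
    ``after`` (so the period coefficient reads "before vs after") and
    for every other categorical variable its first declared level.
    """

    response: str
    covariates: tuple[str, ...]
    reference: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.response in self.covariates:
            raise ValueError("response cannot appear among covariates")


def _levels_for(var: str, table: CohortTable) -> list[str] | None:
    if var == "period":
        return list(PERIOD_LEVELS)
    schema = table.schemas.get(var)
    if schema is not None and schema.categories is not None:
        return list(schema.categories)
    return None


def design_matrix(
    df: pd.DataFrame, design: DesignSpec, table: CohortTable, include_response: bool = True
) -> tuple[pd.DataFrame, pd.Series | None]:
    """Complete-case design matrix with intercept and reference-coded dummies."""
    used = list(design.covariates) + ([design.response] if include_response else [])
    rows = df.dropna(subset=[c for c in used if c in df.columns])
    X = pd.DataFrame(index=rows.index)
    X["intercept"] = 1.0
    for var in design.covariates:
        levels = _levels_for(var, table)
        if levels is None:
            X[var] = rows[var].astype(float)
            continue
        ref = design.reference.get(var, "after" if var == "period" else levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not among levels of {var!r}")
        for lvl in levels:
            if lvl == ref:
                continue
            X[f"{var}[{lvl}]"] = (rows[var] == lvl).astype(float)
    y = rows[design.response].astype(float) if include_response else None
    return X, y


@dataclass
class ModelFit:
    """Coefficients, covariance and 95% CIs of a federated fit."""

    kind: str
    params: pd.Series
    cov: pd.DataFrame
    conf_int: pd.DataFrame  # columns: lower, upper
    n: int
    converged: bool = True
    iterations: int = 0
    loglik: float | None = None

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def hazard_ratios(self) -> pd.DataFrame:
        if self.kind != "cox":
            raise ValueError("hazard ratios only defined for Cox fits")
        return pd.DataFrame(
            {
                "HR": np.exp(self.params),
                "lower": np.exp(self.conf_int["lower"]),
                "upper": np.exp(self.conf_int["upper"]),
            }
        )


def _check_rank(xtx: np.ndarray, columns: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(xtx)
    if rank < xtx.shape[0]:
        # name columns in the null space
        _, s, vt = np.linalg.svd(xtx)
        null = vt[rank:]
        involved = sorted(
            {columns[j] for row in null for j in np.flatnonzero(np.abs(row) > 1e-8)}
        )
        raise RankDeficiencyError(f"design is rank-deficient; collinear columns: {involved}")


def fed_ols(nodes: Sequence, design: DesignSpec) -> ModelFit:
    """Pooled linear regression from per-node cross-products.

    Each node contributes X'X (p x p), X'y (p), y'y and n on its own
    complete cases; the coordinator solves the summed normal equations
    and recovers the residual variance from the pooled pieces, so the
    result equals ordinary least squares on the concatenated data.
    """
    columns: list[str] | None = None
    xtx = xty = None
    yty = 0.0
    n_total = 0
    for nd in nodes:
        table = nd.table if hasattr(nd, "table") else nd
        X, y = design_matrix(table.df, design, table)
        if columns is None:
            columns = list(X.columns)
            p = len(columns)
            xtx = np.zeros((p, p))
            xty = np.zeros(p)
        elif list(X.columns) != columns:
            raise ValueError("schema mismatch across nodes")
        Xv = X.to_numpy(float)
        yv = y.to_numpy(float)
        xtx += Xv.T @ Xv
        xty += Xv.T @ yv
        yty += float(yv @ yv)
        n_total += len(X)
    p = len(columns)
    if n_total <= p:
        raise ValueError(f"need more observations ({n_total}) than parameters ({p})")
    _check_rank(xtx, columns)
    beta = np.linalg.solve(xtx, xty)
    rss = yty - 2 * beta @ xty + beta @ xtx @ beta
    dof = n_total - p
    sigma2 = max(rss, 0.0) / dof
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    tq = stats.t.ppf(0.975, dof)
    ci = pd.DataFrame(
        {"lower": beta - tq * se, "upper": beta + tq * se}, index=columns
    )
    return ModelFit(
        kind="ols",
        params=pd.Series(beta, index=columns),
        cov=pd.DataFrame(cov, index=columns, columns=columns),
        conf_int=ci,
        n=n_total,
    )


def cox_loglik_grad_hess(
    X: np.ndarray, time: np.ndarray, event: np.ndarray, beta: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Breslow partial log-likelihood, gradient and Hessian for one stratum.

    Each event at time t contributes x'beta - log S0(t) with
    S0(t) = sum over the at-risk set {T_j >= t} of exp(x_j'beta); tied
    events reuse the same risk set (Breslow convention).
    """
    order = np.argsort(time, kind="stable")
    X = X[order]
    time = time[order]
    event = event[order].astype(bool)
    eta = X @ beta
    eta -= eta.max()  # guard overflow; cancels in all ratios and in loglik up to const
    w = np.exp(eta)
    wx = w[:, None] * X
    wxx = w[:, None, None] * (X[:, :, None] * X[:, None, :])
    # suffix sums: risk set of an event at position k is indices >= first index with same time
    s0 = np.cumsum(w[::-1])[::-1]
    s1 = np.cumsum(wx[::-1], axis=0)[::-1]
    s2 = np.cumsum(wxx[::-1], axis=0)[::-1]
    start = np.searchsorted(time, time, side="left")
    ll = 0.0
    g = np.zeros_like(beta)
    h = np.zeros((beta.size, beta.size))
    for k in np.flatnonzero(event):
        r = start[k]
        ll += eta[k] - math.log(s0[r])
        m1 = s1[r] / s0[r]
        g += X[k] - m1
        h -= s2[r] / s0[r] - np.outer(m1, m1)
    return ll, g, h


def _cox_node_data(
    nd, design: DesignSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str]]:
    table: CohortTable = nd.table if hasattr(nd, "table") else nd
    out = table.outcomes().set_index("patient_id")
    df = table.df.set_index("patient_id").join(out[["time_days", "event"]])
    X, _ = design_matrix(df, design, table, include_response=False)
    X = X.drop(columns=["intercept"])
    rows = df.loc[X.index]
    return (
        X.to_numpy(float),
        rows["time_days"].to_numpy(float),
        rows["event"].to_numpy(float),
        list(X.columns),
    )


def fed_cox(
    nodes: Sequence,
    design: DesignSpec,
    outcomes: Mapping[str, pd.DataFrame] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> ModelFit:
    """Center-stratified Cox model via distributed Newton-Raphson.

    Per iteration every node evaluates (loglik, gradient, Hessian) of its
    stratum's Breslow partial likelihood at the shared coefficients; the
    coordinator sums them and takes a Newton step (with step-halving),
    stopping when the pooled gradient norm falls below ``tol``.
    Variance is the inverse observed information; hazard-ratio CIs are
    exp(beta +/- 1.96 se).
    """
    data = []
    columns: list[str] | None = None
    for nd in nodes:
        if outcomes is not None:
            table: CohortTable = nd.table if hasattr(nd, "table") else nd
            oc = outcomes[getattr(nd, "id", table.center)]
            df = table.df.set_index("patient_id").join(
                oc.set_index("patient_id")[["time_days", "event"]]
            )
            X, _ = design_matrix(df, design, table, include_response=False)
            X = X.drop(columns=["intercept"])
            rows = df.loc[X.index]
            tup = (
                X.to_numpy(float),
                rows["time_days"].to_numpy(float),
                rows["event"].to_numpy(float),
                list(X.columns),
            )
        else:
            tup = _cox_node_data(nd, design)
        if columns is None:
            columns = tup[3]
        elif tup[3] != columns:
            raise ValueError("schema mismatch across nodes")
        if tup[2].sum() >= 1:  # strata without events contribute nothing
            data.append(tup[:3])
    if not data:
        raise ValueError("no events in any stratum")
    p = len(columns)
    n_total = sum(len(t) for _, t, _ in data)

    beta = np.zeros(p)
    ll_prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll, g, h = 0.0, np.zeros(p), np.zeros((p, p))
        for Xs, ts, es in data:
            lls, gs, hs = cox_loglik_grad_hess(Xs, ts, es, beta)
            ll, g, h = ll + lls, g + gs, h + hs
        if np.linalg.norm(g) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-h, g)
        except np.linalg.LinAlgError as exc:
            raise RankDeficiencyError(f"singular information matrix: {exc}") from exc
        # step-halving keeps the likelihood monotone
        scale = 1.0
        while scale > 1e-6:
            cand = beta + scale * step
            ll_c = sum(cox_loglik_grad_hess(Xs, ts, es, cand)[0] for Xs, ts, es in data)
            if ll_c >= ll - 1e-12:
                break
            scale /= 2.0
        beta = beta + scale * step
        ll_prev = ll
    # information at the solution
    h = np.zeros((p, p))
    ll = 0.0
    for Xs, ts, es in data:
        lls, _, hs = cox_loglik_grad_hess(Xs, ts, es, beta)
        ll += lls
        h += hs
    cov = np.linalg.inv(-h)
    se = np.sqrt(np.diag(cov))
    ci = pd.DataFrame({"lower": beta - 1.959963984540054 * se, "upper": beta + 1.959963984540054 * se}, index=columns)
    return ModelFit(
        kind="cox",
        params=pd.Series(beta, index=columns),
        cov=pd.DataFrame(cov, index=columns, columns=columns),
        conf_int=ci,
        n=n_total,
        converged=converged,
        iterations=it,
        loglik=ll,
    )


def significance_by_ci(fit: ModelFit, null_value: float | None = None) -> pd.Series:
    """Flag coefficients whose 95% CI excludes the null value.

    For hazard ratios the null is 1 (applied on the HR scale); for OLS
    slopes the natural null is 0.
    """
    if null_value is None:
        null_value = 1.0 if fit.kind == "cox" else 0.0
    if fit.kind == "cox":
        lo = np.exp(fit.conf_int["lower"])
        hi = np.exp(fit.conf_int["upper"])
    else:
        lo, hi = fit.conf_int["lower"], fit.conf_int["upper"]
    return (null_value < lo) | (null_value > hi)
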