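"""Hypothesis tests on pooled aggregates.

Chi-square (Yates-corrected for 2x2), an exact Fisher test for general
r x c tables (probability-mass two-sided criterion, full enumeration
with a seeded Monte-Carlo fallback), the pooled-variance Student t-test
computed from sufficient statistics only, its locally differentially
private counterpart, the chi-square-vs-Fisher selection rule (chi-square
needs every observed cell >= 5) and the p < alpha confounder screen.

All tests are two-sided.  Everything here consumes aggregates — counts
and (n, mean, sd) summaries — so it can run coordinator-side on pooled
federation output, noised or not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .dp import MechanismSpec, laplace_release, substream

__all__ = [
    "TestResult",
    "GroupSummary",
    "chisq_test",
    "fisher_exact",
    "select_test",
    "test_association",
    "student_t",
    "dp_t_test",
    "screen_confounders",
    "FisherEnumerationError",
]


class FisherEnumerationError(RuntimeError):
    """Exact enumeration too large; use monte_carlo=True (seeded)."""


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: float | None
    p_value: float
    test: str
    correction: bool = False
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value out of [0,1]: {self.p_value}")


@dataclass(frozen=True)
class GroupSummary:
    """Sufficient statistics for one comparison group (possibly DP-noised)."""

    n: float
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("group summary needs n >= 2")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")


def _as_counts(table: pd.DataFrame | np.ndarray | Sequence[Sequence[int]]) -> np.ndarray:
    arr = np.asarray(table.values if isinstance(table, pd.DataFrame) else table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if (arr < 0).any():
        raise ValueError("contingency table counts must be nonnegative")
    return arr


def chisq_test(table, yates: bool = True) -> TestResult:
    """Pearson chi-square; Yates continuity correction on 2x2 tables.

    The correction matters in practice: on small 2x2 tables the corrected
    and uncorrected p can differ at the second decimal.
    """
    arr = _as_counts(table)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("chi-square undefined with a zero row or column margin")
    correction = yates and arr.shape == (2, 2)
    chi2, p, df, _ = stats.chi2_contingency(arr, correction=correction)
    return TestResult(float(chi2), float(df), float(p), "chi-square", correction)


def _log_table_prob(arr: np.ndarray) -> float:
    """log hypergeometric probability of an r x c table given its margins."""
    n = arr.sum()
    return float(
        gammaln(arr.sum(axis=1) + 1).sum()
        + gammaln(arr.sum(axis=0) + 1).sum()
        - gammaln(n + 1)
        - gammaln(arr + 1).sum()
    )


def _enumerate_tables(row_sums, col_rem, row_idx, current, out, cap):
    """Recursive enumeration of all integer tables with the given margins."""
    r = len(row_sums)
    if row_idx == r - 1:
        # last row is forced by the column remainders
        if (col_rem >= 0).all():
            out.append(current + [col_rem.copy()])
            if len(out) > cap:
                raise FisherEnumerationError(
                    "too many tables for exact enumeration; rerun with monte_carlo=True"
                )
        return
    target = row_sums[row_idx]
    c = len(col_rem)

    def fill(j, remaining, row):
        if j == c - 1:
            if 0 <= remaining <= col_rem[j]:
                nxt = row + [remaining]
                _enumerate_tables(
                    row_sums, col_rem - np.array(nxt), row_idx + 1, current + [np.array(nxt)], out, cap
                )
            return
        for v in range(min(remaining, col_rem[j]) + 1):
            fill(j + 1, remaining - v, row + [v])

    fill(0, target, [])


def fisher_exact(
    table,
    monte_carlo: bool = False,
    n_samples: int = 100_000,
    seed: int = 0,
    max_tables: int = 2_000_000,
) -> TestResult:
    """Two-sided exact test for an r x c table, probability-mass criterion.

    The p-value sums the hypergeometric probabilities of every table with
    the observed margins whose probability is at most that of the
    observed table (within 1e-7 slack against ties lost to rounding).
    Enumeration is exact up to ``max_tables``; beyond that a seeded
    Monte-Carlo version samples margin-preserving tables by permutation.
    """
    arr = _as_counts(table).astype(int)
    row_sums = arr.sum(axis=1)
    col_sums = arr.sum(axis=0)
    log_obs = _log_table_prob(arr)
    slack = 1e-7

    if monte_carlo:
        rng = substream(seed, 7)
        rows = np.repeat(np.arange(arr.shape[0]), row_sums)
        cols = np.repeat(np.arange(arr.shape[1]), col_sums)
        hits = 0
        for _ in range(n_samples):
            perm = rng.permutation(cols)
            t = np.zeros_like(arr)
            np.add.at(t, (rows, perm), 1)
            if _log_table_prob(t) <= log_obs + slack:
                hits += 1
        return TestResult(math.nan, None, hits / n_samples, "fisher (monte-carlo)")

    out: list[list[np.ndarray]] = []
    _enumerate_tables(row_sums, col_sums.copy(), 0, [], out, max_tables)
    p = 0.0
    for rows_list in out:
        t = np.vstack(rows_list)
        lp = _log_table_prob(t)
        if lp <= log_obs + slack:
            p += math.exp(lp)
    return TestResult(math.nan, None, min(p, 1.0), "fisher")


def select_test(table) -> Literal["chi-square", "fisher"]:
    """Chi-square when every observed cell has at least 5, Fisher otherwise."""
    arr = _as_counts(table)
    return "chi-square" if (arr >= 5).all() else "fisher"


def test_association(table, yates: bool = True, seed: int = 0) -> TestResult:
    """Apply the selection rule, then the selected test."""
    if select_test(table) == "chi-square":
        return chisq_test(table, yates=yates)
    try:
        return fisher_exact(table)
    except FisherEnumerationError:
        return fisher_exact(table, monte_carlo=True, seed=seed)


def student_t(a: GroupSummary, b: GroupSummary) -> TestResult:
    """Two-sided pooled-variance t-test from sufficient statistics."""
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 <= 0:
        if a.mean == b.mean:
            return TestResult(0.0, float(df), 1.0, "t")
        return TestResult(math.inf, float(df), 0.0, "t", degenerate=True)
    t = (a.mean - b.mean) / math.sqrt(sp2 * (1 / a.n + 1 / b.n))
    p = 2.0 * stats.t.sf(abs(t), df)
    return TestResult(float(t), float(df), float(p), "t")


def dp_t_test(
    nodes,
    variable: str,
    group_var: str,
    epsilon_total: float,
    root_seed: int = 0,
    noise_free: bool = False,
    levels: Sequence | None = None,
) -> TestResult:
    """Locally differentially private two-group t-test.

    Each node releases, for each of the two groups, a noisy count, a
    noisy clamped sum, and a noisy clamped sum of squares, each at
    epsilon_total/6 (so each node spends epsilon_total in all).  The
    coordinator pools these into per-group (n, mean, sd) summaries —
    noisy counts rounded to integers and floored at 2 before the degrees
    of freedom — and computes the pooled t statistic.

    Because the Laplace noise scales are public, the coordinator knows
    the exact noise variance carried by each group's released mean and
    adds it to the sampling variance in the denominator; ignoring it
    would make the test anti-conservative (the numerator is noisier than
    the plain standard error admits).  In noise-free mode the correction
    vanishes and the result equals the exact test on the pooled raw
    data.
    """
    if epsilon_total <= 0:
        raise ValueError("epsilon_total must be > 0")
    if levels is None:
        levels = sorted(
            set().union(*[set(nd.table.df[group_var].dropna().unique()) for nd in nodes])
        )
    if len(levels) != 2:
        raise ValueError(f"dp_t_test needs exactly two groups, got {levels}")
    sub = epsilon_total / 6.0
    agg = {lvl: [0.0, 0.0, 0.0] for lvl in levels}  # n, sum, sumsq
    sum_noise_var = {lvl: 0.0 for lvl in levels}  # known Laplace variance on the sum
    for ni, nd in enumerate(nodes):
        b = nd._bounds(variable)
        sens_sum = max(abs(b.lower), abs(b.upper))
        sens_ssq = max(b.lower**2, b.upper**2)
        rng = substream(root_seed, 4, ni)
        for gi, lvl in enumerate(levels):
            vals = nd.table.df.loc[nd.table.df[group_var] == lvl, variable].dropna().to_numpy(float)
            if not noise_free:
                vals = b.clip(vals)
            stats3 = (float(len(vals)), float(vals.sum()), float((vals**2).sum()))
            sens3 = (1.0, sens_sum, sens_ssq)
            for k, (v, s) in enumerate(zip(stats3, sens3)):
                agg[lvl][k] += laplace_release(
                    v, MechanismSpec(sub, s), rng, noise_free=noise_free
                )
            if not noise_free:
                sum_noise_var[lvl] += 2.0 * (sens_sum / sub) ** 2
        nd.ledger.charge(nd.id, f"dp_t_test:{variable}", epsilon_total)

    summaries = []
    mean_noise_var = []
    degenerate = False
    for lvl in levels:
        n, s, ssq = agg[lvl]
        n = max(round(n), 2)
        if n == 2 and not noise_free and agg[lvl][0] < 1.5:
            degenerate = True
        var = max(ssq / n - (s / n) ** 2, 0.0) * n / (n - 1)
        summaries.append(GroupSummary(float(n), s / n, math.sqrt(var)))
        mean_noise_var.append(sum_noise_var[lvl] / n**2)
    a, b = summaries
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    denom2 = sp2 * (1 / a.n + 1 / b.n) + mean_noise_var[0] + mean_noise_var[1]
    if denom2 <= 0:
        res = student_t(a, b)
    else:
        t = (a.mean - b.mean) / math.sqrt(denom2)
        res = TestResult(float(t), float(df), float(2.0 * stats.t.sf(abs(t), df)), "t (dp)")
    if degenerate:
        return TestResult(res.statistic, res.df, res.p_value, res.test, degenerate=True)
    return res


def screen_confounders(p_values: Mapping[str, float], threshold: float = 0.20) -> set[str]:
    """Variables whose bivariate p falls strictly below the threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return {name for name, p in p_values.items() if p < threshold}
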