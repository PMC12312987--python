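"""Coordinator / node simulation for federated aggregate queries.

Each :class:`Node` wraps one center's :class:`~fedstats.cohort.CohortTable`.
A node never emits anything but an :class:`AggregateMessage` holding
sufficient statistics (scalars, bin-count vectors, quantile grids) — no
record-level data crosses the node boundary by construction.  Before
releasing anything a node runs its disclosure checks (minimum cell count,
minimum subset size); a failing check yields a masked message with no
payload.

Privacy modes per query:

* ``dp="none"``   — exact sufficient statistics.
* ``dp="local"``  — each node perturbs its own payload with the Laplace
  mechanism before sending; every node's ledger is charged.
* ``dp="central"``— nodes send exact payloads, the coordinator adds a
  single noise draw after pooling (trusted-coordinator model); one ledger
  charge.  For a k-node sum this needs k times less noise variance than
  local DP at the same budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import CohortTable
from .dp import (
    BudgetLedger,
    ClampBounds,
    MechanismSpec,
    dp_count,
    dp_extremum,
    dp_histogram,
    dp_quantile,
    laplace_release,
    substream,
)

__all__ = [
    "DisclosurePolicy",
    "QuerySpec",
    "AggregateMessage",
    "PooledResult",
    "MaskedResultError",
    "Node",
    "Federation",
    "check_disclosure",
    "run_query",
    "pool_mean",
    "pool_sd",
    "pool_table",
    "pool_quantiles",
]

DEFAULT_PERCENTILES = (5, 25, 50, 75, 95)

_SCALAR_STATS = {"count", "sum", "mean", "sd", "min", "max", "quantile"}
_VECTOR_STATS = {"histogram", "percentiles"}


class MaskedResultError(RuntimeError):
    """Every node's answer was withheld by disclosure checks."""


@dataclass(frozen=True)
class DisclosurePolicy:
    """Minimum-cell-count style release thresholds (inclusive pass)."""

    min_cell_count: int = 3
    min_subset_n: int = 3
    strict: bool = False  # if True, a masked node fails the whole query

    def __post_init__(self) -> None:
        if self.min_cell_count < 1 or self.min_subset_n < 1:
            raise ValueError("disclosure thresholds must be >= 1")


@dataclass(frozen=True)
class QuerySpec:
    """One federated statistical query."""

    variable: str
    statistic: Literal[
        "count", "sum", "mean", "sd", "min", "max", "quantile", "percentiles", "histogram"
    ]
    filter: Mapping[str, object] | None = None
    dp: Literal["none", "local", "central"] = "none"
    epsilon: float | None = None
    q: float | None = None
    group_by: str | None = None

    def __post_init__(self) -> None:
        if (self.dp != "none") != (self.epsilon is not None):
            raise ValueError("epsilon must be given exactly when dp != 'none'")
        if self.statistic == "quantile" and self.q is None:
            raise ValueError("quantile queries need q")


@dataclass
class AggregateMessage:
    """The only thing a node ever emits."""

    node: str
    n: int | float
    payload: dict | None
    epsilon_charged: float = 0.0
    status: Literal["ok", "masked"] = "ok"

    def __post_init__(self) -> None:
        if self.status == "masked" and self.payload is not None:
            raise ValueError("masked messages must carry no payload")


@dataclass
class PooledResult:
    value: object
    n_total: float
    messages: list[AggregateMessage]
    warnings: list[str] = field(default_factory=list)
    epsilon: float | None = None
    dp: str = "none"


def check_disclosure(
    n: int,
    policy: DisclosurePolicy,
    bin_counts: Sequence[int] | None = None,
) -> Literal["ok", "masked"]:
    """Apply minimum-subset / minimum-cell rules to one node's raw result.

    Thresholds pass inclusively: a cell of exactly ``min_cell_count``
    survives.  Empty cells pass too — a count of zero singles out no
    individual; it is the small nonempty cells (1 to threshold-1) that
    disclose.  The check always runs on the true counts, before any DP
    noise, so masking itself never depends on the noise draw.
    """
    if n < policy.min_subset_n:
        return "masked"
    if bin_counts is not None and any(
        0 < int(c) < policy.min_cell_count for c in bin_counts
    ):
        return "masked"
    return "ok"


class Node:
    """One center: local data, local ledger, local disclosure policy."""

    def __init__(
        self,
        node_id: str,
        table: CohortTable,
        policy: DisclosurePolicy | None = None,
        ledger: BudgetLedger | None = None,
    ) -> None:
        self.id = node_id
        self.table = table
        self.policy = policy or DisclosurePolicy()
        self.ledger = ledger or BudgetLedger()

    # -- local helpers -------------------------------------------------
    def _filtered(self, query: QuerySpec) -> pd.DataFrame:
        df = self.table.df
        for col, val in (query.filter or {}).items():
            df = df[df[col] == val]
        return df

    def _bounds(self, variable: str) -> ClampBounds:
        schema = self.table.schemas.get(variable)
        if schema is None or schema.clamp is None:
            raise KeyError(f"no clamp bounds declared for variable {variable!r}")
        return schema.clamp

    def _categories(self, variable: str) -> list[str]:
        schema = self.table.schemas.get(variable)
        if schema is None or schema.categories is None:
            raise KeyError(f"{variable!r} is not a categorical schema variable")
        return list(schema.categories)

    def answer(
        self,
        query: QuerySpec,
        rng: np.random.Generator | None = None,
        noise_free: bool = False,
    ) -> AggregateMessage:
        """Answer one query: disclosure check, then exact or noised payload."""
        df = self._filtered(query)
        stat = query.statistic
        local_dp = query.dp == "local" and not noise_free
        eps = query.epsilon or 0.0

        if stat == "histogram":
            cats = self._categories(query.variable)
            if query.group_by is not None:
                # joint cells over (category, group level) are still disjoint,
                # so the whole cross-table is one parallel-composition release
                glevels = (
                    ["before", "after"]
                    if query.group_by == "period"
                    else self._categories(query.group_by)
                )
                pairs = [(c, g) for g in glevels for c in cats]
                values = list(
                    df[[query.variable, query.group_by]]
                    .dropna()
                    .itertuples(index=False, name=None)
                )
            else:
                glevels = None
                pairs = cats
                values = list(df[query.variable].dropna())
            true_bins = np.array([sum(1 for v in values if v == c) for c in pairs])
            status = check_disclosure(len(values), self.policy, true_bins)
            if status == "masked":
                return AggregateMessage(self.id, len(values), None, 0.0, "masked")
            if query.dp == "local":
                bins = dp_histogram(
                    values, pairs, eps, rng, ledger=self.ledger, node=self.id,
                    noise_free=noise_free,
                )
            else:
                bins = true_bins
            return AggregateMessage(
                self.id,
                len(values),
                {
                    "categories": cats,
                    "groups": glevels,
                    "bins": [int(b) for b in bins],
                },
                eps if query.dp == "local" else 0.0,
            )

        values = df[query.variable].dropna().to_numpy(dtype=float) if stat != "count" else None
        n = len(df) if stat == "count" else len(values)
        status = check_disclosure(n, self.policy)
        if status == "masked":
            return AggregateMessage(self.id, n, None, 0.0, "masked")

        charge = 0.0
        if stat == "count":
            out_n = dp_count(range(n), eps, rng, noise_free=noise_free) if local_dp else float(n)
            payload = {"n": out_n}
        elif stat == "sum":
            # clamping exists only to bound sensitivity; exact queries ship
            # the raw statistic
            if local_dp:
                b = self._bounds(query.variable)
                sens = max(abs(b.lower), abs(b.upper))
                s = laplace_release(float(b.clip(values).sum()), MechanismSpec(eps, sens), rng)
            else:
                s = float(values.sum())
            payload = {"sum": s}
        elif stat in ("mean", "sd"):
            k = 2 if stat == "mean" else 3
            sub = eps / k if local_dp else 0.0
            work = values
            if local_dp:
                b = self._bounds(query.variable)
                work = b.clip(values)
            nn = float(n)
            ssum = float(work.sum())
            ssq = float((work**2).sum())
            if local_dp:
                nn = laplace_release(nn, MechanismSpec(sub, 1.0), rng)
                ssum = laplace_release(
                    ssum, MechanismSpec(sub, max(abs(b.lower), abs(b.upper))), rng
                )
                if stat == "sd":
                    ssq = laplace_release(
                        ssq, MechanismSpec(sub, max(b.lower**2, b.upper**2)), rng
                    )
            payload = {"n_stat": nn, "sum": ssum}
            if stat == "sd":
                payload["sumsq"] = ssq
        elif stat in ("min", "max"):
            if local_dp:
                v = dp_extremum(values, self._bounds(query.variable), eps, stat, rng)
            else:
                v = float(values.min() if stat == "min" else values.max())
            payload = {stat: v}
        elif stat == "quantile":
            if local_dp:
                v = dp_quantile(values, self._bounds(query.variable), query.q, eps, rng)
            else:
                v = float(np.quantile(values, query.q))
            payload = {"q": query.q, "value": v}
        elif stat == "percentiles":
            grid = DEFAULT_PERCENTILES
            if local_dp:
                sub = eps / len(grid)
                b = self._bounds(query.variable)
                vals = [dp_quantile(values, b, p / 100, sub, rng) for p in grid]
            else:
                vals = [float(np.quantile(values, p / 100)) for p in grid]
            payload = {"grid": list(grid), "values": vals}
        else:
            raise ValueError(f"unknown statistic {stat!r}")

        if query.dp == "local":
            charge = eps
            self.ledger.charge(self.id, f"{stat}:{query.variable}", eps)
        return AggregateMessage(self.id, n, payload, charge)


# ---------------------------------------------------------------------------
# pooling


def pool_mean(messages: Sequence[tuple[float, float]]) -> float:
    """n-weighted mean of per-node (n, mean) pairs."""
    total_n = sum(n for n, _ in messages)
    if total_n <= 0:
        raise ValueError("zero total n")
    return sum(n * m for n, m in messages) / total_n


def pool_sd(messages: Sequence[tuple[float, float, float]]) -> float:
    """Pooled SD from per-node (n, mean, sd) triples.

    pooled variance = [sum (n_i - 1) s_i^2 + sum n_i (m_i - m)^2] / (N - 1),
    which equals the variance of the concatenated raw data exactly.
    """
    total_n = sum(n for n, _, _ in messages)
    if total_n < 2:
        raise ValueError("pooled sd needs total n >= 2")
    m = pool_mean([(n, mu) for n, mu, _ in messages])
    within = sum((n - 1) * s**2 for n, _, s in messages)
    between = sum(n * (mu - m) ** 2 for n, mu, _ in messages)
    return float(np.sqrt((within + between) / (total_n - 1)))


def pool_table(tables: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Element-wise sum of per-node contingency tables (same category sets)."""
    if not tables:
        raise ValueError("no tables to pool")
    base = tables[0]
    out = base.copy()
    for t in tables[1:]:
        if list(t.index) != list(base.index) or list(t.columns) != list(base.columns):
            raise ValueError("contingency tables have mismatched categories")
        out = out + t
    return out

def pool_quantiles(messages: Sequence[tuple[float, Sequence[float]]]) -> np.ndarray:
    """n-weighted average of per-node quantile vectors.

    An approximation to the quantiles of the pooled sample (exact pooling
    would require exchanging order statistics across nodes, which leaks);
    it is consistent when node distributions coincide.
    """
    grid_len = {len(qs) for _, qs in messages}
    if len(grid_len) != 1:
        raise ValueError("quantile grids differ across nodes")
    total_n = sum(n for n, _ in messages)
    if total_n <= 0:
        raise ValueError("zero total n")
    acc = np.zeros(grid_len.pop())
    for n, qs in messages:
        acc += n * np.asarray(qs, dtype=float)
    return acc / total_n


class Federation:
    """A set of nodes plus the coordinator-side pooling logic."""

    def __init__(
        self,
        nodes: Sequence[Node],
        policy: DisclosurePolicy | None = None,
        root_seed: int = 0,
        noise_free: bool = False,
    ) -> None:
        if not nodes:
            raise ValueError("a federation needs at least one node")
        self.nodes = list(nodes)
        self.policy = policy or DisclosurePolicy()
        for nd in self.nodes:
            nd.policy = self.policy
        self.root_seed = root_seed
        self.noise_free = noise_free
        self._query_counter = 0
        self.central_ledger = BudgetLedger()
        self.message_log: list[AggregateMessage] = []

    @property
    def ledgers(self) -> dict[str, BudgetLedger]:
        return {nd.id: nd.ledger for nd in self.nodes}

    def run_query(self, query: QuerySpec) -> PooledResult:
        """Fan a query out to every node and pool the ok answers."""
        self._query_counter += 1
        qi = self._query_counter
        msgs = []
        for ni, node in enumerate(self.nodes):
            rng = substream(self.root_seed, 2, qi, ni)
            msgs.append(node.answer(query, rng, noise_free=self.noise_free))
        self.message_log.extend(msgs)
        ok = [m for m in msgs if m.status == "ok"]
        warnings = [f"node {m.node} masked by disclosure policy" for m in msgs if m.status == "masked"]
        if warnings and self.policy.strict:
            raise MaskedResultError("; ".join(warnings))
        if not ok:
            raise MaskedResultError(f"all nodes masked for {query.statistic} on {query.variable}")

        value = self._pool(query, ok)
        if query.dp == "central" and not self.noise_free:
            value = self._central_noise(query, ok, value, substream(self.root_seed, 3, qi))
        return PooledResult(
            value=value,
            n_total=float(sum(m.n for m in ok)),
            messages=msgs,
            warnings=warnings,
            epsilon=query.epsilon,
            dp=query.dp,
        )

    def _pool(self, query: QuerySpec, ok: list[AggregateMessage]) -> object:
        stat = query.statistic
        if stat == "count":
            return float(sum(m.payload["n"] for m in ok))
        if stat == "sum":
            return float(sum(m.payload["sum"] for m in ok))
        if stat == "mean":
            ns = [max(m.payload["n_stat"], 1.0) for m in ok]
            return float(sum(m.payload["sum"] for m in ok) / sum(ns))
        if stat == "sd":
            n = sum(max(m.payload["n_stat"], 2.0) for m in ok)
            s = sum(m.payload["sum"] for m in ok)
            ssq = sum(m.payload["sumsq"] for m in ok)
            return float(np.sqrt(max(ssq / n - (s / n) ** 2, 0.0) * n / max(n - 1, 1.0)))
        if stat == "min":
            return float(min(m.payload["min"] for m in ok))
        if stat == "max":
            return float(max(m.payload["max"] for m in ok))
        if stat == "quantile":
            return float(pool_quantiles([(m.n, [m.payload["value"]]) for m in ok])[0])
        if stat == "percentiles":
            grid = ok[0].payload["grid"]
            pooled = pool_quantiles([(m.n, m.payload["values"]) for m in ok])
            return {int(g): float(v) for g, v in zip(grid, pooled)}
        if stat == "histogram":
            cats = ok[0].payload["categories"]
            groups = ok[0].payload["groups"]
            for m in ok:
                if m.payload["categories"] != cats or m.payload["groups"] != groups:
                    raise ValueError("category mismatch across nodes")
            total = np.sum([m.payload["bins"] for m in ok], axis=0)
            if groups is None:
                return pd.Series(total, index=cats)
            return pd.DataFrame(
                total.reshape(len(groups), len(cats)).T, index=cats, columns=groups
            )
        raise ValueError(f"unknown statistic {stat!r}")

    def _central_noise(
        self, query: QuerySpec, ok: list[AggregateMessage], value: object, rng: np.random.Generator
    ) -> object:
        """One coordinator-side noise draw on the pooled value (trusted model)."""
        eps = query.epsilon
        stat = query.statistic
        schema = self.nodes[0].table.schemas.get(query.variable)
        bounds = schema.clamp if schema is not None else None
        self.central_ledger.charge("coordinator", f"{stat}:{query.variable}", eps)
        if stat == "count":
            return laplace_release(value, MechanismSpec(eps, 1.0), rng)
        if stat == "sum":
            sens = max(abs(bounds.lower), abs(bounds.upper))
            return laplace_release(value, MechanismSpec(eps, sens), rng)
        if stat == "mean":
            n = sum(m.n for m in ok)
            sens = bounds.width / max(n, 1)
            return laplace_release(value, MechanismSpec(eps, sens), rng)
        if stat == "histogram":
            noisy = value + rng.laplace(0.0, 1.0 / eps, size=len(value))
            return pd.Series(
                np.maximum(np.rint(noisy.to_numpy(dtype=float)), 0).astype(int), index=value.index
            )
        raise ValueError(f"central DP not defined for statistic {stat!r}")


def run_query(
    nodes: Sequence[Node],
    query: QuerySpec,
    policy: DisclosurePolicy | None = None,
    root_seed: int = 0,
    noise_free: bool = False,
) -> PooledResult:
    """Convenience wrapper: one-shot federation around a node list."""
    return Federation(nodes, policy, root_seed, noise_free).run_query(query)
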