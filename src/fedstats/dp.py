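"""Pure epsilon-differential-privacy primitives.

Implements the Laplace mechanism with per-statistic sensitivities, the
exponential mechanism for quantiles, histogram release under parallel
composition, and an additive privacy-budget ledger.

A note on the privacy parameter: epsilon is the standard pure-DP budget.
The Laplace mechanism adds noise with scale ``b = sensitivity / epsilon``
(density ``exp(-|x|/b) / 2b``, variance ``2 b**2``); smaller epsilon means
more noise and stronger privacy.  Post-processing (clamping a release back
into its domain, rounding counts to nonnegative integers) never consumes
budget.

Every operation takes a ``noise_free`` switch (test-only): it degenerates
the mechanism to its exact non-private counterpart — no noise and no
clamping — which is the epsilon -> infinity limit the degeneration tests
rely on.  Budget accounting is unchanged by the switch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "ClampBounds",
    "MechanismSpec",
    "BudgetLedger",
    "substream",
    "laplace_release",
    "dp_count",
    "dp_sum",
    "dp_mean",
    "dp_variance",
    "dp_sd",
    "dp_extremum",
    "dp_quantile",
    "dp_histogram",
]


@dataclass(frozen=True)
class ClampBounds:
    """Public value bounds [lower, upper] in the variable's own units.

    Every sensitivity used here is derived from these bounds, so they must
    be chosen from public knowledge (units, physiology, protocol), never
    from the data being protected.
    """

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"clamp bounds need lower < upper, got [{self.lower}, {self.upper}]")

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def clip(self, values: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(values, dtype=float), self.lower, self.upper)


@dataclass(frozen=True)
class MechanismSpec:
    """One DP query's budget, sensitivity and mechanism kind."""

    epsilon: float
    sensitivity: float
    mechanism: Literal["laplace", "exponential"] = "laplace"
    clamp: ClampBounds | None = None

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")
        if self.sensitivity < 0:
            raise ValueError(f"sensitivity must be >= 0, got {self.sensitivity}")

    @property
    def scale(self) -> float:
        """Laplace scale b = sensitivity / epsilon."""
        return self.sensitivity / self.epsilon


class BudgetLedger:
    """Cumulative privacy spend per (node, dataset), additive composition.

    Pure-DP sequential composition: the budget of a sequence of releases is
    the sum of the budgets of each release.  The ledger only ever grows.
    """

    def __init__(self) -> None:
        self._entries: list[dict] = []
        self._totals: dict[tuple[str, str], float] = {}

    def charge(self, node: str, statistic: str, epsilon: float, dataset: str = "default") -> None:
        if epsilon < 0:
            raise ValueError("cannot charge a negative budget")
        key = (node, dataset)
        self._totals[key] = self._totals.get(key, 0.0) + epsilon
        self._entries.append(
            {
                "node": node,
                "dataset": dataset,
                "statistic": statistic,
                "epsilon": epsilon,
                "cumulative": self._totals[key],
            }
        )

    def total(self, node: str, dataset: str = "default") -> float:
        return self._totals.get((node, dataset), 0.0)

    def grand_total(self) -> float:
        return sum(self._totals.values())

    @property
    def entries(self) -> list[dict]:
        return list(self._entries)

    def to_json_lines(self) -> str:
        return "\n".join(json.dumps(e) for e in self._entries)

    def snapshot(self) -> dict[str, float]:
        """Per-node cumulative spend (summed over datasets)."""
        out: dict[str, float] = {}
        for (node, _ds), tot in self._totals.items():
            out[node] = out.get(node, 0.0) + tot
        return out


def substream(root_seed: int, *path: int) -> np.random.Generator:
    """Derive an independent generator for a (node, query, ...) coordinate.

    One root seed fans out deterministically: the same (seed, path) always
    yields the same stream, and distinct paths yield independent streams.
    """
    ss = np.random.SeedSequence(int(root_seed) % (2**31), spawn_key=tuple(int(p) for p in path))
    return np.random.default_rng(ss)


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def laplace_release(
    true_value: float,
    spec: MechanismSpec,
    rng: np.random.Generator | int | None = None,
    *,
    noise_free: bool = False,
) -> float:
    """Release ``true_value`` through the Laplace mechanism.

    With sensitivity 0 (or in noise-free mode) the value passes through
    exactly.  Deterministic for a fixed generator state.
    """
    if spec.mechanism != "laplace":
        raise ValueError("laplace_release needs a laplace MechanismSpec")
    if noise_free or spec.sensitivity == 0:
        return float(true_value)
    b = spec.scale
    if not math.isfinite(b):
        raise ValueError("non-finite Laplace scale (check sensitivity and epsilon)")
    return float(true_value + _as_rng(rng).laplace(0.0, b))


def _clean(values: Iterable[float]) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    return arr[~np.isnan(arr)]


def dp_count(
    values: Iterable,
    epsilon: float,
    rng: np.random.Generator | int | None = None,
    *,
    ledger: BudgetLedger | None = None,
    node: str = "local",
    noise_free: bool = False,
) -> float:
    """Noisy cardinality: Laplace release of len(values) with sensitivity 1."""
    n = len(values) if hasattr(values, "__len__") else sum(1 for _ in values)
    spec = MechanismSpec(epsilon=epsilon, sensitivity=1.0)
    out = laplace_release(float(n), spec, rng, noise_free=noise_free)
    if ledger is not None:
        ledger.charge(node, "count", epsilon)
    return out


def dp_sum(
    values: Iterable[float],
    bounds: ClampBounds,
    epsilon: float,
    rng: np.random.Generator | int | None = None,
    *,
    ledger: BudgetLedger | None = None,
    node: str = "local",
    noise_free: bool = False,
) -> float:
    """Noisy clamped sum; sensitivity max(|L|, |U|)."""
    arr = _clean(values)
    if not noise_free:
        arr = bounds.clip(arr)
    sens = max(abs(bounds.lower), abs(bounds.upper))
    spec = MechanismSpec(epsilon=epsilon, sensitivity=sens, clamp=bounds)
    out = laplace_release(float(arr.sum()), spec, rng, noise_free=noise_free)
    if ledger is not None:
        ledger.charge(node, "sum", epsilon)
    return out


def dp_mean(
    values: Iterable[float],
    bounds: ClampBounds,
    epsilon: float,
    rng: np.random.Generator | int | None = None,
    *,
    ledger: BudgetLedger | None = None,
    node: str = "local",
    noise_free: bool = False,
) -> float:
    """Noisy mean as noisy_sum / noisy_count, budget split epsilon/2 each.

    The count release is floored at 1 (post-processing) so the ratio is
    always defined.  Missing values are dropped before clamping.
    """
    arr = _clean(values)
    if not noise_free:
        arr = bounds.clip(arr)
    if arr.size == 0:
        raise ValueError("dp_mean needs at least one non-missing value")
    r = _as_rng(rng)
    half = epsilon / 2.0
    noisy_sum = dp_sum(arr, bounds, half, r, noise_free=noise_free)
    noisy_n = dp_count(arr, half, r, noise_free=noise_free)
    if ledger is not None:
        ledger.charge(node, "mean", epsilon)
    return noisy_sum / max(noisy_n, 1.0)


def dp_variance(
    values: Iterable[float],
    bounds: ClampBounds,
    epsilon: float,
    rng: np.random.Generator | int | None = None,
    *,
    ledger: BudgetLedger | None = None,
    node: str = "local",
    noise_free: bool = False,
) -> float:
    """Noisy population variance from three noisy aggregates at epsilon/3.

    Uses count (sensitivity 1), sum (max(|L|,|U|)) and sum of squares
    (max(L^2, U^2)); the result is floored at 0 before release.
    """
    arr = _clean(values)
    if not noise_free:
        arr = bounds.clip(arr)
    if arr.size < 2:
        raise ValueError("dp_variance needs at least two non-missing values")
    r = _as_rng(rng)
    third = epsilon / 3.0
    noisy_n = max(dp_count(arr, third, r, noise_free=noise_free), 2.0)
    noisy_sum = dp_sum(arr, bounds, third, r, noise_free=noise_free)
    sq_bounds = ClampBounds(0.0, max(bounds.lower**2, bounds.upper**2))
    noisy_ssq = laplace_release(
        float((arr**2).sum()),
        MechanismSpec(epsilon=third, sensitivity=sq_bounds.upper),
        r,
        noise_free=noise_free,
    )
    if ledger is not None:
        ledger.charge(node, "variance", epsilon)
    var = noisy_ssq / noisy_n - (noisy_sum / noisy_n) ** 2
    return max(var, 0.0)


def dp_sd(
    values: Iterable[float],
    bounds: ClampBounds,
    epsilon: float,
    rng: np.random.Generator | int | None = None,
    *,
    ledger: BudgetLedger | None = None,
    node: str = "local",
    noise_free: bool = False,
) -> float:
    return math.sqrt(
        dp_variance(values, bounds, epsilon, rng, ledger=ledger, node=node, noise_free=noise_free)
    )


def dp_extremum(
    values: Iterable[float],
    bounds: ClampBounds,
    epsilon: float,
    which: Literal["min", "max"],
    rng: np.random.Generator | int | None = None,
    *,
    ledger: BudgetLedger | None = None,
    node: str = "local",
    noise_free: bool = False,
) -> float:
    """Noisy min or max: clamped true extremum + Laplace(U-L / epsilon).

    A single record can move a clamped extremum anywhere in [L, U], hence
    sensitivity U - L.  The release is re-clamped into [L, U] afterwards
    (post-processing, free).
    """
    arr = _clean(values)
    if not noise_free:
        arr = bounds.clip(arr)
    if arr.size == 0:
        raise ValueError("dp_extremum needs at least one value")
    true = float(arr.min() if which == "min" else arr.max())
    if ledger is not None:
        ledger.charge(node, which, epsilon)
    if noise_free:
        return true
    spec = MechanismSpec(epsilon=epsilon, sensitivity=bounds.width, clamp=bounds)
    out = laplace_release(true, spec, rng)
    return float(np.clip(out, bounds.lower, bounds.upper))


def dp_quantile(
    values: Iterable[float],
    bounds: ClampBounds,
    q: float,
    epsilon: float,
    rng: np.random.Generator | int | None = None,
    *,
    ledger: BudgetLedger | None = None,
    node: str = "local",
    noise_free: bool = False,
) -> float:
    """Differentially private q-quantile via the exponential mechanism.

    The domain [L, U] is cut at the sorted clamped values into intervals;
    interval i (values below = i) gets utility u_i = -|i - q n|, and is
    selected with probability proportional to ``length_i * exp(eps*u_i/2)``
    (utility sensitivity 1), then a point is drawn uniformly inside it.
    Far cheaper in noise than Laplace on the order statistic, whose
    sensitivity would be the full domain width.
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must be in (0, 1)")
    raw = _clean(values)
    if raw.size == 0:
        raise ValueError("dp_quantile needs at least one value")
    if ledger is not None:
        ledger.charge(node, f"quantile({q})", epsilon)
    if noise_free:
        return float(np.quantile(raw, q))
    arr = np.sort(bounds.clip(raw))
    n = arr.size
    edges = np.concatenate(([bounds.lower], arr, [bounds.upper]))
    lengths = np.diff(edges)  # n+1 intervals
    idx = np.arange(n + 1)
    utility = -np.abs(idx - q * n)
    logw = np.where(lengths > 0, np.log(np.maximum(lengths, 1e-300)), -np.inf) + epsilon * utility / 2.0
    logw -= logw.max()
    w = np.exp(logw)
    total = w.sum()
    if not total > 0:  # all intervals empty: every value identical at a bound
        return float(arr[0])
    r = _as_rng(rng)
    i = int(r.choice(n + 1, p=w / total))
    return float(r.uniform(edges[i], edges[i + 1])) if lengths[i] > 0 else float(edges[i])


def dp_histogram(
    values: Iterable,
    categories: Sequence,
    epsilon: float,
    rng: np.random.Generator | int | None = None,
    *,
    ledger: BudgetLedger | None = None,
    node: str = "local",
    noise_free: bool = False,
) -> np.ndarray:
    """Noisy per-category counts under parallel composition.

    Bins are disjoint, so each bin gets independent Laplace(1/epsilon)
    noise while the whole table costs epsilon once (not epsilon * bins).
    Released counts are rounded to the nearest nonnegative integer
    (post-processing, matches how occurrence tables are printed).
    """
    cats = list(categories)
    vals = list(values)
    unknown = set(vals) - set(cats)
    if unknown:
        raise ValueError(f"values outside category list: {sorted(map(str, unknown))}")
    counts = np.array([sum(1 for v in vals if v == c) for c in cats], dtype=float)
    if ledger is not None:
        ledger.charge(node, "histogram", epsilon)
    if noise_free:
        return counts.astype(int)
    r = _as_rng(rng)
    noisy = counts + r.laplace(0.0, 1.0 / epsilon, size=counts.size)
    return np.maximum(np.rint(noisy), 0).astype(int)
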