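"""Cell-type composition tables, enrichment arithmetic, and proportion tests.

Selection protocols are scored by how strongly they enrich the target cell
type.  This module holds the bookkeeping: composition tables (counts or
fractions per cell type), ratio arithmetic at the one-decimal precision used
in reports, the exact hypergeometric proportion test (the ``phyper``-style
construction: is a type over- or under-represented in a sample relative to
the pooled background?), and Benjamini–Hochberg false-discovery-rate
adjustment across types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CompositionTable",
    "TestResult",
    "enrichment_ratio",
    "combined_fraction",
    "hypergeom_test",
    "bh_adjust",
    "compare_groups",
]

_FRACTION_ATOL = 1e-6


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CompositionTable:
    """Per-cell-type composition of one group, as counts or fractions.

    Exactly one of counts/fractions semantics applies: build from
    :meth:`from_counts` when raw cell numbers are known (required for
    testing) or :meth:`from_fractions` for ratio-only arithmetic.
    """

    label: str
    counts: dict[str, int] | None = None
    fractions: dict[str, float] = field(default_factory=dict)

    @classmethod
    def from_counts(cls, counts: Mapping[str, int], label: str = "") -> "CompositionTable":
        counts = {k: int(v) for k, v in counts.items()}
        if any(v < 0 for v in counts.values()):
            raise ValueError("counts must be non-negative")
        total = sum(counts.values())
        fractions = {k: (v / total if total else 0.0) for k, v in counts.items()}
        return cls(label=label, counts=counts, fractions=fractions)

    @classmethod
    def from_fractions(cls, fractions: Mapping[str, float], label: str = "") -> "CompositionTable":
        fractions = {k: float(v) for k, v in fractions.items()}
        s = sum(fractions.values())
        if abs(s - 1.0) > _FRACTION_ATOL:
            raise ValueError(f"fractions must sum to 1 +/- {_FRACTION_ATOL}, got {s}")
        return cls(label=label, counts=None, fractions=fractions)

    @property
    def total(self) -> int:
        if self.counts is None:
            raise ValueError(f"table {self.label!r} has no counts")
        return sum(self.counts.values())

    def percent(self, cell_type: str, decimals: int = 1) -> float:
        return _round_half_up(100.0 * self.fractions[cell_type], decimals)

    def to_frame(self) -> pd.DataFrame:
        rows = {
            "cell_type": list(self.fractions),
            "fraction": list(self.fractions.values()),
        }
        if self.counts is not None:
            rows["count"] = [self.counts[k] for k in self.fractions]
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class TestResult:
    """One cell type's hypergeometric proportion test against the pooled background."""

    cell_type: str
    x: int  # type count in the sample
    n: int  # sample size
    K: int  # type count in the pooled background
    N: int  # pooled total
    p_raw: float
    p_adj: float
    direction: str  # "enriched" | "depleted" | "none"


def enrichment_ratio(a: float, b: float, decimals: int = 1) -> float:
    """Fold difference a/b of two percentages, rounded half-up.

    >>> enrichment_ratio(18.2, 8.3)
    2.2
    >>> enrichment_ratio(10.84, 2.38)
    4.6
    """
    if b == 0:
        raise ZeroDivisionError("reference fraction is zero")
    return _round_half_up(a / b, decimals)


def combined_fraction(table: CompositionTable, types: Iterable[str], decimals: int = 1) -> float:
    """Summed percentage of the named cell types, rounded half-up to one decimal."""
    types = list(types)
    missing = [t for t in types if t not in table.fractions]
    if missing:
        raise KeyError(f"unknown cell type(s) {missing} in table {table.label!r}")
    return _round_half_up(100.0 * sum(table.fractions[t] for t in types), decimals)


def hypergeom_test(x: int, n: int, K: int, N: int, alternative: str = "enriched") -> float:
    """Exact hypergeometric tail probability for a type's count in a sample.

    ``X ~ Hypergeometric(N, K, n)`` counts how many of ``n`` draws (without
    replacement) from a pool of ``N`` containing ``K`` of the type land on the
    type.  ``enriched`` returns P(X >= x), ``depleted`` P(X <= x), and
    ``two-sided`` 2 min(tails) capped at 1.
    """
    for name, v in (("x", x), ("n", n), ("K", K), ("N", N)):
        if v != int(v) or v < 0:
            raise ValueError(f"{name} must be a non-negative integer, got {v!r}")
    x, n, K, N = int(x), int(n), int(K), int(N)
    if not (x <= n <= N and x <= K <= N):
        raise ValueError(f"inconsistent counts x={x}, n={n}, K={K}, N={N}")
    dist = stats.hypergeom(N, K, n)
    upper = float(dist.sf(x - 1))
    lower = float(dist.cdf(x))
    if alternative == "enriched":
        return upper
    if alternative == "depleted":
        return lower
    if alternative == "two-sided":
        return min(1.0, 2.0 * min(upper, lower))
    raise ValueError(f"unknown alternative {alternative!r}")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (FDR), order-preserving."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def compare_groups(
    sample: CompositionTable,
    reference: CompositionTable,
    alternative: str = "two-sided",
) -> list[TestResult]:
    """Per-type hypergeometric tests of a sample against sample+reference pooled.

    For each cell type: N = pooled total, K = pooled type count, n = sample
    total, x = sample type count; p-values are BH-adjusted across types.
    """
    if sample.counts is None or reference.counts is None:
        raise ValueError("compare_groups needs count tables (use from_counts)")
    types = sorted(set(sample.counts) | set(reference.counts))
    if not types or sample.total == 0 or reference.total == 0:
        raise ValueError("empty composition table")
    n = sample.total
    N = n + reference.total
    raw, meta = [], []
    for t in types:
        x = sample.counts.get(t, 0)
        K = x + reference.counts.get(t, 0)
        raw.append(hypergeom_test(x, n, K, N, alternative=alternative))
        frac_sample = x / n
        frac_pool = K / N
        direction = (
            "enriched" if frac_sample > frac_pool
            else "depleted" if frac_sample < frac_pool
            else "none"
        )
        meta.append((t, x, K, direction))
    adj = bh_adjust(raw)
    return [
        TestResult(cell_type=t, x=x, n=n, K=K, N=N, p_raw=p, p_adj=float(pa), direction=d)
        for (t, x, K, d), p, pa in zip(meta, raw, adj)
    ]
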