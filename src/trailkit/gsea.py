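"""Unweighted gene set enrichment analysis (GSEA).

The statistic is a Kolmogorov–Smirnov-like running sum over a ranked gene
list: walking the list from top to bottom, the sum rises by (n − k) on each
of the k category members and falls by k on each of the n − k non-members.
With these increments the walk always returns to zero, so under the null
hypothesis — the k member positions uniform over the C(n, k) placements —
the maximal absolute deviation D is a pivotal statistic.  A category whose
members pile up at the top of the list produces a positive ("mountain-like")
excursion and is called enriched; one whose members sit at the bottom
produces a negative ("valley-like") excursion and is called depleted.

The p-value is the exact null probability that any placement's running sum
reaches an absolute deviation >= the observed D.  It is computed by counting
monotone lattice paths from (0, 0) to (n, k) that stay strictly inside the
band |j·n − i·k| < D (position i, members seen j), a dynamic programme over
(n+1) × (k+1) cells; the complement over C(n, k) is the p-value.  A
Monte-Carlo permutation fallback covers category/list sizes where the DP
table would be unreasonably large.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .categories import CategoryCollection, GeneCategory
from .preprocess import RankedGeneList

__all__ = [
    "RunningSumProfile",
    "GseaResult",
    "running_sum",
    "exact_p",
    "permutation_p",
    "gsea_test",
]

#: beyond this many DP cells (n * k) the exact method falls back to permutation
MAX_DP_CELLS = 50_000_000

_RESCALE_THRESHOLD = 1e280


@dataclass
class RunningSumProfile:
    """Full running-sum walk for one category on one ranked list."""

    rs: np.ndarray  # partial sums RS_1..RS_n, integers
    max_abs_deviation: int  # D
    sign_at_max: str  # "+" or "-", taken at the first position attaining D
    n: int
    k: int
    ambiguous: bool = False  # both +D and -D attained somewhere on the walk

    def __post_init__(self) -> None:
        if self.sign_at_max not in ("+", "-"):
            raise ValueError("sign_at_max must be '+' or '-'")


@dataclass
class GseaResult:
    """Per-category outcome of the running-sum test."""

    category: str
    k: int
    n: int
    max_abs_deviation: int
    direction: str  # "enriched" (top of list) or "depleted" (bottom)
    p_raw: float
    method: str  # "exact" or "permutation"
    ambiguous: bool = False
    p_adj: float | None = None
    significant: bool | None = None


def running_sum(ranked: RankedGeneList, category: GeneCategory) -> RunningSumProfile:
    """Walk the ranked list and return the running-sum profile.

    Only category members present in the list count toward k; every gene of
    the list contributes a step, so the statistic is always evaluated against
    the full list length n.
    """
    members = category.members & ranked.gene_set
    n = len(ranked)
    k = len(members)
    if k == 0:
        raise ValueError(
            f"category {category.name!r} shares no genes with the ranked list"
        )
    is_member = np.fromiter((g in members for g in ranked.genes), dtype=bool, count=n)
    incr = np.where(is_member, n - k, -k).astype(np.int64)
    rs = np.cumsum(incr)
    abs_rs = np.abs(rs)
    d = int(abs_rs.max())
    first = int(np.argmax(abs_rs))  # first index attaining D
    sign = "+" if rs[first] >= 0 else "-"
    ambiguous = d > 0 and bool((rs == d).any() and (rs == -d).any())
    return RunningSumProfile(
        rs=rs, max_abs_deviation=d, sign_at_max=sign, n=n, k=k, ambiguous=ambiguous
    )


@lru_cache(maxsize=100_000)
def exact_p(n: int, k: int, d: int) -> float:
    """Exact null probability that max |RS| >= d for k members among n ranks.

    Counts the placements whose walk stays strictly within (−d, d) by dynamic
    programming over states (position i, members used j), where the running
    sum is RS = j·(n−k) − (i−j)·k = j·n − i·k; the survival count over
    C(n, k) gives p = 1 − survivors / C(n, k).  Counts are carried in float64
    (integer-exact up to 2^53) with rescaling for large tables.
    """
    for name, val in (("n", n), ("k", k), ("d", d)):
        if not float(val).is_integer():
            raise ValueError(f"{name} must be an integer, got {val!r}")
    n, k, d = int(n), int(k), int(d)
    if not 0 < k <= n:
        raise ValueError(f"need 0 < k <= n, got k={k}, n={n}")
    if d < 0:
        raise ValueError("d must be non-negative")
    if d == 0:
        return 1.0  # every walk attains |RS| >= 0
    if d > k * (n - k):
        return 0.0  # beyond the maximal attainable deviation

    ways = np.zeros(k + 1)
    ways[0] = 1.0
    log_scale = 0.0
    for i in range(1, n + 1):
        ways[1:] = ways[1:] + ways[:-1]  # member step: (i-1, j-1) -> (i, j)
        j = np.arange(k + 1)
        # infeasible states (not enough members/non-members left) and states
        # outside the open band are pruned
        bad = (j > i) | (i - j > n - k) | (np.abs(j * n - i * k) >= d)
        ways[bad] = 0.0
        peak = ways.max()
        if peak > _RESCALE_THRESHOLD:
            ways /= peak
            log_scale += math.log(peak)
    survivors = ways[k]
    if survivors == 0.0:
        return 1.0
    log_total = math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)
    if log_scale == 0.0 and log_total < 700.0:
        # exact integer path: both counts representable without rescaling
        ratio = survivors / math.comb(n, k)
    else:
        ratio = math.exp(math.log(survivors) + log_scale - log_total)
    return float(min(1.0, max(0.0, 1.0 - ratio)))


def permutation_p(
    ranked: RankedGeneList,
    category: GeneCategory,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate of the running-sum p-value.

    Uses the add-one estimator p = (1 + #{D* >= D_obs}) / (n_perm + 1), which
    never returns 0 and is reproducible for a given seed.
    """
    profile = running_sum(ranked, category)
    return _permutation_tail(profile.n, profile.k, profile.max_abs_deviation,
                             n_perm=n_perm, seed=seed)


def _permutation_tail(n: int, k: int, d_obs: int, n_perm: int, seed: int) -> float:
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if d_obs == 0:
        return 1.0
    rng = np.random.default_rng(seed)
    exceed = 0
    batch = max(1, 5_000_000 // n)
    remaining = n_perm
    template_row = np.zeros(n, dtype=bool)
    template_row[:k] = True
    while remaining > 0:
        b = min(batch, remaining)
        remaining -= b
        mask = np.tile(template_row, (b, 1))
        mask = rng.permuted(mask, axis=1)
        incr = np.where(mask, n - k, -k).astype(np.int64)
        dstar = np.abs(np.cumsum(incr, axis=1)).max(axis=1)
        exceed += int((dstar >= d_obs).sum())
    return (1 + exceed) / (n_perm + 1)


def gsea_test(
    ranked: RankedGeneList,
    coll: CategoryCollection,
    min_size: int = 2,
    method: str = "exact",
    max_dp_cells: int = MAX_DP_CELLS,
    n_perm: int = 10_000,
    seed: int = 0,
) -> list[GseaResult]:
    """Run the running-sum test for every category against one ranked list.

    Categories with fewer than ``min_size`` genes on the list are excluded.
    ``method`` is "exact" (DP p-value, permutation fallback above
    ``max_dp_cells`` states) or "permutation".  Results are returned in
    lexicographic category order with raw p-values only; multiple-testing
    adjustment is the significance module's job.
    """
    if method not in ("exact", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    gene_set = ranked.gene_set
    n = len(ranked)
    results: list[GseaResult] = []
    for name in sorted(coll.names()):
        cat = coll[name]
        k = len(cat.members & gene_set)
        if k < min_size:
            continue
        profile = running_sum(ranked, cat)
        use_exact = method == "exact" and n * k <= max_dp_cells
        if use_exact:
            p = exact_p(n, k, profile.max_abs_deviation)
            how = "exact"
        else:
            p = _permutation_tail(n, k, profile.max_abs_deviation,
                                  n_perm=n_perm, seed=seed)
            how = "permutation"
        direction = "enriched" if profile.sign_at_max == "+" else "depleted"
        results.append(
            GseaResult(
                category=name,
                k=k,
                n=n,
                max_abs_deviation=profile.max_abs_deviation,
                direction=direction,
                p_raw=p,
                method=how,
                ambiguous=profile.ambiguous,
            )
        )
    return results
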