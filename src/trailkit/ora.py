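"""Over-representation analysis (ORA).

A pre-selected test set of genes (e.g. everything called differentially
expressed) is compared against a reference set — the gene universe, here
typically all probe sets on the chip — one category at a time.  Under the
null the overlap x between the test set (size t) and a category (size k
within the reference of size m) is hypergeometric; a category is
over-represented when x exceeds the expectation e = t·k/m and
under-represented when it falls short, and the reported p-value is the
corresponding one-sided hypergeometric tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy.stats import hypergeom

from .categories import CategoryCollection, ReferenceSet, restrict_to_reference

logger = logging.getLogger(__name__)

__all__ = ["OraResult", "hypergeom_tail", "ora_test"]


@dataclass
class OraResult:
    """Per-category outcome of the hypergeometric test."""

    category: str
    m: int  # reference-set size
    k: int  # category size within the reference
    t: int  # test-set size
    x: int  # overlap of test set with category
    expected: float  # e = t * k / m
    direction: str  # "over-represented" or "under-represented"
    p_raw: float
    p_adj: float | None = None
    significant: bool | None = None


def hypergeom_tail(m: int, k: int, t: int, x: int, direction: str) -> float:
    """One-sided hypergeometric tail probability.

    ``direction`` "upper": P(X >= x); "lower": P(X <= x), for X the overlap
    when t genes are drawn without replacement from a universe of m genes of
    which k are in the category.
    """
    if not (0 <= k <= m and 0 <= t <= m):
        raise ValueError(f"inconsistent counts: m={m}, k={k}, t={t}")
    if not (max(0, t + k - m) <= x <= min(k, t)):
        raise ValueError(f"overlap x={x} impossible for m={m}, k={k}, t={t}")
    if direction == "upper":
        return float(hypergeom.sf(x - 1, m, k, t))
    if direction == "lower":
        return float(hypergeom.cdf(x, m, k, t))
    raise ValueError(f"direction must be 'upper' or 'lower', got {direction!r}")


def ora_test(
    test: set[str] | frozenset[str],
    ref: ReferenceSet,
    coll: CategoryCollection,
    min_size: int = 2,
) -> list[OraResult]:
    """Hypergeometric over/under-representation test for every category.

    Test-set members outside the reference are dropped with a warning — the
    reference defines the universe.  Categories are restricted to the
    reference first; those with fewer than ``min_size`` genes there are
    excluded.  Direction is decided by comparing x to its expectation e
    (x = e counts as over-represented, whose upper-tail p is then >= 0.5 and
    never significant).  Raw p-values only; adjustment happens downstream.
    """
    if not test:
        raise ValueError("empty test set")
    stray = set(test) - ref.members
    if stray:
        logger.warning(
            "%d test-set genes are absent from the reference and were dropped", len(stray)
        )
    test_in_ref = set(test) & ref.members
    if not test_in_ref:
        raise ValueError("no test-set gene is present in the reference set")
    restricted, _ = restrict_to_reference(coll, ref)
    m = len(ref)
    t = len(test_in_ref)
    results: list[OraResult] = []
    for name in sorted(restricted.names()):
        cat = restricted[name]
        k = len(cat)
        if k < min_size:
            continue
        x = len(cat.members & test_in_ref)
        e = t * k / m
        if x >= e:
            direction, p = "over-represented", hypergeom_tail(m, k, t, x, "upper")
        else:
            direction, p = "under-represented", hypergeom_tail(m, k, t, x, "lower")
        results.append(
            OraResult(category=name, m=m, k=k, t=t, x=x, expected=e,
                      direction=direction, p_raw=p)
        )
    return results
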