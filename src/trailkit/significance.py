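"""Multiple-testing adjustment and significance calls.

Both enrichment tests (running-sum GSEA and hypergeometric ORA) produce one
raw p-value per category; the family of categories tested in one analysis
run is adjusted with the Benjamini–Hochberg step-up procedure, which
controls the false discovery rate, and categories are flagged significant at
an (inclusive) threshold on the adjusted p-value, 0.05 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["AdjustedResults", "bh_adjust", "call_significant", "adjust_results"]

DEFAULT_ALPHA = 0.05


@dataclass
class AdjustedResults:
    """Results with adjusted p-values and significance flags attached."""

    results: list
    alpha: float
    method: str = "fdr_bh"

    @property
    def significant(self) -> list:
        return [r for r in self.results if r.significant]


def bh_adjust(pvals: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min_{j >= i} (m * p_(j) / j), capped at 1, for the sorted raw
    p-values p_(1) <= ... <= p_(m).
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def call_significant(results: list, alpha: float = DEFAULT_ALPHA,
                     method: str = "fdr_bh") -> AdjustedResults:
    """Flag results with adjusted p <= alpha (inclusive threshold).

    Requires ``p_adj`` to be present on every result (see
    :func:`adjust_results`); ordering is preserved.
    """
    for r in results:
        if r.p_adj is None:
            raise ValueError("adjusted p-values missing; run adjust_results first")
        r.significant = r.p_adj <= alpha
    return AdjustedResults(results=results, alpha=alpha, method=method)


def adjust_results(results: list, alpha: float = DEFAULT_ALPHA,
                   method: str = "fdr_bh") -> AdjustedResults:
    """Attach BH-adjusted p-values (or copy raw p for method "none") and flag
    significance in one step.  The family is exactly the supplied result
    list — one analysis run over one category collection."""
    if method == "none":
        for r in results:
            r.p_adj = r.p_raw
    elif method == "fdr_bh":
        adjusted = bh_adjust([r.p_raw for r in results])
        for r, q in zip(results, adjusted):
            r.p_adj = q
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return call_significant(results, alpha=alpha, method=method)
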