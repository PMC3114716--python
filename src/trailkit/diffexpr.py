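"""Differential-expression selection by per-gene ANOVA with a regularized
error model.

For each gene a two-group single-factor ANOVA compares replicate signals
(on a log2 scale by default).  Small replicate numbers make raw per-gene
variances unstable, so the error term is regularized the way web-era
microarray ANOVA tools did it: the per-gene residual variance is smoothed
toward the average variance of genes of similar intensity (a sliding,
upper-trimmed window over genes ordered by mean signal), the working error
variance is the maximum of the smoothed and the actual residual variance
("max(average, actual)"), and a Bayesian shrinkage with a configurable prior
degree-of-freedom count blends the two, which also augments the F test's
denominator degrees of freedom.  Genes are called differentially expressed by
Benjamini–Hochberg FDR across the gene table; the union of calls over a set
of pairwise comparisons is the test set handed to over-representation
analysis.

The exact internals of the original web tool were never published; every
knob of this reconstruction (error model, trim fraction, prior df, window
size) is exposed in :class:`NiaSettings` so alternatives can be configured.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .preprocess import ExpressionMatrix
from .significance import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "NiaSettings",
    "DEGeneTable",
    "DeUnion",
    "smoothed_variance",
    "pairwise_anova",
    "select_de_union",
]

ERROR_MODELS = ("actual", "average", "max_avg_actual")


@dataclass(frozen=True)
class NiaSettings:
    """Tuning knobs of the regularized ANOVA.

    Defaults: max(average, actual) error model, 1% of the highest variances
    trimmed per window before averaging, 10 prior degrees of freedom for the
    Bayesian error model, FDR threshold 0.05, no permutations (parametric F
    p-values only).
    """

    error_model: str = "max_avg_actual"
    trim_proportion: float = 0.01
    prior_df: int = 10
    fdr_alpha: float = 0.05
    window_size: int = 500
    variance_floor: float = 1e-12
    log_transform: bool = True

    def __post_init__(self) -> None:
        if self.error_model not in ERROR_MODELS:
            raise ValueError(f"error_model must be one of {ERROR_MODELS}")
        if not 0 <= self.trim_proportion < 0.5:
            raise ValueError("trim_proportion must be in [0, 0.5)")
        if self.prior_df < 0:
            raise ValueError("prior_df must be >= 0")
        if self.window_size < 1:
            raise ValueError("window_size must be positive")
        if self.variance_floor <= 0:
            raise ValueError("variance_floor must be positive")


@dataclass
class DEGeneTable:
    """Per-gene ANOVA table for one pairwise comparison.

    ``table`` columns: mean_a, mean_b, residual_var, smoothed_var, error_var,
    posterior_var, F, df1, df2, p_raw, p_adj, significant.
    """

    table: pd.DataFrame
    comparison: str
    tissue: str = ""

    @property
    def significant_genes(self) -> set[str]:
        return set(self.table.index[self.table["significant"]])


@dataclass
class DeUnion:
    """Union of significant genes over several comparisons, split by tissue."""

    per_tissue: dict[str, set[str]] = field(default_factory=dict)

    @property
    def all_genes(self) -> set[str]:
        out: set[str] = set()
        for genes in self.per_tissue.values():
            out |= genes
        return out

    def counts(self) -> dict[str, int]:
        return {tissue: len(genes) for tissue, genes in sorted(self.per_tissue.items())}


def smoothed_variance(
    variances: np.ndarray,
    intensities: np.ndarray,
    settings: NiaSettings = NiaSettings(),
) -> np.ndarray:
    """Intensity-windowed, upper-trimmed average of per-gene variances.

    Genes are ordered by mean intensity; each gene's smoothed variance is the
    mean of the residual variances in its centered window of
    ``settings.window_size`` genes (clipped at the ends of the ordering)
    after discarding the largest ``trim_proportion`` fraction of variances in
    that window — outlier-noisy genes should not inflate their neighbours'
    error term.  Returned in the input gene order.
    """
    variances = np.asarray(variances, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if variances.shape != intensities.shape:
        raise ValueError("variances and intensities must be aligned")
    n = variances.size
    trim = settings.trim_proportion
    if trim > 0 and n < 1.0 / trim:
        logger.warning(
            "only %d genes (< 1/trim_proportion); variance trimming skipped", n
        )
        trim = 0.0
    order = np.argsort(intensities, kind="stable")
    v_sorted = variances[order]
    half = settings.window_size // 2
    smoothed_sorted = np.empty(n)
    for c in range(n):
        lo = max(0, c - half)
        hi = min(n, c + (settings.window_size - half))
        window = v_sorted[lo:hi]  # clipped (shorter) near the ends
        # ceil: any positive trim discards at least one value per window
        drop = int(np.ceil(trim * window.size)) if trim > 0 else 0
        if drop > 0:
            keep = np.partition(window, window.size - drop)[: window.size - drop]
        else:
            keep = window
        smoothed_sorted[c] = keep.mean()
    out = np.empty(n)
    out[order] = smoothed_sorted
    return out


def pairwise_anova(
    mat: ExpressionMatrix,
    group_a: list[str],
    group_b: list[str],
    settings: NiaSettings = NiaSettings(),
    comparison: str = "",
    tissue: str = "",
) -> DEGeneTable:
    """Two-group regularized ANOVA per gene; groups are sample-name lists.

    Group A is the test condition and group B the baseline.  Per gene:
    pooled within-group residual variance (df = n_A + n_B − 2) is smoothed
    across the intensity ordering, combined per the configured error model,
    shrunk with ``prior_df`` pseudo-observations of the smoothed variance,
    and used as the F denominator with df (1, residual df + prior_df).
    p-values are BH-adjusted across genes at ``fdr_alpha``.
    """
    for name, group in (("A", group_a), ("B", group_b)):
        if len(group) < 2:
            raise ValueError(f"group {name} needs >= 2 samples, got {len(group)}")
        missing = [s for s in group if s not in mat.values.columns]
        if missing:
            raise ValueError(f"group {name} samples missing from matrix: {missing}")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")

    A = mat.values[list(group_a)].to_numpy(dtype=float)
    B = mat.values[list(group_b)].to_numpy(dtype=float)
    if settings.log_transform:
        A = np.log2(A + 1.0)
        B = np.log2(B + 1.0)
    na, nb = A.shape[1], B.shape[1]
    df_resid = na + nb - 2

    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)
    ss_within = ((A - mean_a[:, None]) ** 2).sum(axis=1) + (
        (B - mean_b[:, None]) ** 2
    ).sum(axis=1)
    resid_var = ss_within / df_resid
    intensity = np.concatenate([A, B], axis=1).mean(axis=1)
    smoothed = smoothed_variance(resid_var, intensity, settings)

    if settings.error_model == "actual":
        error_var = resid_var
    elif settings.error_model == "average":
        error_var = smoothed
    else:  # max(average, actual)
        error_var = np.maximum(smoothed, resid_var)

    prior = settings.prior_df
    if prior > 0:
        posterior = (prior * smoothed + df_resid * error_var) / (prior + df_resid)
    else:
        posterior = error_var

    ms_between = na * nb / (na + nb) * (mean_a - mean_b) ** 2
    denom = np.maximum(posterior, settings.variance_floor)
    F = ms_between / denom
    df2 = df_resid + prior
    p_raw = f_dist.sf(F, 1, df2)
    p_adj = np.asarray(bh_adjust(p_raw))

    table = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "residual_var": resid_var,
            "smoothed_var": smoothed,
            "error_var": error_var,
            "posterior_var": posterior,
            "F": F,
            "df1": 1,
            "df2": df2,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "significant": p_adj <= settings.fdr_alpha,
        },
        index=mat.values.index,
    )
    return DEGeneTable(table=table, comparison=comparison, tissue=tissue)


def select_de_union(tables: list[DEGeneTable]) -> DeUnion:
    """Union of significant genes across comparisons, partitioned by tissue.

    A gene significant in several comparisons is counted once per tissue; the
    flattened union (all tissues pooled) is the ORA test set.
    """
    union = DeUnion()
    for tab in tables:
        tissue = tab.tissue or "all"
        union.per_tissue.setdefault(tissue, set()).update(tab.significant_genes)
    return union
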