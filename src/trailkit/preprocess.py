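"""Expression-matrix preprocessing: scaling, quantile normalization,
replicate medians, and fold-change ranked lists.

The pipeline mirrors standard single-channel microarray practice: probe-set
signals are scaled so every array has the same average intensity, quantile
normalization forces all arrays onto one common empirical distribution,
replicates are summarized per condition by their median, and each pairwise
comparison of conditions yields a list of genes ranked by log2 fold change —
the input format consumed by the running-sum enrichment test.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "ConditionMatrix",
    "ComparisonSpec",
    "RankedGeneList",
    "DESIGN_COLUMNS",
    "scale_to_target",
    "quantile_normalize",
    "replicate_median",
    "fold_change_ranking",
    "read_matrix",
    "write_matrix",
    "read_design",
    "write_design",
    "read_ranked_list",
    "write_ranked_list",
]

DESIGN_COLUMNS = ("tissue", "genotype", "treatment", "replicate")
CONDITION_COLUMNS = ("tissue", "genotype", "treatment")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative signals plus a sample design.

    ``values``: DataFrame indexed by gene id, one column per sample.
    ``design``: DataFrame indexed by sample name with columns
    (tissue, genotype, treatment, replicate); every sample column of
    ``values`` must have a complete design row.
    """

    values: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.index.isnull().any():
            raise ValueError("missing gene ids in expression matrix")
        if (self.values.values < 0).any():
            raise ValueError("expression signals must be non-negative")
        missing_cols = [c for c in DESIGN_COLUMNS if c not in self.design.columns]
        if missing_cols:
            raise ValueError(f"design table lacks columns {missing_cols}")
        missing_samples = [s for s in self.values.columns if s not in self.design.index]
        if missing_samples:
            raise ValueError(f"samples without design rows: {missing_samples}")
        sub = self.design.loc[list(self.values.columns), list(DESIGN_COLUMNS)]
        if sub.isnull().any().any():
            raise ValueError("incomplete design attributes")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def condition_of(self, sample: str) -> tuple[str, str, str]:
        row = self.design.loc[sample]
        return (row["tissue"], row["genotype"], row["treatment"])


@dataclass
class ConditionMatrix:
    """Per-gene medians across replicates, one column per condition.

    Columns are a MultiIndex (tissue, genotype, treatment); derived from an
    :class:`ExpressionMatrix` by :func:`replicate_median`.
    """

    medians: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.medians.columns, pd.MultiIndex):
            raise ValueError("condition matrix columns must be a (tissue, genotype, treatment) MultiIndex")
        if self.medians.columns.has_duplicates:
            raise ValueError("duplicate condition columns")

    def has_condition(self, tissue: str, genotype: str, treatment: str) -> bool:
        return (tissue, genotype, treatment) in self.medians.columns

    def column(self, tissue: str, genotype: str, treatment: str) -> pd.Series:
        return self.medians[(tissue, genotype, treatment)]


@dataclass(frozen=True)
class ComparisonSpec:
    """One pairwise contrast: test (genotype, treatment) vs baseline within a tissue."""

    tissue: str
    test_genotype: str
    test_treatment: str
    baseline_genotype: str
    baseline_treatment: str

    def __post_init__(self) -> None:
        if (self.test_genotype, self.test_treatment) == (
            self.baseline_genotype,
            self.baseline_treatment,
        ):
            raise ValueError("test and baseline conditions must differ")

    @property
    def test(self) -> tuple[str, str, str]:
        return (self.tissue, self.test_genotype, self.test_treatment)

    @property
    def baseline(self) -> tuple[str, str, str]:
        return (self.tissue, self.baseline_genotype, self.baseline_treatment)

    @property
    def label(self) -> str:
        if self.test_genotype == self.baseline_genotype:
            return (f"{self.tissue}: {self.test_treatment} vs {self.baseline_treatment}"
                    f" ({self.test_genotype})")
        if self.test_treatment == self.baseline_treatment:
            return (f"{self.tissue}: {self.test_genotype} vs {self.baseline_genotype}"
                    f" ({self.test_treatment})")
        return (f"{self.tissue}: {self.test_genotype}/{self.test_treatment}"
                f" vs {self.baseline_genotype}/{self.baseline_treatment}")

    def reversed(self) -> "ComparisonSpec":
        return ComparisonSpec(
            self.tissue,
            self.baseline_genotype,
            self.baseline_treatment,
            self.test_genotype,
            self.test_treatment,
        )


@dataclass
class RankedGeneList:
    """Gene ids sorted by score, highest first; the GSEA input.

    Ties in score are broken lexicographically by gene id so the ordering —
    and therefore every downstream p-value — is reproducible.
    """

    genes: list[str]
    scores: np.ndarray
    comparison: str = ""

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.genes) != len(self.scores):
            raise ValueError("genes and scores differ in length")
        if len(self.genes) < 2:
            raise ValueError("ranked list needs at least 2 genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("duplicate gene ids in ranked list")
        if np.any(np.diff(self.scores) > 0):
            raise ValueError("scores must be non-increasing from top to bottom")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def gene_set(self) -> frozenset[str]:
        return frozenset(self.genes)


# ---------------------------------------------------------------------------
# operations


def scale_to_target(mat: ExpressionMatrix, target: float = 100.0) -> ExpressionMatrix:
    """Scale every sample so its mean signal over all probe sets equals ``target``."""
    if target <= 0:
        raise ValueError("target must be positive")
    means = mat.values.mean(axis=0)
    if (means <= 0).any():
        bad = list(means.index[means <= 0])
        raise ValueError(f"samples with non-positive mean signal: {bad}")
    scaled = mat.values * (target / means)
    return ExpressionMatrix(values=scaled, design=mat.design)


def quantile_normalize(mat: ExpressionMatrix) -> ExpressionMatrix:
    """Force all sample columns onto the common quantile distribution.

    The common distribution is the vector of row means of the column-sorted
    matrix; each value is replaced by the common quantile at its rank within
    its own column.  Tied values within a column all receive the mean of the
    quantile values their tie group spans, which keeps the transform
    deterministic and symmetric in the tied entries.
    """
    X = mat.values.to_numpy(dtype=float)
    n_genes, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    ref = np.sort(X, axis=0).mean(axis=1)  # common distribution, ascending
    out = np.empty_like(X)
    for j in range(n_samples):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        sorted_vals = col[order]
        assigned = ref.copy()
        # average the reference quantiles across each tie run
        start = 0
        while start < n_genes:
            stop = start + 1
            while stop < n_genes and sorted_vals[stop] == sorted_vals[start]:
                stop += 1
            if stop - start > 1:
                assigned[start:stop] = ref[start:stop].mean()
            start = stop
        out[order, j] = assigned
    values = pd.DataFrame(out, index=mat.values.index, columns=mat.values.columns)
    return ExpressionMatrix(values=values, design=mat.design)


def replicate_median(mat: ExpressionMatrix) -> ConditionMatrix:
    """Summarize replicates: per gene per condition, the median signal."""
    keys = mat.design.loc[list(mat.values.columns), list(CONDITION_COLUMNS)]
    grouper = pd.MultiIndex.from_frame(keys)
    medians = mat.values.T.groupby(grouper).median().T
    medians.columns = pd.MultiIndex.from_tuples(medians.columns, names=CONDITION_COLUMNS)
    return ConditionMatrix(medians=medians)


def fold_change_ranking(
    cm: ConditionMatrix,
    spec: ComparisonSpec,
    pseudocount: float = 0.0,
) -> RankedGeneList:
    """Rank genes by log2 fold change of condition medians, highest first.

    score(g) = log2((median_test(g) + c) / (median_baseline(g) + c)) with
    pseudocount c >= 0; c must be positive if any median is zero.  Ties are
    broken by gene id (lexicographic, ascending).
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    for cond in (spec.test, spec.baseline):
        if not cm.has_condition(*cond):
            raise ValueError(f"condition {cond} not present in the condition matrix")
    test = cm.column(*spec.test).to_numpy(dtype=float) + pseudocount
    base = cm.column(*spec.baseline).to_numpy(dtype=float) + pseudocount
    if np.any(base == 0) or np.any(test == 0):
        raise ValueError("zero median encountered; use a positive pseudocount")
    scores = np.log2(test / base)
    genes = np.asarray(cm.medians.index, dtype=object)
    order = np.lexsort((genes, -scores))
    return RankedGeneList(
        genes=list(genes[order]),
        scores=scores[order],
        comparison=spec.label,
    )


# ---------------------------------------------------------------------------
# text I/O (TSV, one header row)


def read_matrix(matrix_path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    design = read_design(design_path)
    return ExpressionMatrix(values=values, design=design)


def write_matrix(mat: ExpressionMatrix, matrix_path: str | Path,
                 design_path: str | Path | None = None) -> None:
    mat.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    if design_path is not None:
        write_design(mat.design, design_path)


def read_design(path: str | Path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    design["replicate"] = design["replicate"].astype(int)
    return design


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index_label="sample")


def read_ranked_list(path: str | Path, comparison: str = "") -> RankedGeneList:
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "score"], dtype={0: str})
    return RankedGeneList(genes=list(df["gene_id"]), scores=df["score"].to_numpy(),
                          comparison=comparison)


def write_ranked_list(ranked: RankedGeneList, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, score in zip(ranked.genes, ranked.scores):
            fh.write(f"{gene}\t{score:.10g}\n")
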