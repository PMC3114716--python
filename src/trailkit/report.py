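"""Multi-comparison enrichment reporting.

The experimental design behind this package is a 2 x 2 x 2 grid — tissue
(root, leaf) x genotype (wild type, mutant) x treatment (+Fe, −Fe) — from
which eight meaningful pairwise comparisons are formed (per tissue: treatment
contrast within each genotype, genotype contrast within each treatment).
This module drives ranked-list GSEA over all configured comparisons and one
or more category collections, assembles the per-(comparison, category)
significance calls into a matrix, summarizes co-regulation as disjoint
Venn regions, and tabulates induced/repressed counts per comparison.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .categories import CategoryCollection
from .gsea import GseaResult, gsea_test
from .preprocess import ComparisonSpec, ConditionMatrix, fold_change_ranking
from .significance import adjust_results

__all__ = [
    "ComparisonMatrix",
    "VennSummary",
    "CountTable",
    "run_comparisons",
    "venn_summary",
    "count_table",
    "write_matrix_tsv",
    "write_venn_json",
    "write_venn_text",
]

#: rendering of enrichment direction in reports: induced = toward the top of
#: the test-vs-baseline ranking, repressed = toward the bottom
DIRECTION_MARK = {"enriched": "+", "depleted": "-"}


@dataclass
class ComparisonMatrix:
    """All per-comparison GSEA results, adjusted, in configured order."""

    comparisons: list[str]  # labels, configured order
    results: dict[str, list[GseaResult]]  # label -> adjusted results
    collection_label: str = ""

    def __post_init__(self) -> None:
        missing = [c for c in self.comparisons if c not in self.results]
        if missing:
            raise ValueError(f"comparisons without results: {missing}")

    def significant_cells(self) -> dict[tuple[str, str], str]:
        """(comparison, category) -> direction, significant cells only."""
        cells: dict[tuple[str, str], str] = {}
        for comp in self.comparisons:
            for res in self.results[comp]:
                if res.significant:
                    cells[(comp, res.category)] = res.direction
        return cells

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for comp in self.comparisons:
            for res in self.results[comp]:
                rows.append(
                    {
                        "comparison": comp,
                        "category": res.category,
                        "k": res.k,
                        "n": res.n,
                        "max_abs_deviation": res.max_abs_deviation,
                        "direction": res.direction,
                        "p_raw": res.p_raw,
                        "p_adj": res.p_adj,
                        "significant": res.significant,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class VennSummary:
    """Disjoint-region membership of significant categories.

    Each significant category belongs to exactly one region: the set of
    comparisons in which it is significant.  Per-comparison directions are
    kept because a category may be induced in one comparison and repressed in
    another.
    """

    regions: dict[frozenset[str], dict[str, dict[str, str]]] = field(default_factory=dict)
    comparisons: list[str] = field(default_factory=list)

    @property
    def total_categories(self) -> int:
        return sum(len(cats) for cats in self.regions.values())

    def region_of(self, category: str) -> frozenset[str] | None:
        for region, cats in self.regions.items():
            if category in cats:
                return region
        return None


@dataclass
class CountTable:
    """Induced/repressed/total significant-category counts per comparison."""

    table: pd.DataFrame  # index: comparison label; columns: induced, repressed, total (+ area counts)


def run_comparisons(
    cm: ConditionMatrix,
    colls: CategoryCollection | list[CategoryCollection],
    specs: list[ComparisonSpec],
    min_size: int = 2,
    alpha: float = 0.05,
    adjust: str = "fdr_bh",
    pseudocount: float = 0.0,
) -> ComparisonMatrix:
    """Rank, test, and adjust every comparison against every collection.

    For each comparison a fold-change ranked list is built from the condition
    medians and tested against each category collection; the FDR family is
    one (comparison, collection) analysis run.  Results from several
    collections are concatenated per comparison.
    """
    if isinstance(colls, CategoryCollection):
        colls = [colls]
    labels = [spec.label for spec in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("comparison labels must be unique")
    results: dict[str, list[GseaResult]] = {}
    for spec in specs:
        ranked = fold_change_ranking(cm, spec, pseudocount=pseudocount)
        per_comp: list[GseaResult] = []
        for coll in colls:
            res = gsea_test(ranked, coll, min_size=min_size)
            adjust_results(res, alpha=alpha, method=adjust)
            per_comp.extend(res)
        results[spec.label] = per_comp
    return ComparisonMatrix(comparisons=labels, results=results)


def venn_summary(mat: ComparisonMatrix) -> VennSummary:
    """Assign every significant category to its exact region of comparisons."""
    by_category: dict[str, dict[str, str]] = {}
    for (comp, cat), direction in mat.significant_cells().items():
        by_category.setdefault(cat, {})[comp] = direction
    summary = VennSummary(comparisons=list(mat.comparisons))
    for cat in sorted(by_category):
        marks = by_category[cat]
        region = frozenset(marks)
        summary.regions.setdefault(region, {})[cat] = dict(sorted(marks.items()))
    return summary


def count_table(
    mat: ComparisonMatrix,
    area_map: dict[str, str] | None = None,
) -> CountTable:
    """Per comparison: induced and repressed significant categories and the sum.

    With an optional category -> area mapping, the number of distinct areas
    the counted categories fall into is reported alongside (the parenthesized
    counts of summary tables); categories without an area entry count as
    their own singleton area.
    """
    rows = []
    cells = mat.significant_cells()
    for comp in mat.comparisons:
        induced = sorted(c for (cc, c), d in cells.items() if cc == comp and d == "enriched")
        repressed = sorted(c for (cc, c), d in cells.items() if cc == comp and d == "depleted")
        row: dict[str, object] = {
            "comparison": comp,
            "induced": len(induced),
            "repressed": len(repressed),
            "total": len(induced) + len(repressed),
        }
        if area_map is not None:
            def n_areas(cats: list[str]) -> int:
                return len({area_map.get(c, c) for c in cats})

            row["induced_areas"] = n_areas(induced)
            row["repressed_areas"] = n_areas(repressed)
            row["total_areas"] = n_areas(induced + repressed)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("comparison")
    return CountTable(table=table)


# ---------------------------------------------------------------------------
# writers


def write_matrix_tsv(mat: ComparisonMatrix, path: str | Path) -> None:
    mat.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _region_key(region: frozenset[str], order: list[str]) -> str:
    return " & ".join(c for c in order if c in region)


def write_venn_json(summary: VennSummary, path: str | Path) -> None:
    payload = {
        "comparisons": summary.comparisons,
        "total_categories": summary.total_categories,
        "regions": [
            {
                "comparisons": sorted(region, key=summary.comparisons.index),
                "categories": {
                    cat: marks for cat, marks in sorted(cats.items())
                },
            }
            for region, cats in sorted(
                summary.regions.items(),
                key=lambda kv: (len(kv[0]), _region_key(kv[0], summary.comparisons)),
            )
        ],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=False)
        fh.write("\n")


def write_venn_text(summary: VennSummary, path: str | Path) -> None:
    """Plain-text region report; directions rendered as +/- suffixes."""
    with open(path, "w") as fh:
        fh.write(f"# {summary.total_categories} significant categories across "
                 f"{len(summary.comparisons)} comparisons\n")
        for region, cats in sorted(
            summary.regions.items(),
            key=lambda kv: (len(kv[0]), _region_key(kv[0], summary.comparisons)),
        ):
            fh.write(f"[{_region_key(region, summary.comparisons)}]\n")
            for cat, marks in sorted(cats.items()):
                rendered = ", ".join(
                    f"{comp}{DIRECTION_MARK[d]}" for comp, d in marks.items()
                )
                fh.write(f"  {cat}: {rendered}\n")
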