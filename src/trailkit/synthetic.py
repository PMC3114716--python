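"""Synthetic expression experiments with known category-level ground truth.

The generator emulates the shape of a two-tissue factorial microarray study:
tissue (root, leaf) x genotype (WT, nas4x-1) x treatment (+Fe, -Fe), three
biological replicates per condition, probe-set-level signals on a positive
raw scale.  Per-gene baseline abundances are log-normal; replicate noise is
Gaussian on the log2 scale; *implanted* categories receive an additive log2
shift (multiplicative on the raw scale, so it moves fold-change rankings) in
the test condition of each comparison they are configured to affect, while
*decoy* categories are random gene sets with no effect.  The emitted matrix,
design, category, reference and truth files are exactly the text formats the
rest of the package consumes, so every pipeline stage can be exercised — and
its false/true positive behaviour measured — without any external data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .categories import CategoryCollection, GeneCategory, ReferenceSet, write_gmt, write_reference
from .preprocess import ComparisonSpec, ExpressionMatrix, write_design, write_matrix

__all__ = [
    "Implant",
    "SimConfig",
    "SimTruth",
    "SimBundle",
    "standard_comparisons",
    "simulate_experiment",
    "write_fixture",
    "read_truth",
]


def standard_comparisons(
    tissues: tuple[str, ...] = ("root", "leaf"),
    genotypes: tuple[str, str] = ("WT", "nas4x-1"),
    treatments: tuple[str, str] = ("+Fe", "-Fe"),
) -> list[ComparisonSpec]:
    """The eight meaningful pairwise comparisons of the 2x2x2 design.

    Per tissue: stress vs control within each genotype, and mutant vs wild
    type within each treatment.  With the defaults:
    -Fe vs +Fe (WT), -Fe vs +Fe (nas4x-1), nas4x-1 vs WT (+Fe),
    nas4x-1 vs WT (-Fe), for roots and leaves respectively.
    """
    wt, mut = genotypes
    ctrl, stress = treatments
    specs = []
    for tissue in tissues:
        specs.append(ComparisonSpec(tissue, wt, stress, wt, ctrl))
        specs.append(ComparisonSpec(tissue, mut, stress, mut, ctrl))
        specs.append(ComparisonSpec(tissue, mut, ctrl, wt, ctrl))
        specs.append(ComparisonSpec(tissue, mut, stress, wt, stress))
    return specs


@dataclass(frozen=True)
class Implant:
    """One category with a real, known effect.

    ``delta`` is the log2 effect size in units of the replicate noise
    standard deviation; ``direction`` "induced" shifts the category's genes
    up in the test condition of every affected comparison, "repressed" down.
    """

    name: str
    size: int
    comparisons: tuple[ComparisonSpec, ...]
    delta: float
    direction: str = "induced"

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("implanted categories need >= 2 members")
        if self.direction not in ("induced", "repressed"):
            raise ValueError("direction must be 'induced' or 'repressed'")
        if not self.comparisons:
            raise ValueError("implant must affect at least one comparison")

    @property
    def signed_delta(self) -> float:
        return self.delta if self.direction == "induced" else -self.delta


@dataclass(frozen=True)
class SimConfig:
    """Study-shaped simulation parameters.

    Defaults mirror a compact version of the factorial design: 2,000 genes,
    eight conditions, three replicates each.  Baseline log2 signal ~
    Normal(7, 2) — a typical microarray log-intensity spread — and replicate
    noise sigma = 0.3 on the log2 scale, a realistic biological-replicate
    scatter for array data.  Effect sizes of implants are expressed in units
    of sigma.
    """

    n_genes: int = 2000
    tissues: tuple[str, ...] = ("root", "leaf")
    genotypes: tuple[str, str] = ("WT", "nas4x-1")
    treatments: tuple[str, str] = ("+Fe", "-Fe")
    replicates: int = 3
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 2.0
    noise_sd: float = 0.3
    implants: tuple[Implant, ...] = ()
    n_decoys: int = 20
    decoy_size_range: tuple[int, int] = (5, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least 1 replicate per condition")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.decoy_size_range[0] < 2 or self.decoy_size_range[0] > self.decoy_size_range[1]:
            raise ValueError("invalid decoy size range")
        total = sum(im.size for im in self.implants)
        if total > self.n_genes:
            raise ValueError(
                f"implants cover {total} genes but only {self.n_genes} exist"
            )

    @property
    def conditions(self) -> list[tuple[str, str, str]]:
        return [
            (ti, ge, tr)
            for ti in self.tissues
            for ge in self.genotypes
            for tr in self.treatments
        ]


@dataclass
class SimTruth:
    """Ground truth of one simulated experiment.

    ``category_truth``: implanted category -> intended comparison labels and
    direction.  ``gene_truth``: comparison label -> genes whose *net*
    condition effect differs between that comparison's test and baseline
    condition (an implant can silently cancel in a comparison where it moved
    both sides — such genes are not truly DE there and are not listed).
    ``decoys``: names of the effect-free categories.
    """

    category_truth: dict[str, dict] = field(default_factory=dict)
    gene_truth: dict[str, set[str]] = field(default_factory=dict)
    decoys: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "category_truth": self.category_truth,
            "gene_truth": {c: sorted(g) for c, g in sorted(self.gene_truth.items())},
            "decoys": sorted(self.decoys),
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "SimTruth":
        payload = json.loads(text)
        return cls(
            category_truth=payload["category_truth"],
            gene_truth={c: set(g) for c, g in payload["gene_truth"].items()},
            decoys=list(payload["decoys"]),
        )


@dataclass
class SimBundle:
    matrix: ExpressionMatrix
    categories: CategoryCollection
    truth: SimTruth
    reference: ReferenceSet


def simulate_experiment(cfg: SimConfig) -> SimBundle:
    """Draw one experiment: signals, categories (implants + decoys), truth.

    Reproducible: the same config (including seed) yields bitwise-identical
    output.  Raw signals are 2**(baseline + condition effect + noise); the
    condition effect is the sum of the log2 shifts of every implant touching
    that condition.
    """
    rng = np.random.default_rng(cfg.seed)
    width = max(4, len(str(cfg.n_genes - 1)))
    genes = [f"G{i:0{width}d}" for i in range(cfg.n_genes)]
    conditions = cfg.conditions
    cond_index = {c: j for j, c in enumerate(conditions)}

    baseline = rng.normal(cfg.baseline_log2_mean, cfg.baseline_log2_sd, size=cfg.n_genes)

    # assign implant members from a shuffled gene order so implants are
    # disjoint; decoys are drawn from the remaining (effect-free) genes
    shuffled = list(rng.permutation(cfg.n_genes))
    effect = np.zeros((cfg.n_genes, len(conditions)))
    coll = CategoryCollection(namespace="gene")
    truth = SimTruth()
    cursor = 0
    for implant in cfg.implants:
        idx = shuffled[cursor : cursor + implant.size]
        cursor += implant.size
        members = frozenset(genes[i] for i in idx)
        coll.add(GeneCategory(implant.name, members, source="implant"))
        shift = implant.signed_delta * cfg.noise_sd
        for spec in implant.comparisons:
            if spec.test not in cond_index:
                raise ValueError(f"implant {implant.name!r} targets unknown condition {spec.test}")
            effect[idx, cond_index[spec.test]] += shift
        truth.category_truth[implant.name] = {
            "comparisons": [spec.label for spec in implant.comparisons],
            "direction": implant.direction,
            "delta": implant.delta,
            "size": implant.size,
        }

    free = np.array(shuffled[cursor:], dtype=int)
    for d in range(cfg.n_decoys):
        lo, hi = cfg.decoy_size_range
        size = int(rng.integers(lo, hi + 1))
        if size > free.size:
            raise ValueError("decoy size exceeds the number of effect-free genes")
        idx = rng.choice(free, size=size, replace=False)
        name = f"decoy_{d:03d}"
        coll.add(GeneCategory(name, frozenset(genes[i] for i in idx), source="decoy"))
        truth.decoys.append(name)

    # true per-gene DE status per comparison, from net condition effects
    for spec in standard_comparisons(cfg.tissues, cfg.genotypes, cfg.treatments):
        if spec.test in cond_index and spec.baseline in cond_index:
            diff = effect[:, cond_index[spec.test]] - effect[:, cond_index[spec.baseline]]
            truth.gene_truth[spec.label] = {genes[i] for i in np.nonzero(diff)[0]}

    # replicate signals
    columns, design_rows, data = [], [], []
    for cond in conditions:
        ti, ge, tr = cond
        for r in range(1, cfg.replicates + 1):
            name = f"{ti}_{ge}_{tr}_r{r}"
            columns.append(name)
            design_rows.append({"sample": name, "tissue": ti, "genotype": ge,
                                "treatment": tr, "replicate": r})
            noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
            data.append(baseline + effect[:, cond_index[cond]] + noise)
    values = pd.DataFrame(
        np.power(2.0, np.column_stack(data)), index=pd.Index(genes, name="gene_id"),
        columns=columns,
    )
    design = pd.DataFrame(design_rows).set_index("sample")
    matrix = ExpressionMatrix(values=values, design=design)
    reference = ReferenceSet(frozenset(genes), label="simulated chip")
    return SimBundle(matrix=matrix, categories=coll, truth=truth, reference=reference)


def write_fixture(bundle: SimBundle, directory: str | Path) -> dict[str, Path]:
    """Emit the fixture files the CLI consumes; returns the path map.

    Files: matrix.tsv, design.tsv, categories.gmt, reference.txt, truth.json.
    Output is deterministic (sorted keys, fixed float format) so identical
    configs produce identical bytes.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": directory / "matrix.tsv",
        "design": directory / "design.tsv",
        "categories": directory / "categories.gmt",
        "reference": directory / "reference.txt",
        "truth": directory / "truth.json",
    }
    bundle.matrix.values.to_csv(paths["matrix"], sep="\t", index_label="gene_id",
                                float_format="%.8g")
    write_design(bundle.matrix.design, paths["design"])
    write_gmt(bundle.categories, paths["categories"])
    write_reference(bundle.reference, paths["reference"])
    paths["truth"].write_text(bundle.truth.to_json())
    return paths


def read_truth(path: str | Path) -> SimTruth:
    return SimTruth.from_json(Path(path).read_text())
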