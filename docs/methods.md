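# Methods

This note documents the statistical machinery implemented in `trailkit`, the
conventions it adopts where the literature leaves choices open, and what the
synthetic-experiment generator does and does not emulate.

## Running-sum GSEA

### Statistic

The enrichment test takes a gene list ranked by some score (here: log2 fold
change of condition medians, highest first) and a category of k genes that
appear in the list of length n. Walking the list from top to bottom, a
running sum RS increases by (n − k) on every category member and decreases by
k on every non-member. Two properties follow from this choice of increments:

* RS_n = 0 for every placement, so the walk is a bridge;
* under the null hypothesis — the k member positions exchangeable among the
  C(n, k) placements — the law of the walk does not depend on the scores,
  only on (n, k).

The test statistic is D = max_i |RS_i|, the maximal absolute deviation from
zero. A positive excursion at the first position attaining D means the
members concentrate at the top of the list ("enriched", mountain-shaped
profile); a negative one means concentration at the bottom ("depleted",
valley-shaped). When both +D and −D are attained on one walk the result is
flagged `ambiguous` and the first excursion decides the reported direction —
a deterministic tie-break; the flag lets callers notice the coin-flip.

### Exact p-value

p = P(max_i |RS_i| ≥ D) under the null. After i steps with j members seen,
RS = j(n − k) − (i − j)k = jn − ik, so a placement is a monotone lattice path
from (0, 0) to (n, k) and the survival event {max |RS| < D} is the event that
the path avoids every state with |jn − ik| ≥ D. Survivor paths are counted by
dynamic programming over the (n + 1) × (k + 1) table

    ways[i][j] = ways[i−1][j] + ways[i−1][j−1],

zeroing forbidden and infeasible cells, and p = 1 − ways[n][k] / C(n, k).
Counts are carried in float64, which represents integers exactly up to 2^53;
for larger tables the column is rescaled and a log-scale offset tracked, and
the final ratio is formed in log space via `lgamma`. For every n ≤ 12 the
result agrees with brute-force enumeration of all C(n, k) placements to
better than 1e-12 (tested); a 2,000 × 10 table evaluates in ~40 ms.

Edge conventions: d = 0 returns 1 (every walk attains |RS| ≥ 0);
d > k(n − k) returns 0 (beyond the maximal attainable deviation); k = n gives
a identically-zero walk with D = 0 and p = 1.

The exact method is used whenever n·k ≤ 5·10^7 DP cells; beyond that a
permutation fallback estimates the tail with the add-one estimator
p̂ = (1 + #{D* ≥ D}) / (n_perm + 1), reproducible for a given seed.

### Choices the literature leaves open

The increment magnitudes ±(n − k)/±k, the first-excursion sign rule, and
lexicographic tie-breaking of equal fold changes in the ranked list are this
package's conventions, chosen for determinism and for making the exact tail
computable; they are declared here rather than inherited from any published
description, which specifies only "increase on member / decrease otherwise".
P-values for categories containing tied-score genes depend on the tie rule.

## Over-representation analysis

For a test set of t genes drawn from a reference universe of m genes, and a
category occupying k of the m, the overlap x is hypergeometric under the
null. The expected overlap is e = tk/m; a category with x ≥ e is classified
over-represented and assigned the upper tail P(X ≥ x), otherwise
under-represented with the lower tail P(X ≤ x). The boundary x = e counts as
over-represented — its upper tail is ≥ 0.5 and can never be called
significant, so the convention is conservative. Tails come from
`scipy.stats.hypergeom` and satisfy upper(x) + lower(x) = 1 + P(X = x)
exactly (tested against subset enumeration for all m ≤ 12).

Test-set members absent from the reference are dropped with a warning rather
than enlarging m: the reference defines the universe. Categories are
intersected with the reference before k is measured; the same restriction
rule feeds GSEA, so k always refers to genes actually observable.

## Multiple testing

Raw p-values from one analysis run — one ranked list or one test set against
one category collection — form one family and are adjusted with the
Benjamini–Hochberg step-up procedure (via `statsmodels`), q_(i) = min_{j≥i}
m·p_(j)/j capped at 1. Significance is called at q ≤ α with α = 0.05 by
default; the threshold is inclusive. Families are deliberately *not* pooled
across the eight comparisons or across collections: each (comparison,
collection) pair is its own analysis run.

## Preprocessing

* **Scaling**: each sample column is multiplied by target/mean so that the
  average signal over all probe sets equals a common target (default 100).
* **Quantile normalization**: the common distribution is the vector of row
  means of the column-sorted matrix; each value is replaced by the common
  quantile at its rank in its own column. Within-column ties all receive the
  mean of the quantile values their tie run spans — deterministic and
  symmetric in the tied entries. On tie-free data the transform is
  idempotent and leaves all columns with bitwise-identical sorted vectors;
  with ties the tie-averaging perturbs the shared distribution slightly, the
  standard behaviour of this tie rule.
* **Replicate summary**: per gene and condition, the median over that
  condition's replicates (designed for n = 3 per condition, any n ≥ 1 works).
* **Ranking**: score(g) = log2((med_test + c)/(med_baseline + c)) with
  pseudocount c ≥ 0 (default 0; a zero median then raises instead of
  silently bending scores). log2 rather than plain ratios is a symmetry
  choice only — the ranking order, which is all the enrichment test
  consumes, is identical. Ties break lexicographically by gene id.

## Differential expression (regularized ANOVA)

Per gene, a two-group single-factor ANOVA on log2(signal + 1):

* pooled within-group residual variance s²_g with df_g = n_A + n_B − 2;
* smoothed variance: genes ordered by mean log-intensity, each gene's
  smoothed value is the mean of residual variances in its centered window of
  500 genes (clipped — shorter — near the ends), after discarding the top
  ⌈0.01·window⌉ largest variances in the window (any positive trim discards
  at least one value);
* error model `max_avg_actual` (default): s²_err = max(smoothed, s²_g);
  alternatives `actual` and `average` are selectable;
* Bayesian shrinkage: s²_post = (d₀·smoothed + df_g·s²_err)/(d₀ + df_g) with
  prior df d₀ = 10, and the F test uses df (1, df_g + d₀);
* F = between-group mean square / max(s²_post, floor), p from the F
  distribution, BH-adjusted across the gene table at α = 0.05.

With d₀ = 0 and the `actual` model the statistic reduces exactly to the
squared pooled-variance t statistic (tested). The window size (500), the
end-clipping rule, and reading "zero mutations" in legacy settings strings
as "zero permutations, parametric p-values" are this package's documented
reconstruction of a tool whose internals were never published; all knobs
live in `NiaSettings`. The union of significant genes over a set of
comparisons, partitioned by tissue, is the ORA test set.

## Comparison driver, Venn regions, count tables

The factorial design tissue × genotype × treatment (2 × 2 × 2, three
replicates) yields eight meaningful pairwise comparisons: per tissue, the
treatment contrast within each genotype and the genotype contrast within
each treatment. `run_comparisons` builds the ranked list for each, tests
every collection, adjusts per (comparison, collection) family, and returns
the full matrix of calls. `venn_summary` assigns each significant category
to exactly one region — the set of comparisons in which it is significant —
keeping per-comparison directions (a category may be induced in one
comparison and repressed in another; text output renders +/− suffixes).
`count_table` tabulates induced/repressed/total per comparison, optionally
with distinct-area counts when a category → area mapping is supplied.
Regions partition the significant categories, and the per-comparison totals
equal the sum over regions containing that comparison (both tested).

## Synthetic experiments

`simulate_experiment` draws per-gene baseline log2 abundances from
Normal(7, 2) — a typical microarray log-intensity spread — and replicate
values as baseline + condition effect + Normal(0, σ) with σ = 0.3, a
realistic biological-replicate scatter on the log2 scale for array data.
Signals are exponentiated to the raw scale, so effects are additive in log2
and multiplicative in signal, matching the fold-change ranking semantics.
Implanted categories receive a shift of δ·σ in the test condition of each
comparison they target (sign per configured direction); decoy categories
are random sets from the remaining genes, disjoint from all implants. The
recorded gene-level truth is derived from the *net* condition effects, so an
implant that moves both sides of some other comparison equally is correctly
not listed as differentially expressed there — and conversely, a shift to a
condition that serves as another comparison's baseline genuinely affects
that comparison and is listed.

What the generator does not emulate: probe-level artifacts (PM/MM,
saturation), intensity-dependent variance, batch or array effects,
correlated genes outside implanted categories. Passing recovery tests
therefore demonstrate the statistical machinery under clean factorial
conditions, not robustness to real-array pathologies.

### Problem sizes used in validation

The shipped validation suite measures, among others: exactness of the GSEA
p-value for all n ≤ 12 against enumeration; null calibration from 1,000
random rankings × 50 random categories (n = 200, k ∈ [2, 10]), where the
empirical P(p ≤ 0.05) must not exceed 0.05 plus three standard errors (the
discrete statistic is conservative, typically ~0.048); implanted-category
recovery at δ = 2σ, k = 10, 2,000 genes over 100 seeds (≥ 95% required,
100% observed) with decoy false-positive mean ≤ 5% (~0.5% observed); ANOVA
null behaviour on 3 vs 3 × 10,000 genes and sensitivity ≥ 0.9 at δ = 4σ on
200-gene simulations. These sizes keep the full suite around a minute while
leaving each check statistically meaningful.

## Known limitations

* The exact-p DP is O(n·k) per category with small constants; thousands of
  categories against very long lists may warrant the permutation fallback.
* The ambiguous-direction flag is informational; no two-sided direction
  inference is attempted.
* Quantile normalization assumes the arrays share a common distribution;
  it is not appropriate when most genes change.
* The ANOVA reconstruction is faithful to the published settings strings,
  not bit-for-bit to any web tool's output.
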