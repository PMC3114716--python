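import numpy as np
import pytest
from scipy import stats

from trailkit.diffexpr import (
    DEGeneTable,
    NiaSettings,
    pairwise_anova,
    select_de_union,
    smoothed_variance,
)
from trailkit.synthetic import Implant, SimConfig, simulate_experiment, standard_comparisons

from .conftest import make_matrix


def two_group_matrix(A, B, genes=None):
    """Genes x (3+3) matrix with WT +Fe / WT -Fe design."""
    rows = [
        ("a1", "root", "WT", "-Fe", 1), ("a2", "root", "WT", "-Fe", 2),
        ("a3", "root", "WT", "-Fe", 3),
        ("b1", "root", "WT", "+Fe", 1), ("b2", "root", "WT", "+Fe", 2),
        ("b3", "root", "WT", "+Fe", 3),
    ]
    values = np.hstack([np.asarray(A, float), np.asarray(B, float)])
    return make_matrix(values, genes=genes, design_rows=rows)


GROUP_A = ["a1", "a2", "a3"]
GROUP_B = ["b1", "b2", "b3"]


class TestSmoothedVariance:
    def test_constant_variances_unchanged(self):
        v = np.full(300, 2.5)
        out = smoothed_variance(v, np.arange(300.0))
        np.testing.assert_allclose(out, 2.5)

    def test_single_outlier_trimmed_from_window(self):
        v = np.ones(100)
        v[40] = 1000.0
        out = smoothed_variance(v, np.arange(100.0), NiaSettings(window_size=100))
        np.testing.assert_allclose(out, 1.0)

    def test_trim_zero_is_plain_moving_average(self):
        rng = np.random.default_rng(2)
        v = rng.gamma(2.0, 1.0, size=60)
        settings = NiaSettings(trim_proportion=0.0, window_size=7)
        out = smoothed_variance(v, np.arange(60.0), settings)
        # centered window, clipped at the ends
        expected = [v[max(0, c - 3): min(60, c + 4)].mean() for c in range(60)]
        np.testing.assert_allclose(out, expected)

    def test_too_few_genes_skips_trimming_with_warning(self, caplog):
        v = np.ones(50)
        v[10] = 100.0
        with caplog.at_level("WARNING"):
            out = smoothed_variance(v, np.arange(50.0), NiaSettings(window_size=50))
        assert "skipped" in caplog.text
        assert out[0] > 1.0  # the outlier stayed in the average

    def test_returned_in_input_gene_order(self):
        v = np.array([1.0, 9.0, 5.0])
        intens = np.array([3.0, 1.0, 2.0])  # ordering reverses the genes
        out = smoothed_variance(v, intens, NiaSettings(window_size=1, trim_proportion=0.0))
        np.testing.assert_allclose(out, v)  # window 1: each gene keeps its own variance


class TestPairwiseAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        vals = np.tile([[1.0, 2.0, 3.0]], (4, 1))
        mat = two_group_matrix(vals, vals)
        tab = pairwise_anova(mat, GROUP_A, GROUP_B).table
        np.testing.assert_allclose(tab["F"], 0.0)
        np.testing.assert_allclose(tab["p_raw"], 1.0)

    def test_f_equals_squared_t_without_regularization(self):
        rng = np.random.default_rng(5)
        A = rng.normal(8.0, 1.0, size=(30, 3))
        B = rng.normal(9.0, 1.0, size=(30, 3))
        settings = NiaSettings(error_model="actual", prior_df=0, log_transform=False)
        mat = two_group_matrix(np.abs(A), np.abs(B))
        tab = pairwise_anova(mat, GROUP_A, GROUP_B, settings).table
        t, p = stats.ttest_ind(np.abs(A), np.abs(B), axis=1)
        np.testing.assert_allclose(tab["F"], t**2, rtol=1e-10)
        np.testing.assert_allclose(tab["p_raw"], p, rtol=1e-10)

    def test_constant_groups_with_large_shift_are_significant(self):
        mat = two_group_matrix(np.full((1, 3), 1000.0), np.full((1, 3), 1.0))
        tab = pairwise_anova(mat, GROUP_A, GROUP_B).table
        assert tab["significant"].iloc[0]
        assert tab["p_adj"].iloc[0] < 0.05

    def test_swapping_group_labels_preserves_p(self):
        rng = np.random.default_rng(9)
        A = rng.gamma(3.0, 30.0, size=(25, 3))
        B = rng.gamma(3.0, 40.0, size=(25, 3))
        mat = two_group_matrix(A, B)
        fwd = pairwise_anova(mat, GROUP_A, GROUP_B).table
        rev = pairwise_anova(mat, GROUP_B, GROUP_A).table
        np.testing.assert_allclose(fwd["p_raw"], rev["p_raw"], rtol=1e-12)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(13)
        A = rng.gamma(3.0, 30.0, size=(40, 3))
        B = rng.gamma(3.0, 40.0, size=(40, 3))
        genes = [f"g{i:02d}" for i in range(40)]
        mat = two_group_matrix(A, B, genes=genes)
        perm = rng.permutation(40)
        mat_perm = two_group_matrix(A[perm], B[perm], genes=[genes[i] for i in perm])
        t1 = pairwise_anova(mat, GROUP_A, GROUP_B).table
        t2 = pairwise_anova(mat_perm, GROUP_A, GROUP_B).table
        np.testing.assert_allclose(
            t1.loc[genes, "p_raw"], t2.loc[genes, "p_raw"], rtol=1e-12
        )

    def test_degenerate_group_sizes_rejected(self):
        mat = two_group_matrix(np.ones((3, 3)), np.ones((3, 3)))
        with pytest.raises(ValueError):
            pairwise_anova(mat, ["a1"], GROUP_B)

    def test_df2_includes_prior_df(self):
        mat = two_group_matrix(np.ones((3, 3)) * 4, np.ones((3, 3)) * 5)
        tab = pairwise_anova(mat, GROUP_A, GROUP_B, NiaSettings(prior_df=10)).table
        assert (tab["df2"] == 4 + 10).all()


class TestSelectDeUnion:
    @staticmethod
    def table_with(genes_sig, all_genes, comparison, tissue):
        import pandas as pd

        df = pd.DataFrame(
            {"significant": [g in genes_sig for g in all_genes]},
            index=pd.Index(all_genes, name="gene_id"),
        )
        return DEGeneTable(table=df, comparison=comparison, tissue=tissue)

    def test_union_counts_each_gene_once(self):
        genes = [f"g{i}" for i in range(6)]
        tables = [
            self.table_with({"g0", "g1"}, genes, "c1", "leaf"),
            self.table_with({"g1", "g2"}, genes, "c2", "leaf"),
            self.table_with({"g1"}, genes, "c3", "leaf"),
        ]
        union = select_de_union(tables)
        assert union.per_tissue == {"leaf": {"g0", "g1", "g2"}}
        assert union.counts() == {"leaf": 3}

    def test_empty_when_nothing_significant(self):
        genes = ["g0", "g1"]
        union = select_de_union([self.table_with(set(), genes, "c", "root")])
        assert union.all_genes == set()

    def test_tissue_partition_from_simulated_truth(self):
        target = standard_comparisons(tissues=("leaf",))[0]
        cfg = SimConfig(
            n_genes=300, tissues=("root", "leaf"), n_decoys=0, seed=4,
            implants=(Implant("leafy", 20, (target,), 5.0),),
        )
        bundle = simulate_experiment(cfg)
        mat = bundle.matrix
        d = mat.design
        tables = []
        for tissue in ("root", "leaf"):
            spec = standard_comparisons(tissues=(tissue,))[0]
            ga = list(d.index[(d.tissue == tissue) & (d.genotype == "WT") & (d.treatment == "-Fe")])
            gb = list(d.index[(d.tissue == tissue) & (d.genotype == "WT") & (d.treatment == "+Fe")])
            tables.append(pairwise_anova(mat, ga, gb, comparison=spec.label, tissue=tissue))
        union = select_de_union(tables)
        truth = bundle.truth.gene_truth[target.label]
        assert union.per_tissue.get("root", set()) == set()
        assert union.per_tissue["leaf"] <= truth  # only implanted genes recovered
        assert len(union.per_tissue["leaf"]) >= 0.5 * len(truth)
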