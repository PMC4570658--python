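import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from devdup.diffexpr import (
    DECallConfig,
    HousekeepingConfig,
    call_pairwise_de,
    housekeeping_genes,
    regulated_genes,
    sample_overview,
    stage_specificity_stat,
    wilcoxon_ranksum_p,
)
from devdup.formats import ExpressionTable
from devdup.synthio import FamilySimConfig, simulate_dataset

from conftest import ternary_from_array


def enumeration_ranksum_p(x, y):
    """Independent oracle: two-sided rank-sum p by full enumeration of all
    C(n1+n2, n1) group assignments of the pooled midranks."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(x) + len(y)
    ranks = st.rankdata(pooled)
    total = ranks.sum()
    mu = n1 * total / n
    dev = abs(ranks[:n1].sum() - mu)
    hits = sum(
        1
        for idx in itertools.combinations(range(n), n1)
        if abs(ranks[list(idx)].sum() - mu) >= dev - 1e-9
    )
    return hits / comb(n, n1)


class TestCallPairwiseDE:
    def test_ten_samples_give_45_columns(self):
        rng = np.random.default_rng(0)
        expr = ExpressionTable(
            pd.DataFrame(rng.uniform(1, 50, (3, 10)),
                         index=list("abc"), columns=[f"s{i}" for i in range(10)])
        )
        de = call_pairwise_de(expr)
        assert de.data.shape == (3, 45)

    def test_constant_gene_has_all_zero_row(self):
        expr = ExpressionTable(
            pd.DataFrame([[5.0] * 4], index=["flat"], columns=list("abcd"))
        )
        de = call_pairwise_de(expr)
        assert (de.data.loc["flat"] == 0).all()

    def test_fold_change_rule_hand_arithmetic(self):
        # x_i=1, x_j=7, c=1, tau=1: log2(8/2)=2 >= 1 -> +1 in the (i,j) column
        expr = ExpressionTable(pd.DataFrame([[1.0, 7.0]], index=["g"], columns=["i", "j"]))
        de = call_pairwise_de(expr, DECallConfig(log2fc_threshold=1.0, pseudocount=1.0))
        assert de.data.loc["g", "i|j"] == 1

    def test_antisymmetry_under_sample_reversal(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.uniform(0, 100, (20, 5)),
                          index=[f"g{i}" for i in range(20)], columns=list("abcde"))
        fwd = call_pairwise_de(ExpressionTable(df))
        rev = call_pairwise_de(ExpressionTable(df[list("edcba")]))
        for i, j in fwd.pairs:
            assert (fwd.data[f"{i}|{j}"] == -rev.data[f"{j}|{i}"]).all()

    def test_infinite_threshold_gives_all_zero_matrix(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.uniform(0, 100, (10, 4)),
                          index=[f"g{i}" for i in range(10)], columns=list("abcd"))
        expr = ExpressionTable(df)
        de = call_pairwise_de(expr, DECallConfig(log2fc_threshold=1e9))
        assert (de.data == 0).all().all()
        hk = housekeeping_genes(expr, de, HousekeepingConfig(floor=10.0))
        assert hk == set(df.index[(df >= 10).all(axis=1)])

    def test_fewer_than_two_samples_rejected(self):
        expr = ExpressionTable(pd.DataFrame({"only": [1.0]}, index=["g"]))
        with pytest.raises(ValueError):
            call_pairwise_de(expr)

    def test_replicate_groups_gate_calls(self):
        # two groups x three replicates: a clean 8-fold change passes the
        # t-test gate, pure noise does not produce calls
        rng = np.random.default_rng(3)
        a = rng.uniform(9, 11, (1, 3))
        b = a * 8
        df = pd.DataFrame(np.vstack([np.hstack([a, b]), np.full((1, 6), 10.0)]),
                          index=["de", "flat"], columns=[f"s{i}" for i in range(6)])
        groups = {f"s{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        de = call_pairwise_de(ExpressionTable(df), replicate_groups=groups)
        assert list(de.data.columns) == ["g1|g2"]
        assert de.data.loc["de", "g1|g2"] == 1
        assert de.data.loc["flat", "g1|g2"] == 0


class TestHousekeeping:
    def make(self, expr_rows, ternary_rows):
        genes = [f"g{i:03d}" for i in range(len(expr_rows))]
        expr = ExpressionTable(
            pd.DataFrame(expr_rows, index=genes,
                         columns=[f"s{i}" for i in range(len(expr_rows[0]))])
        )
        de = ternary_from_array(ternary_rows)
        return expr, de

    def test_robust_never_de_gene_included(self):
        expr, de = self.make([[12.0] * 3], [[0, 0, 0]])
        assert housekeeping_genes(expr, de) == {"g000"}

    def test_floor_violation_in_one_sample_excludes(self):
        expr, de = self.make([[12.0, 9.9, 12.0]], [[0, 0, 0]])
        assert housekeeping_genes(expr, de) == set()

    def test_single_de_call_excludes(self):
        expr, de = self.make([[12.0] * 3], [[0, 1, 0]])
        assert housekeeping_genes(expr, de) == set()

    def test_misaligned_universe_rejected(self):
        expr, de = self.make([[12.0] * 3], [[0, 0, 0], [0, 0, 0]])
        with pytest.raises(ValueError):
            housekeeping_genes(expr, de)

    def test_truth_recovery_on_noise_free_simulation(self):
        cfg = FamilySimConfig(n_families=50, noise_sigma=0.0, seed=11)
        truth, _, expr = simulate_dataset(cfg)
        de = call_pairwise_de(expr)
        hk = housekeeping_genes(expr, de)
        focal = truth.focal_genes()
        assert hk == set(focal[~focal["regulated"]]["gene"])


class TestRegulatedGenes:
    class FakeBC:
        def __init__(self, genes):
            self.genes = genes

    def test_union_semantics(self):
        a = self.FakeBC(list("abcde"))
        b = self.FakeBC(list("cdefg"))
        assert regulated_genes([a, b]) == set("abcdefg")
        assert regulated_genes([a, self.FakeBC(list("fghij"))]) == set("abcdefghij")
        assert regulated_genes([]) == set()


class TestWilcoxon:
    def test_exact_p_for_separated_triples(self):
        # {1,2,3} vs {10,11,12}: the most extreme of the 20 assignments on
        # both sides -> two-sided p = 2/20
        assert wilcoxon_ranksum_p([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_identical_multisets_give_p_one(self):
        assert wilcoxon_ranksum_p([1, 2, 2, 3], [1, 2, 2, 3]) == pytest.approx(1.0)

    @pytest.mark.parametrize("trial", range(40))
    def test_exact_p_equals_enumeration_with_ties(self, trial):
        rng = np.random.default_rng(trial)
        n1, n2 = rng.integers(1, 7, size=2)
        x = rng.integers(0, 4, n1).astype(float)
        y = rng.integers(0, 4, n2).astype(float)
        assert wilcoxon_ranksum_p(x, y) == pytest.approx(enumeration_ranksum_p(x, y), abs=1e-12)

    def test_large_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 1, 30)
        y = rng.normal(1, 1, 30)
        expected = st.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        assert wilcoxon_ranksum_p(x, y) == pytest.approx(expected)


class TestStageSpecificity:
    def test_identical_stage_distributions_give_one(self):
        vals = {"s0": [1, 2, 3], "s1": [1, 2, 3], "s2": [1, 2, 3]}
        groups = {"s0": "a", "s1": "b", "s2": "c"}
        assert stage_specificity_stat(vals, groups) == pytest.approx(1.0)

    def test_exact_smallest_p_for_separated_stages(self):
        vals = {"s0": [1, 2, 3], "s1": [10, 11, 12]}
        groups = {"s0": "a", "s1": "b"}
        assert stage_specificity_stat(vals, groups) == pytest.approx(0.1)

    def test_max_semantics_driven_by_identical_pair(self):
        vals = {"s0": [1, 2, 3], "s1": [100, 110, 120], "s2": [1, 2, 3]}
        groups = {"s0": "a", "s1": "b", "s2": "c"}
        assert stage_specificity_stat(vals, groups) == pytest.approx(1.0)

    def test_empty_stage_rejected(self):
        with pytest.raises(ValueError):
            stage_specificity_stat({"s0": [1.0]}, {"s0": "a"})


class TestSampleOverview:
    def test_duplicate_samples_correlate_and_merge_first(self):
        rng = np.random.default_rng(5)
        col = rng.uniform(1, 100, 30)
        df = pd.DataFrame(
            {"a": col, "b": col, "c": rng.uniform(1, 100, 30), "d": rng.uniform(1, 100, 30)},
            index=[f"g{i}" for i in range(30)],
        )
        expr = ExpressionTable(df)
        de = call_pairwise_de(expr)
        rep = sample_overview(expr, de)
        assert rep.spearman.loc["a", "b"] == pytest.approx(1.0)
        assert rep.de_counts.loc["a", "b"] == 0
        # first linkage merge joins the two identical samples
        first = sorted(rep.linkage[0, :2].astype(int))
        labels = list(rep.de_counts.index)
        assert {labels[first[0]], labels[first[1]]} == {"a", "b"}

    def test_variance_fractions_valid(self, expr_10_samples):
        de = call_pairwise_de(expr_10_samples)
        rep = sample_overview(expr_10_samples, de)
        fr = rep.pca_variance_fractions
        assert fr.sum() <= 1.0 + 1e-9
        assert (np.diff(fr) <= 1e-12).all()

    def test_three_sample_merge_order_from_hand_distances(self):
        # DE counts {(1,2):0, (1,3):4, (2,3):4} -> rows of the count matrix
        # put samples 1 and 2 at Euclidean distance 0: they merge first
        arr = np.zeros((4, 3), dtype=np.int8)
        arr[:, 1] = 1   # pair (s0, s2)
        arr[:, 2] = 1   # pair (s1, s2)
        de = ternary_from_array(arr, n_samples=3)
        rng = np.random.default_rng(0)
        expr = ExpressionTable(
            pd.DataFrame(rng.uniform(1, 10, (4, 3)),
                         index=[f"g{i:03d}" for i in range(4)], columns=["s0", "s1", "s2"])
        )
        rep = sample_overview(expr, de)
        assert rep.de_counts.loc["s0", "s1"] == 0
        assert rep.de_counts.loc["s0", "s2"] == 4
        first = sorted(rep.linkage[0, :2].astype(int))
        assert first == [0, 1]

    def test_constant_sample_flagged(self):
        df = pd.DataFrame(
            {"a": [1.0, 2.0, 3.0], "b": [2.0, 1.0, 5.0], "c": [7.0, 7.0, 7.0]},
            index=["g0", "g1", "g2"],
        )
        expr = ExpressionTable(df)
        de = call_pairwise_de(expr)
        rep = sample_overview(expr, de)
        assert rep.constant_samples == ["c"]
        assert np.isnan(rep.spearman.loc["c", "a"])
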