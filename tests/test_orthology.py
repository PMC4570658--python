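import numpy as np
import pandas as pd
import pytest

from devdup.formats import SimilarityGraph
from devdup.orthology import (
    CLASSES,
    OrthologyConfig,
    OrthologyModel,
    best_interspecies_scores,
    classify_genes,
    evaluate_against_curated,
    find_inparalogs,
    one_to_one_orthologs,
    paralog_components,
)
from devdup.synthio import FamilySimConfig, ScoreParams, simulate_dataset

CFG = OrthologyConfig(focal_species="Ppa", comparison_species="Cel", panel_species=("Cel",))


def graph(rows):
    """rows: (query, subject, evalue, bitscore); species from id prefix."""
    df = pd.DataFrame(rows, columns=["query", "subject", "evalue", "bitscore"])
    df["query_species"] = df["query"].str.split("-").str[0]
    df["subject_species"] = df["subject"].str.split("-").str[0]
    return SimilarityGraph(df)


class TestBestInterspeciesScores:
    def test_maximum_bitscore_selected(self):
        g = graph([("Ppa-a", "Cel-x", 1e-10, 120), ("Ppa-a", "Cel-y", 1e-30, 300)])
        best = best_interspecies_scores(g, CFG)
        assert best.loc["Ppa-a", "best_bitscore"] == 300
        assert best.loc["Ppa-a", "best_subject"] == "Cel-y"

    def test_gene_without_interspecies_hit_absent(self):
        g = graph([("Ppa-a", "Ppa-b", 1e-10, 120)])
        best = best_interspecies_scores(g, CFG)
        assert "Ppa-a" not in best.index

    def test_tie_broken_by_smaller_evalue(self):
        g = graph([("Ppa-a", "Cel-x", 1e-60, 250), ("Ppa-a", "Cel-y", 1e-80, 250)])
        best = best_interspecies_scores(g, CFG)
        assert best.loc["Ppa-a", "best_subject"] == "Cel-y"

    def test_evalue_threshold_applied(self):
        g = graph([("Ppa-a", "Cel-x", 0.5, 400)])
        best = best_interspecies_scores(g, CFG)
        assert "Ppa-a" not in best.index


class TestInparalogs:
    def test_intraspecies_hit_above_best_interspecies_flags(self):
        g = graph([("Ppa-a", "Cel-x", 1e-30, 250), ("Ppa-a", "Ppa-b", 1e-40, 300)])
        best = best_interspecies_scores(g, CFG)
        flagged, pairs = find_inparalogs(g, best, CFG)
        assert flagged == {"Ppa-a"}
        assert pairs == [("Ppa-a", "Ppa-b")]

    def test_weaker_intraspecies_hit_not_flagged(self):
        g = graph([("Ppa-a", "Cel-x", 1e-30, 250), ("Ppa-a", "Ppa-b", 1e-15, 200)])
        best = best_interspecies_scores(g, CFG)
        flagged, _ = find_inparalogs(g, best, CFG)
        assert flagged == set()

    def test_gene_without_interspecies_hit_never_flagged(self):
        g = graph([("Ppa-a", "Ppa-b", 1e-40, 300)])
        best = best_interspecies_scores(g, CFG)
        flagged, _ = find_inparalogs(g, best, CFG)
        assert flagged == set()

    def test_post_split_duplicate_flagged_on_simulation(self):
        cfg = FamilySimConfig(n_families=15, dup_rate_focal=1.0, dup_rate_other=0.0,
                              orphan_fraction=0.0, seed=6)
        truth, hits, _ = simulate_dataset(cfg, ScoreParams(noise=0.0))
        best = best_interspecies_scores(hits, CFG)
        flagged, _ = find_inparalogs(hits, best, CFG)
        focal = truth.focal_genes()
        multics = focal[focal.groupby("family")["gene"].transform("count") > 1]
        assert set(multics["gene"]) == flagged


class TestOneToOne:
    def setup_best(self, rows):
        g = graph(rows)
        bf = best_interspecies_scores(g, CFG, "Ppa")
        bc = best_interspecies_scores(g, CFG, "Cel")
        return g, bf, bc

    def test_mutual_best_no_inparalogs_reported(self):
        _, bf, bc = self.setup_best(
            [("Ppa-a", "Cel-x", 1e-50, 300), ("Cel-x", "Ppa-a", 1e-50, 300)]
        )
        assert one_to_one_orthologs(bf, bc, set(), set()) == [("Ppa-a", "Cel-x")]

    def test_inparalog_on_either_side_vetoes(self):
        _, bf, bc = self.setup_best(
            [("Ppa-a", "Cel-x", 1e-50, 300), ("Cel-x", "Ppa-a", 1e-50, 300)]
        )
        assert one_to_one_orthologs(bf, bc, {"Ppa-a"}, set()) == []
        assert one_to_one_orthologs(bf, bc, set(), {"Cel-x"}) == []

    def test_non_reciprocal_rejected(self):
        _, bf, bc = self.setup_best(
            [("Ppa-a", "Cel-x", 1e-50, 300),
             ("Cel-x", "Ppa-b", 1e-60, 320), ("Ppa-b", "Cel-x", 1e-60, 310)]
        )
        assert ("Ppa-a", "Cel-x") not in one_to_one_orthologs(bf, bc, set(), set())


class TestParalogComponents:
    def test_chain_forms_single_component(self):
        g = graph([("Ppa-a", "Ppa-b", 1e-10, 100), ("Ppa-b", "Ppa-c", 1e-10, 100)])
        comp = paralog_components(g, CFG)
        assert comp.loc["Ppa-a"] == comp.loc["Ppa-b"] == comp.loc["Ppa-c"]

    def test_isolated_gene_is_singleton(self):
        g = graph([("Ppa-a", "Ppa-b", 1e-10, 100)])
        comp = paralog_components(g, CFG, genes=["Ppa-a", "Ppa-b", "Ppa-z"])
        assert (comp == comp.loc["Ppa-z"]).sum() == 1

    def test_matches_adjacency_matrix_closure_on_random_graph(self):
        rng = np.random.default_rng(0)
        n = 50
        genes = [f"Ppa-g{i:02d}" for i in range(n)]
        adj = np.zeros((n, n), dtype=bool)
        rows = []
        for _ in range(60):
            i, j = rng.integers(0, n, 2)
            if i == j:
                continue
            adj[i, j] = adj[j, i] = True
            rows.append((genes[i], genes[j], 1e-10, 100.0))
        g = graph(rows)
        comp = paralog_components(g, CFG, genes=genes)
        # oracle: transitive closure by repeated boolean matrix squaring
        reach = adj | np.eye(n, dtype=bool)
        for _ in range(int(np.ceil(np.log2(n))) + 1):
            reach = reach | (reach @ reach)
        for i in range(n):
            for j in range(n):
                same = comp.loc[genes[i]] == comp.loc[genes[j]]
                assert same == bool(reach[i, j])

    def test_threshold_monotonicity(self):
        rows = [("Ppa-a", "Ppa-b", 1e-10, 100), ("Ppa-b", "Ppa-c", 1e-2, 30),
                ("Ppa-a", "Cel-x", 1e-10, 90)]
        g = graph(rows)
        loose = OrthologyConfig(evalue_threshold=1.0)
        tight = OrthologyConfig(evalue_threshold=1e-5)
        genes = ["Ppa-a", "Ppa-b", "Ppa-c"]
        comp_loose = paralog_components(g, loose, genes=genes)
        comp_tight = paralog_components(g, tight, genes=genes)
        size = lambda c: c.value_counts().max()
        assert size(comp_tight) <= size(comp_loose)


class TestClassify:
    def test_priority_assignment_rules(self):
        rows = [
            # m1: conserved multicopy trio (panel hits + intra-species edges)
            ("Ppa-m1", "Cel-h", 1e-20, 150), ("Ppa-m2", "Cel-h", 1e-20, 150),
            ("Ppa-m1", "Ppa-m2", 1e-40, 300), ("Ppa-m2", "Ppa-m3", 1e-40, 300),
            ("Ppa-m3", "Cel-h", 1e-20, 150),
            # s1: conserved singleton (panel hit, no paralogs, not reciprocal best)
            ("Ppa-s1", "Cel-h", 1e-10, 90),
            ("Cel-h", "Ppa-m1", 1e-20, 150),
        ]
        g = graph(rows)
        res = classify_genes(g, ["Ppa-m1", "Ppa-m2", "Ppa-m3", "Ppa-s1", "Ppa-lone"], CFG)
        assert res.calls.loc["Ppa-m1", "class"] == "conserved_multicopy"
        assert res.calls.loc["Ppa-s1", "class"] == "conserved_singleton"
        assert res.calls.loc["Ppa-lone", "class"] == "orphan_singleton"

    def test_noise_free_simulation_recovers_truth_exactly(self, noise_free_world):
        _, truth, hits, _ = noise_free_world
        res = OrthologyModel(hits, list(truth.focal_genes()["gene"]), CFG).fit()
        tr = truth.focal_genes().set_index("gene")["true_class"]
        assert (res.calls["class"] == tr.loc[res.calls.index]).all()
        assert res.class_counts().equals(truth.class_counts())

    def test_partition_invariant(self, noise_free_world):
        _, truth, hits, _ = noise_free_world
        res = OrthologyModel(hits, list(truth.focal_genes()["gene"]), CFG).fit()
        assert res.class_counts().sum() == len(truth.focal_genes())

    def test_one_to_one_symmetric_under_role_swap(self, noise_free_world):
        _, truth, hits, _ = noise_free_world
        res = OrthologyModel(hits, list(truth.focal_genes()["gene"]), CFG).fit()
        swapped = OrthologyConfig(focal_species="Cel", comparison_species="Ppa",
                                  panel_species=("Ppa",))
        other_genes = list(truth.genes[truth.genes["species"] == "Cel"]["gene"])
        res2 = OrthologyModel(hits, other_genes, swapped).fit()
        assert {(b, a) for a, b in res.one_to_one_pairs} == set(res2.one_to_one_pairs)

    def test_duplicate_universe_rejected(self):
        g = graph([("Ppa-a", "Cel-x", 1e-10, 100)])
        with pytest.raises(ValueError):
            OrthologyModel(g, ["Ppa-a", "Ppa-a"], CFG)


class TestCuratedEvaluation:
    def make_results(self, predicted_pairs, universe_extra=()):
        rows = [(a, b, 1e-50, 300.0) for a, b in predicted_pairs]
        rows += [(b, a, 1e-50, 300.0) for a, b in predicted_pairs]
        rows += [(g, "Ppa-pad", 1e-3, 60.0) for g in universe_extra]
        g = graph(rows)
        focal = sorted({a for a, _ in predicted_pairs} | {"Ppa-pad"})
        return OrthologyModel(g, focal, CFG).fit()

    def test_confusion_counts(self):
        # 5 curated positives of which 3 predicted, 4 negatives of which 1
        # wrongly predicted; one curated gene outside the hit universe
        pairs = [(f"Ppa-p{i}", f"Cel-p{i}") for i in range(3)] + [("Ppa-n0", "Cel-n0")]
        res = self.make_results(pairs, universe_extra=[f"Cel-p{i}" for i in (3, 4)]
                                + [f"Cel-n{i}" for i in (1, 2, 3)])
        curated = pd.DataFrame(
            {
                "gene": [f"Cel-p{i}" for i in range(5)]
                + [f"Cel-n{i}" for i in range(4)] + ["Cel-absent"],
                "has_one_to_one": [True] * 5 + [False] * 4 + [True],
            }
        )
        rep = evaluate_against_curated(res, curated)
        assert rep["true_positive"] == 3
        assert rep["false_negative"] == 2
        assert rep["false_positive"] == 1
        assert rep["true_negative"] == 3
        assert rep["unassessable"] == 1
        assert rep["agreement_positive"] == pytest.approx(3 / 5)

    def test_perfect_predictor_has_zero_off_diagonal(self, noise_free_world):
        _, truth, hits, _ = noise_free_world
        res = OrthologyModel(hits, list(truth.focal_genes()["gene"]), CFG).fit()
        other = truth.genes[truth.genes["species"] == "Cel"]
        fam_class = (
            truth.focal_genes().drop_duplicates("family").set_index("family")["true_class"]
        )
        curated = pd.DataFrame(
            {
                "gene": other["gene"],
                "has_one_to_one": [fam_class.get(f) == "one_to_one" for f in other["family"]],
            }
        )
        rep = evaluate_against_curated(res, curated)
        assert rep["false_positive"] == 0 and rep["false_negative"] == 0
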