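"""Enrichment scoring, consensus subtyping, labelling, DE and GSEA."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from somascape.immune import (
    consensus_kmeans,
    differential_expression,
    enrichment_scores,
    gsea_preranked,
    label_clusters,
    neutrophil_tcell_ratio,
)
from somascape.simulate import simulate_expression
from somascape.types import ExpressionMatrix, GeneSetCollection


@pytest.fixture(scope="module")
def archetype_cohort(immune_sets):
    sets, lymphoid, myeloid = immune_sets
    expr, labels = simulate_expression(2000, [10, 10, 10, 10], sets, 3.0, 0.5,
                                       seed=41)
    scores = enrichment_scores(expr, sets)
    return expr, labels, scores, sets, lymphoid, myeloid


class TestEnrichmentScores:
    def test_identical_samples_identical_scores(self, immune_sets):
        sets, _, _ = immune_sets
        rng = np.random.default_rng(0)
        col = rng.lognormal(3, 1, 2000)
        genes = [f"G{i + 1:05d}" for i in range(2000)]
        expr = ExpressionMatrix(pd.DataFrame(
            {"a": col, "b": col}, index=genes))
        scores = enrichment_scores(expr, sets)
        assert np.allclose(scores.loc["a"], scores.loc["b"])

    def test_top_set_scores_higher_than_bottom_set(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(500)]
        vals = np.sort(rng.lognormal(2, 1, 500))[::-1]
        expr = ExpressionMatrix(pd.DataFrame({"s1": vals, "s2": vals[::-1]},
                                             index=genes))
        sets = GeneSetCollection({"top": tuple(genes[:50]),
                                  "bottom": tuple(genes[-50:])})
        scores = enrichment_scores(expr, sets)
        assert scores.loc["s1", "top"] > scores.loc["s1", "bottom"]

    def test_gene_order_invariance(self, immune_sets):
        sets, _, _ = immune_sets
        expr, _ = simulate_expression(2000, [2, 2, 2, 2], sets, 1.0, 0.5, seed=2)
        shuffled = ExpressionMatrix(expr.values.sample(frac=1.0, random_state=3))
        a = enrichment_scores(expr, sets)
        b = enrichment_scores(shuffled, sets)
        pd.testing.assert_frame_equal(a, b)

    def test_no_overlap_set_rejected(self):
        expr = ExpressionMatrix(pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0]], index=["g1", "g2"], columns=["a", "b"]))
        with pytest.raises(ValueError):
            enrichment_scores(expr, GeneSetCollection({"x": ("absent",)}))


class TestConsensusKmeans:
    def test_two_point_masses(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1e-6, size=(10, 5)) + 0
        b = rng.normal(0, 1e-6, size=(10, 5)) + 10
        scores = pd.DataFrame(np.vstack([a, b]),
                              index=[f"s{i}" for i in range(20)])
        out = consensus_kmeans(scores, k_range=range(2, 5), n_perm=50, seed=5)
        assert out.k == 2
        assert out.stability == pytest.approx(1.0, abs=1e-9)
        lab = out.labels.to_numpy()
        assert len(set(lab[:10])) == 1 and len(set(lab[10:])) == 1

    def test_archetype_recovery(self, archetype_cohort):
        _, labels, scores, *_ = archetype_cohort
        out = consensus_kmeans(scores, n_perm=100, seed=6)
        assert out.k == 4
        assert adjusted_rand_score(labels, out.labels.to_numpy()) >= 0.9

    def test_sample_order_invariance(self, archetype_cohort):
        _, _, scores, *_ = archetype_cohort
        a = consensus_kmeans(scores, n_perm=50, seed=7)
        perm = scores.sample(frac=1.0, random_state=8)
        b = consensus_kmeans(perm, n_perm=50, seed=7)
        joined = pd.concat(
            [a.labels.rename("a"), b.labels.rename("b")], axis=1
        )
        assert adjusted_rand_score(joined["a"], joined["b"]) == pytest.approx(1.0)

    def test_k_range_too_large_rejected(self):
        scores = pd.DataFrame(np.eye(4))
        with pytest.raises(ValueError):
            consensus_kmeans(scores, k_range=range(2, 9), n_perm=10, seed=0)


class TestLabelClusters:
    def test_archetype_labels_match_planted_structure(self, archetype_cohort):
        _, labels, scores, _, lymphoid, myeloid = archetype_cohort
        out = consensus_kmeans(scores, n_perm=100, seed=9)
        out = label_clusters(scores, out, lymphoid, myeloid)
        sem = out.labels.map(out.cluster_labels)
        truth = pd.Series(labels, index=scores.index).map(
            {1: "hot", 2: "suppressed", 3: "moderate", 4: "cold"}
        )
        assert (sem == truth).mean() >= 0.9

    def test_fallback_labels_for_k_not_four(self):
        scores = pd.DataFrame(np.random.default_rng(10).normal(size=(12, 5)),
                              index=[f"s{i}" for i in range(12)])
        from somascape.immune import ClusterAssignment

        labels = pd.Series([1, 2, 3] * 4, index=scores.index)
        out = label_clusters(scores, ClusterAssignment(labels, 3, {}, 0.5), [], [])
        assert out.cluster_labels == {1: "C1", 2: "C2", 3: "C3"}


class TestNeutrophilTcellRatio:
    def test_equal_scores_give_unit_ratio(self):
        scores = pd.DataFrame(
            {"Neutrophils": [2.0], "T_cells_CD4": [1.0], "T_cells_CD8": [1.0]},
            index=["s1"],
        )
        assert neutrophil_tcell_ratio(scores).iloc[0] == pytest.approx(1.0)

    def test_myeloid_archetype_has_higher_ratio(self, archetype_cohort):
        _, labels, scores, *_ = archetype_cohort
        r = neutrophil_tcell_ratio(scores)
        suppressed = np.median(r.to_numpy()[labels == 2])
        moderate = np.median(r.to_numpy()[labels == 3])
        assert suppressed > moderate

    def test_zero_denominator_flagged(self):
        scores = pd.DataFrame(
            {"Neutrophils": [1.0], "T_cells_CD4": [0.0], "T_cells_CD8": [0.0]},
            index=["s1"],
        )
        assert np.isnan(neutrophil_tcell_ratio(scores).iloc[0])


class TestDifferentialExpression:
    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(11)
        block = rng.lognormal(2, 0.5, size=(200, 4))
        expr = ExpressionMatrix(pd.DataFrame(
            np.hstack([block, block]), index=[f"g{i}" for i in range(200)],
            columns=[f"s{i}" for i in range(8)]))
        labels = pd.Series([1] * 4 + [2] * 4, index=expr.samples)
        out = differential_expression(expr, labels, cluster=1)
        assert np.allclose(out["logFC"], 0.0)
        assert not out["significant"].any()

    def test_planted_fold_change_recovered(self):
        rng = np.random.default_rng(12)
        base = rng.lognormal(3, 0.3, size=(2000, 40))
        up = np.ones((2000, 1))
        up[:50] = 4.0
        vals = base * np.where(np.arange(40) < 20, up, 1.0)
        expr = ExpressionMatrix(pd.DataFrame(
            vals, index=[f"g{i}" for i in range(2000)],
            columns=[f"s{i}" for i in range(40)]))
        labels = pd.Series([1] * 20 + [2] * 20, index=expr.samples)
        out = differential_expression(expr, labels, cluster=1)
        hit = out.iloc[:50]["significant"].mean()
        assert hit >= 0.9

    def test_label_swap_flips_logfc(self):
        rng = np.random.default_rng(13)
        vals = rng.lognormal(2, 0.6, size=(100, 12))
        expr = ExpressionMatrix(pd.DataFrame(
            vals, index=[f"g{i}" for i in range(100)],
            columns=[f"s{i}" for i in range(12)]))
        labels = pd.Series([1] * 6 + [2] * 6, index=expr.samples)
        a = differential_expression(expr, labels, cluster=1)
        b = differential_expression(expr, labels, cluster=2)
        assert np.allclose(a["logFC"], -b["logFC"])
        assert np.allclose(a["p"], b["p"])

    def test_small_group_rejected(self):
        expr = ExpressionMatrix(pd.DataFrame(
            np.ones((10, 5)), index=[f"g{i}" for i in range(10)],
            columns=[f"s{i}" for i in range(5)]))
        labels = pd.Series([1, 1, 2, 2, 2], index=expr.samples)
        with pytest.raises(ValueError):
            differential_expression(expr, labels, cluster=1)


class TestGseaPreranked:
    def test_top_of_ranking_set_is_positive_and_significant(self):
        genes = [f"g{i}" for i in range(300)]
        ranking = pd.Series(np.linspace(3, -3, 300), index=genes)
        sets = GeneSetCollection({"top": tuple(genes[:25])})
        out = gsea_preranked(ranking, sets, n_perm=200, seed=14)
        assert out.loc["top", "ES"] > 0
        assert out.loc["top", "p"] <= 1 / (200 + 1) + 1e-12

    def test_reversed_ranking_flips_es_sign(self):
        genes = [f"g{i}" for i in range(200)]
        rng = np.random.default_rng(15)
        vals = rng.normal(size=200)
        ranking = pd.Series(vals, index=genes)
        sets = GeneSetCollection({"s": tuple(genes[:30])})
        a = gsea_preranked(ranking, sets, n_perm=100, seed=16)
        b = gsea_preranked(-ranking, sets, n_perm=100, seed=16)
        assert np.sign(a.loc["s", "ES"]) == -np.sign(b.loc["s", "ES"])

    def test_random_set_nes_near_one(self):
        genes = [f"g{i}" for i in range(400)]
        rng = np.random.default_rng(17)
        ranking = pd.Series(rng.normal(size=400), index=genes)
        sets = GeneSetCollection({
            f"r{j}": tuple(rng.choice(genes, 30, replace=False)) for j in range(10)
        })
        out = gsea_preranked(ranking, sets, n_perm=200, seed=18)
        assert 0.5 < out["NES"].abs().mean() < 1.6

    def test_duplicate_genes_rejected(self):
        ranking = pd.Series([1.0, 2.0], index=["g1", "g1"])
        with pytest.raises(ValueError):
            gsea_preranked(ranking, GeneSetCollection({"s": ("g1",)}), 10, 0)
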