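"""Downstream biology: gene ranking, preranked GSEA against a brute-force
running-sum oracle, contrast concordance, per-gene meta-analysis, and
cell-type specificity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from radsig.biology import (
    assign_cell_types,
    concordance_of_contrasts,
    gene_feature_meta,
    gsea_preranked,
    rank_genes,
    EnrichmentResult,
)
from radsig.io import ExpressionMatrix, GeneSetCollection


def brute_force_es(metric, in_set, weight_p):
    """Independent oracle: explicit loop over the running sum."""
    n = len(metric)
    nh = sum(in_set)
    wsum = sum(abs(m) ** weight_p for m, h in zip(metric, in_set) if h)
    if wsum == 0:  # degenerate all-zero weights: unweighted steps
        weight_p, wsum = 0.0, float(nh)
    run, best_pos, best_neg = 0.0, 0.0, 0.0
    for m, h in zip(metric, in_set):
        if h:
            run += abs(m) ** weight_p / wsum
        else:
            run -= 1.0 / (n - nh)
        best_pos = max(best_pos, run)
        best_neg = min(best_neg, run)
    # convention: on an exact |max| == |min| tie the positive extreme wins
    return best_pos if best_pos >= -best_neg else best_neg


class TestRankGenes:
    def test_constructed_direction_and_arithmetic(self):
        frame = pd.DataFrame(
            [[5.0, 6.0, 1.0, 2.0], [1.0, 1.5, 1.2, 1.1]],
            index=["up_in_1", "flat"], columns=list("abcd"),
        )
        expr = ExpressionMatrix(frame)
        r = rank_genes(expr, [1, 1, 0, 0])
        assert r.index[0] == "up_in_1" and r.iloc[0] > 0
        # hand-computed SMD for up_in_1: means 5.5 vs 1.5, pooled
        # variance ((1)(0.5)+(1)(0.5))/2 = 0.5 -> SMD = 4/sqrt(0.5)
        assert r.loc["up_in_1"] == pytest.approx(4.0 / np.sqrt(0.5), abs=1e-12)

    def test_permuted_labels_center_metric_at_zero(self):
        rng = np.random.default_rng(0)
        expr = ExpressionMatrix(pd.DataFrame(
            rng.normal(size=(300, 40)), index=[f"g{i}" for i in range(300)],
            columns=[f"s{i}" for i in range(40)]))
        r = rank_genes(expr, rng.permutation([1] * 20 + [0] * 20))
        # SMD under the null has mean 0 and SD ~ sqrt(4/n) ~ 0.32
        assert abs(r.mean()) < 3 * 0.32 / np.sqrt(300)

    def test_one_class_absent_rejected(self):
        expr = ExpressionMatrix(pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["a", "b"]))
        with pytest.raises(ValueError):
            rank_genes(expr, [1, 1])


class TestGseaPreranked:
    def _ranking(self, n=15):
        metric = np.linspace(2.0, -2.0, n)
        return pd.Series(metric, index=[f"g{i}" for i in range(n)])

    def test_top_k_set_positive_es_equals_brute_force(self):
        ranking = self._ranking(10)
        sets = GeneSetCollection({"top": [f"g{i}" for i in range(5)]})
        res = gsea_preranked(ranking, sets, n_perm=100, seed=0)[0]
        in_set = [g in sets["top"] for g in ranking.index]
        assert res.es == pytest.approx(brute_force_es(ranking.to_numpy(), in_set, 1.0), abs=1e-12)
        assert res.es > 0 and res.direction == "up_in_class1"

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_es_equals_exhaustive_running_sum_on_random_instances(self, data):
        n = data.draw(st.integers(8, 20))
        metric = data.draw(st.lists(
            st.floats(-3, 3, allow_nan=False), min_size=n, max_size=n))
        metric = sorted(metric, reverse=True)
        k = data.draw(st.integers(2, max(2, n // 2)))
        members = data.draw(st.permutations(range(n)))[:k]
        ranking = pd.Series(metric, index=[f"g{i}" for i in range(n)])
        sets = GeneSetCollection({"s": [f"g{i}" for i in sorted(members)]})
        res = gsea_preranked(ranking, sets, n_perm=10, seed=1, min_size=2)[0]
        in_set = [i in set(members) for i in range(n)]
        assert res.es == pytest.approx(brute_force_es(metric, in_set, 1.0), abs=1e-10)

    def test_weight_zero_complement_identity(self):
        """At weight_p=0 the statistic is the classic KS form and the
        complement set's ES is the mirror image."""
        ranking = self._ranking(12)
        members = ["g0", "g3", "g7", "g8", "g11"]
        comp = [g for g in ranking.index if g not in members]
        sets = GeneSetCollection({"s": members, "sbar": comp})
        res = {r.set_name: r for r in gsea_preranked(ranking, sets, weight_p=0.0,
                                                     n_perm=10, seed=2)}
        in_set = [g in members for g in ranking.index]
        # complement identity via the brute-force oracle at p=0
        es_s = brute_force_es(ranking.to_numpy(), in_set, 0.0)
        es_c = brute_force_es(ranking.to_numpy(), [not h for h in in_set], 0.0)
        assert res["s"].es == pytest.approx(es_s, abs=1e-12)
        assert res["sbar"].es == pytest.approx(es_c, abs=1e-12)
        # mirror-image extremes up to the step-grid asymmetry
        assert np.sign(res["s"].es) == -np.sign(res["sbar"].es)

    def test_set_absent_from_ranking_skipped(self, caplog):
        ranking = self._ranking(10)
        sets = GeneSetCollection({"ghost": ["x1", "x2", "x3", "x4", "x5"]})
        with caplog.at_level("WARNING", logger="radsig"):
            res = gsea_preranked(ranking, sets, n_perm=10, seed=0)
        assert res == []

    def test_determinism_given_seed(self):
        ranking = self._ranking(20)
        sets = GeneSetCollection({"a": [f"g{i}" for i in range(0, 20, 3)]})
        r1 = gsea_preranked(ranking, sets, n_perm=200, seed=9)
        r2 = gsea_preranked(ranking, sets, n_perm=200, seed=9)
        assert r1[0].es == r2[0].es and r1[0].p_value == r2[0].p_value
        assert r1[0].nes == r2[0].nes


class TestConcordance:
    def _res(self, name, es, fdr):
        return EnrichmentResult(name, es, es, 0.01, fdr,
                                "up_in_class1" if es >= 0 else "up_in_class0", [], 10)

    def test_identical_inputs_full_agreement(self):
        a = [self._res("h1", 0.5, 0.01), self._res("h2", -0.4, 0.02)]
        out = concordance_of_contrasts(a, a, fdr_cut=0.05)
        assert out["n_shared"] == 2 and out["sign_agreement"] == 1.0

    def test_disjoint_significant_sets(self):
        a = [self._res("h1", 0.5, 0.01), self._res("h2", 0.4, 0.9)]
        b = [self._res("h1", 0.5, 0.9), self._res("h2", 0.4, 0.01)]
        out = concordance_of_contrasts(a, b, fdr_cut=0.05)
        assert out["n_shared"] == 0
        assert out["a_only"] == ["h1"] and out["b_only"] == ["h2"]

    def test_planted_set_concordant_between_predicted_and_true_contrasts(self, small_study):
        """A model that predicts outcome well yields the same planted-set
        enrichment direction for predicted-status and true-status
        rankings."""
        _, study = small_study
        expr, samples, truth = study["validation"]
        y = samples.pcr_vector()
        # predicted status from the generating latent score (high AUC)
        pred = (truth.latent_score.reindex(expr.sample_ids) > 0).astype(int).to_numpy()
        sets = GeneSetCollection({"immune_up": truth.planted_up,
                                  "stromal_up": truth.planted_down})
        enrich_true = gsea_preranked(rank_genes(expr, y), sets, n_perm=200, seed=0)
        enrich_pred = gsea_preranked(rank_genes(expr, pred), sets, n_perm=200, seed=0)
        out = concordance_of_contrasts(enrich_true, enrich_pred, fdr_cut=0.25)
        assert "immune_up" in out["shared"] and "stromal_up" in out["shared"]
        assert out["sign_agreement"] == 1.0


class TestGeneFeatureMeta:
    def test_gene_tracking_feature_pooled_beta_one(self):
        rng = np.random.default_rng(1)
        exprs, scores = {}, {}
        for cohort in ("c1", "c2", "c3"):
            n = 60
            f = rng.normal(size=n)
            gene = f + rng.normal(0, 0.3, n)
            ids = [f"{cohort}_{i}" for i in range(n)]
            exprs[cohort] = ExpressionMatrix(pd.DataFrame([gene], index=["gX"], columns=ids))
            scores[cohort] = pd.DataFrame({"feat": f}, index=ids)
        res = gene_feature_meta(exprs, scores, ["gX"])[("gX", "feat")]
        assert res.pooled_beta == pytest.approx(1.0, abs=3 * res.pooled_se)
        assert res.i2 < 50

    def test_independent_gene_null_coverage(self):
        rng = np.random.default_rng(2)
        hits = 0
        reps = 40
        for _ in range(reps):
            exprs, scores = {}, {}
            for cohort in ("c1", "c2"):
                n = 50
                f = rng.normal(size=n)
                gene = rng.normal(size=n)
                ids = [f"{cohort}_{i}" for i in range(n)]
                exprs[cohort] = ExpressionMatrix(pd.DataFrame([gene], index=["gX"], columns=ids))
                scores[cohort] = pd.DataFrame({"feat": f}, index=ids)
            res = gene_feature_meta(exprs, scores, ["gX"])[("gX", "feat")]
            if abs(res.pooled_beta) < 2 * res.pooled_se:
                hits += 1
        assert hits >= 0.85 * reps  # ~95% nominal coverage

    def test_single_cohort_equals_per_cohort_estimate(self):
        rng = np.random.default_rng(3)
        n = 40
        f = rng.normal(size=n)
        gene = 2.0 * f + rng.normal(0, 0.5, n)
        ids = [f"s{i}" for i in range(n)]
        exprs = {"c1": ExpressionMatrix(pd.DataFrame([gene], index=["gX"], columns=ids))}
        scores = {"c1": pd.DataFrame({"feat": f}, index=ids)}
        res = gene_feature_meta(exprs, scores, ["gX"])[("gX", "feat")]
        # oracle: closed-form OLS slope
        beta = np.sum((f - f.mean()) * gene) / np.sum((f - f.mean()) ** 2)
        assert res.pooled_beta == pytest.approx(beta, abs=1e-12)
        assert res.q == 0.0

    def test_constant_feature_cohort_excluded(self, caplog):
        rng = np.random.default_rng(4)
        ids1 = [f"a{i}" for i in range(20)]
        ids2 = [f"b{i}" for i in range(20)]
        f = rng.normal(size=20)
        exprs = {
            "c1": ExpressionMatrix(pd.DataFrame([f + 0.1 * rng.normal(size=20)], index=["gX"], columns=ids1)),
            "c2": ExpressionMatrix(pd.DataFrame([rng.normal(size=20)], index=["gX"], columns=ids2)),
        }
        scores = {"c1": pd.DataFrame({"feat": f}, index=ids1),
                  "c2": pd.DataFrame({"feat": np.ones(20)}, index=ids2)}
        with caplog.at_level("WARNING", logger="radsig"):
            res = gene_feature_meta(exprs, scores, ["gX"])
        assert len(res[("gX", "feat")].betas) == 1  # only c1 contributes


class TestCellTypes:
    REF = pd.DataFrame(
        {"epithelial": [16.0, 4.0, 6.0], "leucocyte": [2.0, 4.0, 5.0],
         "endothelial": [2.0, 4.0, 5.5], "fibroblast": [2.0, 4.0, 3.0]},
        index=["specific", "uniform", "borderline"],
    )

    def test_specific_gene_assigned_with_fold_change(self):
        out = assign_cell_types(self.REF, ["specific"])[0]
        assert out.assigned == "epithelial" and out.fold_change == pytest.approx(8.0)

    def test_uniform_gene_none(self):
        assert assign_cell_types(self.REF, ["uniform"])[0].assigned == "none"

    def test_threshold_boundary_is_inclusive(self):
        ref = pd.DataFrame({"epithelial": [8.0], "leucocyte": [4.0],
                            "endothelial": [1.0], "fibroblast": [1.0]}, index=["g"])
        out = assign_cell_types(ref, ["g"], fc_threshold=2.0)[0]
        assert out.assigned == "epithelial" and out.fold_change == pytest.approx(2.0)

    def test_absent_gene_warned_none(self, caplog):
        with caplog.at_level("WARNING", logger="radsig"):
            out = assign_cell_types(self.REF, ["ghost"])[0]
        assert out.assigned == "none"
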