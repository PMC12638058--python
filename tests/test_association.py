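"""Null model, efficient-score test, candidate filter, sharing structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from gatescores import (GeneAnnotation, PipelineConfig, correlation_block_order,
                        filter_candidates, fit_null,
                        measured_feature_association, qtl_sharing_table,
                        score_test)
from gatescores.association import ScoreTestResult
from gatescores.gate_scores import GateScore

from conftest import make_cohort, make_locus, make_logistic_cohort


def _irls_logistic(y, C, tol=1e-10, maxit=100):
    """Independent reference IRLS fit of a logistic regression."""
    beta = np.zeros(C.shape[1])
    for _ in range(maxit):
        eta = C @ beta
        mu = 1 / (1 + np.exp(-eta))
        W = mu * (1 - mu)
        z = eta + (y - mu) / W
        new = np.linalg.solve((C * W[:, None]).T @ C, (C * W[:, None]).T @ z)
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta


class TestFitNull:
    def test_intercept_only_fit_is_case_fraction(self):
        y = np.r_[np.ones(30), np.zeros(70)].astype(int)
        cohort = make_cohort(np.zeros((100, 1)), phenotype=y)
        null = fit_null(cohort)
        np.testing.assert_allclose(null.mu, 0.3, atol=1e-8)

    def test_matches_reference_irls_fit(self):
        rng = np.random.default_rng(2)
        cohort, C = make_logistic_cohort(800, rng)
        null = fit_null(cohort)
        ref = _irls_logistic(cohort.phenotype.astype(float), C)
        np.testing.assert_allclose(null.coef, ref, atol=1e-6)

    def test_single_class_phenotype_rejected(self):
        cohort = make_cohort(np.zeros((20, 1)), phenotype=np.zeros(20, dtype=int))
        with pytest.raises(ValueError, match="single class"):
            fit_null(cohort)

    def test_rank_deficient_covariates_named(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(50)
        C = np.column_stack([np.ones(50), x, 2 * x])
        y = (rng.random(50) < 0.4).astype(int)
        cohort = make_cohort(np.zeros((50, 1)), phenotype=y, covariates=C)
        with pytest.raises(ValueError, match="c2"):
            fit_null(cohort)

    def test_exclusions_removed_before_fitting(self):
        y = np.r_[np.ones(10), np.zeros(10)].astype(int)
        cohort = make_cohort(np.zeros((20, 1)), phenotype=y,
                             exclusions={"S0", "S1"})
        null = fit_null(cohort)
        assert len(null.y) == 18 and "S0" not in null.sample_ids


class TestScoreTest:
    def test_score_in_covariate_span_is_untestable(self):
        rng = np.random.default_rng(4)
        cohort, C = make_logistic_cohort(500, rng)
        null = fit_null(cohort)
        res = score_test(C[:, 1], null, gene_id="G1")
        assert not res.testable and res.pval is None

    def test_null_scores_calibrated_and_uniform(self):
        """Type-I error and p-value uniformity under the null (small version
        of the full calibration run)."""
        rng = np.random.default_rng(6)
        cohort, _ = make_logistic_cohort(2000, rng)
        null = fit_null(cohort)
        pvals = np.array([
            score_test(rng.standard_normal(2000), null).pval
            for _ in range(400)])
        alpha = float(np.mean(pvals < 0.05))
        assert 0.02 <= alpha <= 0.09
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_beta_std_invariant_to_affine_score_rescaling(self):
        rng = np.random.default_rng(7)
        cohort, _ = make_logistic_cohort(1000, rng)
        null = fit_null(cohort)
        g = rng.standard_normal(1000)
        a = score_test(g, null)
        b = score_test(3.5 * g + 2.0, null)
        assert b.beta_std == pytest.approx(a.beta_std, rel=1e-9)
        assert b.pval == pytest.approx(a.pval, rel=1e-9)

    def test_power_monotone_in_effect_size(self):
        rng = np.random.default_rng(8)
        n, reps = 1500, 60
        rejections = []
        for gamma in (0.0, 0.1, 0.2, 0.3):
            rej = 0
            for _ in range(reps):
                g = rng.standard_normal(n)
                cohort, _ = make_logistic_cohort(n, rng, score_effect=gamma, score=g)
                null = fit_null(cohort)
                rej += score_test(g, null).pval < 0.05
            rejections.append(rej / reps)
        assert rejections == sorted(rejections)
        assert rejections[0] < 0.15 and rejections[-1] > 0.8

    def test_positive_effect_gives_positive_beta_std(self):
        rng = np.random.default_rng(9)
        g = rng.standard_normal(3000)
        cohort, _ = make_logistic_cohort(3000, rng, score_effect=0.5, score=g)
        null = fit_null(cohort)
        res = score_test(g, null)
        assert res.beta_std > 0 and res.pval < 1e-4

    def test_constant_score_rejected(self):
        rng = np.random.default_rng(10)
        cohort, _ = make_logistic_cohort(200, rng)
        null = fit_null(cohort)
        with pytest.raises(ValueError, match="zero variance"):
            score_test(np.ones(200), null)


def _res(gene_id, pval, eff, beta=0.05):
    return ScoreTestResult(gene_id=gene_id, score_type="trans", U=1, V=1,
                           z=1, pval=pval, beta=beta, beta_std=beta,
                           score_sd=1.0, n=100, effective_n=eff)


class TestFilterCandidates:
    @pytest.fixture
    def genes(self):
        return {
            "LEF1": GeneAnnotation("LEF1", "LEF1", "4", 108_050_000),
            "ANKRD55": GeneAnnotation("ANKRD55", "ANKRD55", "5", 56_100_000),
            "PDLIM7": GeneAnnotation("PDLIM7", "PDLIM7", "5", 177_480_000),
            "LOWDIV": GeneAnnotation("LOWDIV", "LOWDIV", "1", 1_000_000),
        }

    @pytest.fixture
    def hits(self):
        return pd.DataFrame({
            "chrom": ["5", "5"],
            "pos": [56_150_000, 177_400_000],  # within 200 kb of ANKRD55/PDLIM7
            "label": ["IL6ST", "RGS14"]})

    def test_filter_tiers(self, genes, hits, config):
        results = [
            _res("LEF1", 7e-7, 6.8, 0.057),     # primary tier, no nearby hit
            _res("ANKRD55", 8e-6, 7.6, 0.052),  # primary tier, hit also nearby
            _res("LOWDIV", 1e-8, 4.9),          # diversity gate fails
            _res("PDLIM7", 4e-5, 8.5, -0.050),  # relaxed tier via nearby hit
        ]
        table = filter_candidates(results, genes, hits, config).set_index("gene_id")
        assert table.loc["LEF1", "passed"] and table.loc["LEF1", "reason"] == "primary_p"
        assert table.loc["ANKRD55", "passed"] and table.loc["ANKRD55", "reason"] == "primary_p"
        assert not table.loc["LOWDIV", "passed"]
        assert table.loc["LOWDIV", "reason"] == "low_diversity"
        assert table.loc["PDLIM7", "passed"] and table.loc["PDLIM7", "reason"] == "gwas_hit_p"

    def test_relaxed_tier_requires_hit(self, genes, config):
        table = filter_candidates([_res("LEF1", 4e-5, 8.0)], genes, None, config)
        assert not table.iloc[0]["passed"] and table.iloc[0]["reason"] == "ns"

    def test_idempotent_and_order_independent(self, genes, hits, config):
        results = [_res("LEF1", 7e-7, 6.8), _res("PDLIM7", 4e-5, 8.5),
                   _res("ANKRD55", 8e-6, 7.6)]
        a = filter_candidates(results, genes, hits, config)
        b = filter_candidates(results[::-1], genes, hits, config)
        pd.testing.assert_frame_equal(a, b)

    def test_missing_gene_annotation_raises(self, config):
        with pytest.raises(KeyError):
            filter_candidates([_res("NOPE", 1e-9, 9.0)], {}, None, config)


def _gate(gene_id, values):
    return GateScore(gene_id=gene_id, values=np.asarray(values, float),
                     locus_variances=[1.0], effective_n=1.0)


class TestCorrelationBlockOrder:
    def test_identical_scores_form_one_group(self):
        v = np.random.default_rng(0).standard_normal(50)
        out = correlation_block_order([_gate("A", v), _gate("B", v.copy())])
        assert out.shared_groups == [{"A", "B"}]
        assert out.correlation.loc["A", "B"] == pytest.approx(1.0)

    def test_independent_scores_have_small_correlation(self):
        rng = np.random.default_rng(1)
        scores = [_gate(f"G{i}", rng.standard_normal(10_000)) for i in range(4)]
        out = correlation_block_order(scores)
        off = out.correlation.to_numpy()[~np.eye(4, dtype=bool)]
        assert np.max(np.abs(off)) < 0.1
        assert out.shared_groups == []

    def test_block_fixture_leaf_order_is_contiguous(self):
        rng = np.random.default_rng(2)
        n = 2000
        f1, f2 = rng.standard_normal(n), rng.standard_normal(n)
        scores = ([_gate(f"A{i}", f1 + 0.3 * rng.standard_normal(n)) for i in range(3)]
                  + [_gate(f"B{i}", f2 + 0.3 * rng.standard_normal(n)) for i in range(3)])
        out = correlation_block_order(scores)
        labels = ["".join(g[0] for g in out.gene_ids)]
        assert labels[0] in ("AAABBB", "BBBAAA")

    def test_constant_score_names_the_gene(self):
        with pytest.raises(ValueError, match="G1"):
            correlation_block_order([_gate("G1", np.ones(10)),
                                     _gate("G2", np.arange(10.0))])

    def test_requires_two_scores(self):
        with pytest.raises(ValueError):
            correlation_block_order([_gate("G1", np.arange(5.0))])


class TestQtlSharingTable:
    def _ann(self):
        return {"X": GeneAnnotation("X", "NEARBY", "9", 32_470_000),
                "A": GeneAnnotation("A", "A", "1", 1000),
                "B": GeneAnnotation("B", "B", "2", 1000)}

    def test_overlapping_intervals_merge(self):
        la = make_locus([32_430_000, 32_500_000], gene_id="A", chrom="9")
        lb = make_locus([32_450_000, 32_520_000], gene_id="B", chrom="9")
        t = qtl_sharing_table(["A", "B"], [la, lb], self._ann())
        assert len(t) == 1
        row = t.iloc[0]
        assert (row["start"], row["end"]) == (32_430_000, 32_520_000)
        assert row["target_genes"] == "A,B"
        assert row["genes_in_clump"] == "NEARBY"

    def test_non_overlapping_intervals_stay_separate(self):
        la = make_locus([1_000_000], gene_id="A", chrom="9")
        lb = make_locus([5_000_000], gene_id="B", chrom="9")
        t = qtl_sharing_table(["A", "B"], [la, lb], self._ann())
        assert len(t) == 2

    def test_chained_overlaps_merge_transitively(self):
        la = make_locus([100, 300], gene_id="A", chrom="9")
        lb = make_locus([250, 600], gene_id="B", chrom="9")
        lc = make_locus([550, 900], gene_id="A", chrom="9")
        t = qtl_sharing_table(["A", "B"], [la, lb, lc], self._ann())
        assert len(t) == 1
        assert (t.iloc[0]["start"], t.iloc[0]["end"]) == (100, 900)

    def test_cis_and_non_candidate_loci_ignored(self):
        la = make_locus([100], gene_id="A", chrom="9", locus_class="cis")
        lb = make_locus([100], gene_id="C", chrom="9")
        t = qtl_sharing_table(["A", "B"], [la, lb], self._ann())
        assert t.empty


class TestMeasuredFeatureAssociation:
    def test_feature_tracking_phenotype_has_positive_effect(self):
        rng = np.random.default_rng(11)
        cohort, _ = make_logistic_cohort(2000, rng)
        feature = cohort.phenotype + 0.5 * rng.standard_normal(2000)
        res = measured_feature_association(feature, cohort)
        assert res.beta_std > 0 and res.pval < 1e-6

    def test_null_feature_p_uniform(self):
        rng = np.random.default_rng(12)
        cohort, _ = make_logistic_cohort(1200, rng)
        pvals = [measured_feature_association(rng.standard_normal(1200), cohort).pval
                 for _ in range(120)]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_restricted_to_measured_subset_and_minimum(self):
        rng = np.random.default_rng(13)
        cohort, _ = make_logistic_cohort(300, rng)
        feature = rng.standard_normal(300)
        feature[60:] = np.nan
        res = measured_feature_association(feature, cohort)
        assert res.n == 60
        feature[40:] = np.nan
        with pytest.raises(ValueError, match="minimum"):
            measured_feature_association(feature, cohort)

    def test_r2_matches_squared_pearson(self):
        rng = np.random.default_rng(14)
        cohort, _ = make_logistic_cohort(500, rng)
        gate = rng.standard_normal(500)
        feature = 0.4 * gate + rng.standard_normal(500)
        res = measured_feature_association(feature, cohort, gate_values=gate)
        assert res.r2 == pytest.approx(np.corrcoef(gate, feature)[0, 1] ** 2)
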