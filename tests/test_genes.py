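"""Promoter mapping, correlation criteria, prioritization and context."""

import warnings

import numpy as np
import pandas as pd
import pytest

import epistab as es
from epistab.core_io import BetaMatrix
from epistab.destabilize import binarize, recurrence
from epistab.genes import (
    build_gene_records,
    context_enrichment,
    correlate_age_expr,
    correlate_meth_expr,
    map_promoter_esls,
    prioritize,
)
from epistab.simulate import simulate_probe_annotation


def _annotation(tss_distances, genes=None):
    probes = pd.Index([f"cg{i:03d}" for i in range(len(tss_distances))])
    ann = simulate_probe_annotation(probes, None, seed=0)
    ann["tss_distance"] = tss_distances
    if genes is not None:
        ann["nearest_gene"] = genes
    return ann


class TestPromoterMapping:
    def test_upstream_locus_mapped(self):
        ann = _annotation([-200], ["G1"])
        assert map_promoter_esls(ann.index, ann) == {"G1": ["cg000"]}

    def test_boundary_minus_1501_excluded(self):
        ann = _annotation([-1501, -1500, 1], ["G1", "G1", "G1"])
        assert map_promoter_esls(ann.index, ann) == {"G1": ["cg001"]}

    def test_symmetric_window_option(self):
        ann = _annotation([-1501, -1500, 1000, 1501], ["G1"] * 4)
        out = map_promoter_esls(ann.index, ann, upstream_bp=1500, downstream_bp=1500)
        assert out == {"G1": ["cg001", "cg002"]}

    def test_matches_interval_oracle(self):
        rng = np.random.default_rng(5)
        d = rng.integers(-4000, 4000, size=200)
        genes = [f"G{i % 20}" for i in range(200)]
        ann = _annotation(d, genes)
        out = map_promoter_esls(ann.index, ann)
        mapped = {p for ps in out.values() for p in ps}
        oracle = {ann.index[i] for i in range(200) if -1500 <= d[i] <= 0}
        assert mapped == oracle

    def test_missing_tss_distance_skipped(self):
        ann = _annotation([-200.0, np.nan], ["G1", "G1"])
        assert map_promoter_esls(ann.index, ann) == {"G1": ["cg000"]}


class TestCorrelations:
    def test_exact_negative_correlation(self):
        rng = np.random.default_rng(2)
        beta = rng.random(20)
        m = BetaMatrix(pd.DataFrame(
            [beta], index=["cg000"], columns=[f"s{i}" for i in range(20)]
        ))
        # expression exactly anti-linear in β on the log2 scale
        expr = pd.DataFrame(
            [2 ** (10.0 - 3.0 * beta) - 1.0],
            index=["G1"], columns=m.sample_ids,
        )
        out = correlate_meth_expr(m, expr, {"G1": ["cg000"]})
        assert out.loc["G1", "mean_r_meth"] == pytest.approx(-1.0)
        assert bool(out.loc["G1", "significant_negative"])

    def test_too_few_shared_samples_error(self):
        m = BetaMatrix(pd.DataFrame([[0.1, 0.2]], index=["cg000"],
                                    columns=["s1", "s2"]))
        expr = pd.DataFrame([[1.0, 2.0]], index=["G1"], columns=["s1", "s2"])
        with pytest.raises(ValueError, match="shared samples"):
            correlate_meth_expr(m, expr, {"G1": ["cg000"]})

    def test_mean_r_invariant_to_esl_order(self):
        rng = np.random.default_rng(3)
        m = BetaMatrix(pd.DataFrame(
            rng.random((3, 15)), index=["cgA", "cgB", "cgC"],
            columns=[f"s{i}" for i in range(15)],
        ))
        expr = pd.DataFrame(rng.random((1, 15)) * 10, index=["G1"],
                            columns=m.sample_ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r1 = correlate_meth_expr(m, expr, {"G1": ["cgA", "cgB", "cgC"]})
            r2 = correlate_meth_expr(m, expr, {"G1": ["cgC", "cgA", "cgB"]})
        assert r1.loc["G1", "mean_r_meth"] == pytest.approx(r2.loc["G1", "mean_r_meth"])

    def test_age_expression_strictly_decreasing(self):
        ages = pd.Series(np.linspace(20, 80, 10),
                         index=[f"s{i}" for i in range(10)])
        expr = pd.DataFrame(
            [2 ** (8.0 - 0.05 * ages.to_numpy()) - 1.0],
            index=["G1"], columns=ages.index,
        )
        out = correlate_age_expr(expr, ages)
        assert out.loc["G1", "r_age"] == pytest.approx(-1.0)
        assert out.loc["G1", "p_age_bonferroni"] < 0.05

    def test_null_correlations_calibrated(self):
        """Independent data: about 5% of genes significant before correction."""
        rng = np.random.default_rng(7)
        n_genes, n = 400, 60
        ages = pd.Series(rng.uniform(20, 80, n), index=[f"s{i}" for i in range(n)])
        expr = pd.DataFrame(rng.random((n_genes, n)) * 10,
                            index=[f"G{i}" for i in range(n_genes)],
                            columns=ages.index)
        out = correlate_age_expr(expr, ages)
        frac = float((out["p_age"] < 0.05).mean())
        assert abs(frac - 0.05) < 0.04

    def test_constant_expression_gene_skipped(self):
        ages = pd.Series([20.0, 40.0, 60.0], index=["s0", "s1", "s2"])
        expr = pd.DataFrame([[2.0, 2.0, 2.0]], index=["G1"], columns=ages.index)
        out = correlate_age_expr(expr, ages)
        assert np.isnan(out.loc["G1", "r_age"])


class TestPrioritize:
    def _records(self, **overrides):
        base = dict(
            mean_r_meth=-0.5, p_meth=0.001, n_esls=2, significant_negative=True,
            r_age=-0.4, p_age=0.001, p_age_bonferroni=0.001, mean_recurrence=0.2,
        )
        base.update(overrides)
        return pd.DataFrame([base], index=pd.Index(["G1"], name="gene"))

    def test_all_criteria_met_prioritized(self):
        out = prioritize(self._records())
        assert bool(out.loc["G1", "prioritized"])

    def test_failing_only_recurrence_excluded(self):
        out = prioritize(self._records(mean_recurrence=0.05))
        assert not bool(out.loc["G1", "prioritized"])

    def test_positive_age_correlation_excluded(self):
        out = prioritize(self._records(r_age=0.4))
        assert not bool(out.loc["G1", "prioritized"])

    def test_empty_input_empty_output(self):
        out = prioritize(pd.DataFrame())
        assert out.empty and "prioritized" in out.columns

    def test_planted_silencing_recovered_end_to_end(self):
        bm, expr, ages, ann, planted = es.simulate_expression_cohort(
            200, 20, 120, seed=15
        )
        bm0, _, _, _, _ = es.simulate_expression_cohort(200, 0, 100, seed=16)
        thr = es.calibrate_threshold([bm0], 99.9)
        rec = recurrence(binarize(bm, thr))
        gene_map = map_promoter_esls(bm.probe_ids, ann)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            meth = correlate_meth_expr(bm, expr, gene_map)
        age = correlate_age_expr(expr, ages)
        out = prioritize(build_gene_records(meth, age, rec["recurrence"], gene_map))
        selected = set(out.index[out["prioritized"]])
        tp = len(selected & set(planted))
        assert tp / max(len(selected), 1) >= 0.9
        assert tp / len(planted) >= 0.9


class TestContextEnrichment:
    def test_matches_cross_product_oracle(self):
        rng = np.random.default_rng(9)
        probes = pd.Index([f"cg{i:04d}" for i in range(800)])
        esl = probes[:200]
        ann = simulate_probe_annotation(probes, esl, seed=3,
                                        esl_island_prob=0.7,
                                        background_island_prob=0.2)
        res = context_enrichment(esl, ann)
        a, b, c, d = res.island_counts
        assert res.island_odds_ratio == pytest.approx((a * d) / (b * c))

    def test_planted_tenfold_enrichment_recovered(self):
        probes = pd.Index([f"cg{i:05d}" for i in range(6000)])
        esl = probes[:1000]
        # odds 0.69/0.31 vs 0.18/0.82 → planted OR ≈ 10
        ann = simulate_probe_annotation(probes, esl, seed=4,
                                        esl_island_prob=0.69,
                                        background_island_prob=0.18)
        res = context_enrichment(esl, ann)
        assert 7.0 < res.island_odds_ratio < 14.0
        assert res.island_p < 0.001

    def test_identical_rates_give_null_or(self):
        probes = pd.Index([f"cg{i:05d}" for i in range(4000)])
        esl = probes[:1000]
        ann = simulate_probe_annotation(probes, esl, seed=5,
                                        esl_island_prob=0.3,
                                        background_island_prob=0.3)
        res = context_enrichment(esl, ann)
        assert 0.75 < res.island_odds_ratio < 1.33
        assert res.island_p > 0.05

    def test_all_esls_in_window_fraction_one(self):
        ann = _annotation([-100, 50, 1500], ["G1"] * 3)
        res = context_enrichment(ann.index[:2], ann)
        assert res.tss_fraction == 1.0

    def test_empty_background_is_error(self):
        ann = _annotation([-100, 50], ["G1", "G1"])
        with pytest.raises(ValueError, match="background"):
            context_enrichment(ann.index, ann)
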