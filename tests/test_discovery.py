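"""Stable-locus discovery: filtering, variance ranking, selection, classes."""

import numpy as np
import pandas as pd
import pytest

import epistab as es
from epistab.core_io import BetaMatrix
from epistab.discovery import (
    classify_bimodal,
    filter_probes,
    filter_purified_outliers,
    rank_variance,
    select_stable,
)
from epistab.simulate import simulate_probe_annotation


def _annotation(probes, **flag_sets):
    ann = simulate_probe_annotation(pd.Index(probes), None, seed=0)
    for flag, subset in flag_sets.items():
        ann[flag] = ann.index.isin(subset)
    return ann


class TestFilterProbes:
    def test_flagged_probes_removed(self):
        probes = [f"cg{i}" for i in range(10)]
        ann = _annotation(probes, near_snp=probes[:4])
        assert len(filter_probes(ann, probes)) == 6

    def test_no_flags_is_identity(self):
        probes = [f"cg{i}" for i in range(5)]
        ann = _annotation(probes)
        assert list(filter_probes(ann, probes)) == probes

    def test_overlapping_flags_remove_union(self):
        probes = [f"cg{i}" for i in range(8)]
        ann = _annotation(probes, near_snp=probes[:3], age_associated=probes[2:5])
        retained = filter_probes(ann, probes, ["near_snp", "age_associated"])
        assert set(retained) == set(probes) - (set(probes[:3]) | set(probes[2:5]))

    def test_probe_missing_from_annotation_is_error(self):
        ann = _annotation(["cg0"])
        with pytest.raises(KeyError, match="cgX"):
            filter_probes(ann, ["cg0", "cgX"])


class TestRankVariance:
    def test_constant_probe_has_zero_variance_rank_one(self):
        m = BetaMatrix(pd.DataFrame(
            {"s1": [0.5, 0.1], "s2": [0.5, 0.9]}, index=["cgA", "cgB"]
        ))
        table = rank_variance(m)
        assert table.loc["cgA", "variance"] == 0.0
        assert table.loc["cgA", "rank"] == 1

    def test_two_point_sample_variance_is_half(self):
        """Unbiased variance of {0, 1} is 0.5 by the hand formula."""
        m = BetaMatrix(pd.DataFrame({"s1": [0.0], "s2": [1.0]}, index=["cgA"]))
        assert rank_variance(m).loc["cgA", "variance"] == pytest.approx(0.5)

    def test_sample_order_invariance(self, healthy_cohort):
        matrix, _, _ = healthy_cohort
        shuffled = BetaMatrix(matrix.values.iloc[:, ::-1])
        v1 = rank_variance(matrix)["variance"]
        v2 = rank_variance(shuffled)["variance"]
        assert np.allclose(v1.sort_index(), v2.sort_index())

    def test_ties_ranked_lexicographically(self):
        m = BetaMatrix(pd.DataFrame(
            {"s1": [0.1, 0.1, 0.1], "s2": [0.1, 0.1, 0.1]},
            index=["cgC", "cgA", "cgB"],
        ))
        assert list(rank_variance(m).index) == ["cgA", "cgB", "cgC"]

    def test_probe_with_single_observation_excluded_with_warning(self):
        m = BetaMatrix(pd.DataFrame(
            {"s1": [0.1, 0.3], "s2": [0.2, np.nan]}, index=["cgA", "cgB"]
        ))
        with pytest.warns(UserWarning, match="<2 observations"):
            table = rank_variance(m)
        assert "cgB" not in table.index


class TestSelectStable:
    def test_ten_percent_of_hundred(self):
        table = pd.DataFrame(
            {"variance": np.linspace(0, 1, 100)},
            index=[f"cg{i:03d}" for i in range(100)],
        )
        assert len(select_stable(table, 0.10)) == 10

    def test_floor_rule(self):
        table = pd.DataFrame(
            {"variance": np.linspace(0, 1, 10_005)},
            index=[f"cg{i:05d}" for i in range(10_005)],
        )
        assert len(select_stable(table, 0.10)) == 1000

    def test_fraction_bounds(self):
        table = pd.DataFrame({"variance": [0.1]}, index=["cgA"])
        for bad in (0.0, 1.0, -0.5, 2.0):
            with pytest.raises(ValueError):
                select_stable(table, bad)


class TestPurifiedOutliers:
    def _candidates(self):
        probes = pd.Index(["cgA", "cgB"])
        means = pd.Series([0.02, 0.03], index=probes)
        return probes, means

    def test_clean_low_pole_candidate_retained(self):
        probes, means = self._candidates()
        pure = {"monocytes": BetaMatrix(pd.DataFrame(
            [[0.01, 0.03], [0.02, 0.02]], index=probes, columns=["p1", "p2"]
        ))}
        kept = filter_purified_outliers(probes, means, pure)
        assert list(kept) == list(probes)

    def test_single_outlier_sample_removes_candidate(self):
        probes, means = self._candidates()
        pure = {"monocytes": BetaMatrix(pd.DataFrame(
            [[0.01, 0.6], [0.02, 0.02]], index=probes, columns=["p1", "p2"]
        ))}
        kept = filter_purified_outliers(probes, means, pure)
        assert list(kept) == ["cgB"]

    def test_high_pole_uses_floor(self):
        probes = pd.Index(["cgH"])
        means = pd.Series([0.97], index=probes)
        pure = {"tcells": BetaMatrix(pd.DataFrame(
            [[0.95, 0.4]], index=probes, columns=["p1", "p2"]
        ))}
        assert len(filter_purified_outliers(probes, means, pure)) == 0

    def test_no_purified_data_skips_filter(self, caplog):
        probes, means = self._candidates()
        import logging

        with caplog.at_level(logging.INFO, logger="epistab.discovery"):
            kept = filter_purified_outliers(probes, means, None)
        assert list(kept) == list(probes)
        assert any("skipped" in r.message for r in caplog.records)

    def test_planted_aberrant_cell_type_removed(self):
        """Probes given one aberrant purified sample are exactly the removals."""
        rng = np.random.default_rng(0)
        probes = pd.Index([f"cg{i:03d}" for i in range(100)])
        means = pd.Series(0.02, index=probes)
        vals = rng.beta(2, 98, size=(100, 10))
        bad = rng.choice(100, size=5, replace=False)
        vals[bad, 0] = 0.5
        pure = {"bcells": BetaMatrix(pd.DataFrame(
            vals, index=probes, columns=[f"p{i}" for i in range(10)]
        ))}
        kept = filter_purified_outliers(probes, means, pure)
        assert set(probes) - set(kept) == set(probes[bad])


class TestClassifyBimodal:
    def _vtable(self, means):
        return pd.DataFrame(
            {"mean_beta": means, "variance": 0.001},
            index=[f"cg{i}" for i in range(len(means))],
        )

    def test_pole_means_classified(self):
        table = classify_bimodal(self._vtable([0.02, 0.97]), pd.Index(["cg0", "cg1"]))
        assert table.loc["cg0", "esl_class"] == "unmethylated"
        assert table.loc["cg1", "esl_class"] == "methylated"

    def test_intermediate_mean_excluded_with_warning(self):
        vt = self._vtable([0.02, 0.5, 0.97])
        with pytest.warns(UserWarning, match="intermediate"):
            table = classify_bimodal(vt, vt.index)
        assert "cg1" not in table.index

    def test_empty_stable_set_is_error(self):
        with pytest.raises(ValueError):
            classify_bimodal(self._vtable([0.5]), pd.Index([]))


class TestPipeline:
    def test_planted_recovery_and_class_labels(self, healthy_cohort, esl_table):
        _, _, truth = healthy_cohort
        found = set(esl_table.index)
        planted = set(truth.stable)
        precision = len(found & planted) / len(found)
        recall = len(found & planted) / len(planted)
        assert precision >= 0.95 and recall >= 0.95
        unmeth = set(esl_table.index[esl_table["esl_class"] == "unmethylated"])
        assert unmeth == found & set(truth.stable_low)

    def test_pipeline_deterministic(self, healthy_cohort, esl_table):
        matrix, _, _ = healthy_cohort
        again = es.discover_esls(matrix, fraction=0.10)
        pd.testing.assert_frame_equal(esl_table, again)

    def test_no_blocklisted_probe_selected(self, healthy_cohort):
        matrix, _, _ = healthy_cohort
        ann = simulate_probe_annotation(matrix.probe_ids, None, seed=5,
                                        flag_fraction=0.05)
        esl = es.discover_esls(matrix, annotation=ann, fraction=0.10)
        flags = ann.loc[esl.index, list(es.core_io.BLOCKLIST_FLAGS)]
        assert not flags.any(axis=None)

    def test_bimodality_gap_reported(self, esl_table):
        assert esl_table.attrs["unmethylated_max_mean"] < 0.2
        assert esl_table.attrs["methylated_min_mean"] > 0.8
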