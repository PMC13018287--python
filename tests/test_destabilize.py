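"""Threshold calibration, binarization and recurrence statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import epistab as es
from epistab.core_io import BetaMatrix
from epistab.destabilize import (
    binarize,
    calibrate_threshold,
    conditional_mean_beta,
    recurrence,
    recurrence_beta_correlation,
)


def _single_sample_cohort(values):
    """A one-sample matrix whose per-locus means equal ``values`` exactly."""
    return BetaMatrix(pd.DataFrame(
        {"s1": values}, index=[f"cg{i:04d}" for i in range(len(values))]
    ))


def _percentile_oracle(values, q):
    """Brute-force sort + linear interpolation between order statistics."""
    x = np.sort(np.asarray(values, dtype=float))
    h = (len(x) - 1) * (q / 100.0)
    lo = int(np.floor(h))
    hi = min(lo + 1, len(x) - 1)
    return x[lo] + (h - lo) * (x[hi] - x[lo])


class TestCalibrate:
    def test_all_equal_pool_gives_that_value(self):
        cohort = _single_sample_cohort([0.03] * 50)
        assert calibrate_threshold([cohort]) == pytest.approx(0.03)

    def test_hundred_point_grid_matches_interpolation_oracle(self):
        values = np.arange(1, 101) / 100.0
        cohort = _single_sample_cohort(values)
        expected = _percentile_oracle(values, 99.9)
        assert calibrate_threshold([cohort], 99.9) == pytest.approx(expected, abs=1e-15)

    def test_single_locus_single_cohort_degenerate(self):
        assert calibrate_threshold([_single_sample_cohort([0.042])]) == pytest.approx(0.042)

    def test_high_pole_uses_mirrored_percentile(self):
        values = np.arange(1, 101) / 100.0
        cohort = _single_sample_cohort(values)
        expected = _percentile_oracle(values, 0.1)
        assert calibrate_threshold([cohort], 99.9, pole="high") == pytest.approx(expected)

    def test_cohort_and_sample_order_invariance(self, unmeth_probes):
        cfg = es.SimulationConfig(n_probes=2000, n_samples=50)
        c1 = es.simulate_cohort(cfg, seed=41)[0].select_probes(unmeth_probes)
        c2 = es.simulate_cohort(cfg, seed=42)[0].select_probes(unmeth_probes)
        t_ab = calibrate_threshold([c1, c2])
        t_ba = calibrate_threshold([c2, c1])
        assert t_ab == t_ba  # same pooled multiset, exactly
        shuffled = BetaMatrix(c1.values.iloc[:, ::-1])
        t_shuf = calibrate_threshold([shuffled, c2])
        # per-locus means are re-summed in a different order: equal to
        # floating-point rounding
        assert t_shuf == pytest.approx(t_ab, rel=1e-12)

    def test_percentile_bounds(self):
        cohort = _single_sample_cohort([0.1])
        for bad in (0.0, 100.0, -1.0):
            with pytest.raises(ValueError):
                calibrate_threshold([cohort], bad)

    def test_defining_property_on_calibration_cohorts(self, unmeth_probes, threshold):
        """Pooled calibration means exceed the 99.9th-percentile threshold at
        a rate of about 0.1% by construction."""
        cfg = es.SimulationConfig(n_probes=2000, n_samples=100)
        pooled = np.concatenate([
            es.simulate_cohort(cfg, seed=s)[0]
            .select_probes(unmeth_probes).values.mean(axis=1).to_numpy()
            for s in (21, 22, 23)
        ])
        rate = float((pooled > threshold).mean())
        assert rate <= 2 / len(pooled) + 0.001


class TestBinarize:
    def test_value_at_threshold_is_not_a_call(self):
        m = BetaMatrix(pd.DataFrame({"s1": [0.05932]}, index=["cgA"]))
        calls = binarize(m, 0.05932)
        assert calls.loc["cgA", "s1"] == 0.0

    def test_value_above_published_style_threshold_is_called(self):
        m = BetaMatrix(pd.DataFrame({"s1": [0.06]}, index=["cgA"]))
        assert binarize(m, 0.05932).loc["cgA", "s1"] == 1.0

    def test_high_pole_calls_below_threshold(self):
        m = BetaMatrix(pd.DataFrame({"s1": [0.7, 0.9]}, index=["cgA", "cgB"]))
        calls = binarize(m, 0.8321, pole="high")
        assert calls.loc["cgA", "s1"] == 1.0
        assert calls.loc["cgB", "s1"] == 0.0

    def test_missing_beta_gives_missing_call(self):
        m = BetaMatrix(pd.DataFrame({"s1": [np.nan]}, index=["cgA"]))
        assert binarize(m, 0.05).isna().all(axis=None)

    def test_mismatched_threshold_warns(self):
        m = BetaMatrix(pd.DataFrame({"s1": [0.1]}, index=["cgA"]))
        with pytest.warns(UserWarning, match="mismatched"):
            binarize(m, 0.8, pole="low")

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.floats(0.01, 0.49))
    def test_matches_elementwise_oracle(self, seed, thr):
        rng = np.random.default_rng(seed)
        vals = rng.random((8, 5))
        m = BetaMatrix(pd.DataFrame(
            vals, index=[f"cg{i}" for i in range(8)],
            columns=[f"s{j}" for j in range(5)],
        ))
        calls = binarize(m, thr).to_numpy()
        for i in range(8):
            for j in range(5):
                assert calls[i, j] == float(vals[i, j] > thr)


class TestRecurrence:
    def _calls(self, rows):
        return pd.DataFrame(
            rows, index=[f"cg{i}" for i in range(len(rows))], dtype=float
        )

    def test_one_of_four_is_recurrent(self):
        rec = recurrence(self._calls([[1, 0, 0, 0]]))
        assert rec.loc["cg0", "recurrence"] == pytest.approx(0.25)
        assert rec.loc["cg0", "recurrence_class"] == "recurrent"

    def test_one_of_thirty_is_low(self):
        rec = recurrence(self._calls([[1] + [0] * 29]))
        assert rec.loc["cg0", "recurrence"] == pytest.approx(1 / 30)
        assert rec.loc["cg0", "recurrence_class"] == "low"

    def test_exactly_five_percent_is_recurrent(self):
        """The class boundary is inclusive: perturbed in 5% or more."""
        rec = recurrence(self._calls([[1] * 5 + [0] * 95]))
        assert rec.loc["cg0", "recurrence_class"] == "recurrent"

    def test_missing_calls_excluded_from_both_sides(self):
        rec = recurrence(self._calls([[1, 0, np.nan, np.nan]]))
        assert rec.loc["cg0", "recurrence"] == pytest.approx(0.5)
        assert rec.loc["cg0", "n_obs"] == 2

    def test_monotone_in_added_perturbed_sample(self):
        base = self._calls([[1, 0, 0], [0, 0, 0]])
        extended = base.copy()
        extended["s_new"] = [1.0, 1.0]
        r0 = recurrence(base)["recurrence"]
        r1 = recurrence(extended)["recurrence"]
        assert (r1 >= r0).all()


class TestConditionalMean:
    def test_mean_over_perturbed_only(self):
        m = BetaMatrix(pd.DataFrame({"s1": [0.3], "s2": [0.01]}, index=["cgA"]))
        calls = pd.DataFrame({"s1": [1.0], "s2": [0.0]}, index=["cgA"])
        assert conditional_mean_beta(m, calls).loc["cgA"] == pytest.approx(0.3)

    def test_no_perturbed_samples_is_missing(self):
        m = BetaMatrix(pd.DataFrame({"s1": [0.3]}, index=["cgA"]))
        calls = pd.DataFrame({"s1": [0.0]}, index=["cgA"])
        assert np.isnan(conditional_mean_beta(m, calls).loc["cgA"])

    def test_matches_masked_mean_oracle(self):
        rng = np.random.default_rng(17)
        vals = rng.random((20, 12))
        calls_arr = rng.choice([0.0, 1.0, np.nan], size=(20, 12))
        idx = [f"cg{i}" for i in range(20)]
        cols = [f"s{j}" for j in range(12)]
        m = BetaMatrix(pd.DataFrame(vals, index=idx, columns=cols))
        calls = pd.DataFrame(calls_arr, index=idx, columns=cols)
        result = conditional_mean_beta(m, calls)
        for i in range(20):
            mask = calls_arr[i] == 1.0
            expected = vals[i][mask].mean() if mask.any() else np.nan
            if np.isnan(expected):
                assert np.isnan(result.iloc[i])
            else:
                assert result.iloc[i] == pytest.approx(expected)


class TestRecurrenceBetaCorrelation:
    def test_perfectly_linear_pairs(self):
        rec = pd.Series([0.1, 0.2, 0.3, 0.4])
        cmb = pd.Series([0.2, 0.4, 0.6, 0.8])
        r, _ = recurrence_beta_correlation(rec, cmb)
        assert r == pytest.approx(1.0)

    def test_anti_linear_pairs(self):
        rec = pd.Series([0.1, 0.2, 0.3])
        cmb = pd.Series([0.9, 0.5, 0.1])
        r, _ = recurrence_beta_correlation(rec, cmb)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            recurrence_beta_correlation(
                pd.Series([0.1, 0.1, 0.1]), pd.Series([0.2, 0.3, 0.4])
            )

    def test_coupled_simulation_gives_strong_positive_r(
        self, cancer_cohort, unmeth_probes, threshold
    ):
        """With perturbation penetrance coupled to clone fraction, recurrent
        loci carry higher methylation among affected samples."""
        matrix, _, _ = cancer_cohort
        sub = matrix.select_probes(unmeth_probes)
        calls = binarize(sub, threshold)
        rec = recurrence(calls)
        cmb = conditional_mean_beta(sub, calls)
        r, p = recurrence_beta_correlation(rec["recurrence"], cmb)
        assert r > 0.5
        assert p < 0.001
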