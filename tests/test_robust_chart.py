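"""MRCD fit, T² statistic, control-limit calibration and run rules."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from cfocr import (apply_run_rules, calibrate_limits, filter_training_set,
                   fit_classical, fit_mrcd, t2_statistic)
from cfocr.robust_chart import ChartCalibration


class TestFitMRCD:
    def test_clean_gaussian_recovery(self):
        """Monte-Carlo sanity bounds at n=500, p=4 (bounds frozen from
        simulation of this estimator)."""
        X = np.random.default_rng(0).standard_normal((500, 4))
        m = fit_mrcd(X)
        assert np.abs(m.location).max() < 0.15
        assert np.linalg.norm(m.scatter - np.eye(4)) < 0.45

    def test_robust_to_gross_outliers(self):
        """20% outliers at +10 sigma barely move the robust location
        while the classical mean is dragged far away."""
        X = np.random.default_rng(1).standard_normal((500, 4))
        X[:100] += 10.0
        m = fit_mrcd(X)
        assert np.abs(m.location).max() < 0.2
        assert np.abs(X.mean(axis=0)).max() > 1.0

    def test_scatter_scale_equivariance(self):
        X = np.random.default_rng(2).standard_normal((300, 4))
        m1, m2 = fit_mrcd(X), fit_mrcd(2.0 * X)
        np.testing.assert_allclose(m2.scatter, 4.0 * m1.scatter, rtol=1e-10)
        np.testing.assert_allclose(m2.location, 2.0 * m1.location, rtol=1e-8, atol=1e-12)

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            fit_mrcd(np.ones((3, 4)))  # n <= p
        with pytest.raises(ValueError):
            fit_mrcd(np.ones((50, 4)))  # identical rows

    def test_reduces_to_classical_without_trimming(self):
        """MRCD with vanishing trim and regularization equals the
        classical estimate (tol 1e-8)."""
        X = np.random.default_rng(3).standard_normal((200, 4))
        m = fit_mrcd(X, alpha_trim=0.0, rho=0.0)
        mean, cov = fit_classical(X)
        np.testing.assert_allclose(m.location, mean, atol=1e-8)
        np.testing.assert_allclose(m.scatter, cov, atol=1e-8)

    def test_cross_check_against_sklearn_mcd(self):
        """Independent oracle: on contaminated data both robust
        estimators land near the clean center while differing in detail."""
        from sklearn.covariance import MinCovDet

        rng = np.random.default_rng(4)
        X = rng.standard_normal((400, 4))
        X[:80] += 8.0
        ours = fit_mrcd(X).location
        theirs = MinCovDet(random_state=0).fit(X).location_
        assert np.abs(ours - theirs).max() < 0.3


class TestT2Statistic:
    def test_zero_at_location(self):
        X = np.random.default_rng(0).standard_normal((100, 4))
        m = fit_mrcd(X)
        assert t2_statistic(m, m.location) == pytest.approx(0.0, abs=1e-12)

    def test_identity_scatter_sum_of_squares(self):
        assert t2_statistic((np.zeros(4), np.eye(4)), np.ones(4)) == pytest.approx(4.0)

    def test_matches_solve_oracle(self, rng):
        mean = rng.normal(size=4)
        A = rng.normal(size=(4, 4))
        cov = A @ A.T + 4 * np.eye(4)
        x = rng.normal(size=4)
        expected = (x - mean) @ np.linalg.solve(cov, x - mean)
        assert t2_statistic((mean, cov), x) == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            t2_statistic((np.zeros(4), np.eye(4)), np.ones(3))


class TestCalibrateLimits:
    def test_classical_large_n_approaches_chi2_limit(self):
        """With known-parameter asymptotics the 5% limit of a 4-variate
        T² chart is the chi-square quantile 9.488."""
        cal = calibrate_limits(4, 3000, alpha=0.05, n_mc=300, seed=1, robust=False)
        assert cal.ucl == pytest.approx(sps.chi2.ppf(0.95, 4), rel=0.05)

    def test_alpha_half_gives_scaled_median(self):
        cal = calibrate_limits(4, 400, alpha=0.5, n_mc=200, seed=2)
        if np.isinf(cal.q_hat):
            expected = cal.d_hat * sps.chi2.ppf(0.5, 4) / 4
        else:
            expected = cal.d_hat * sps.f.ppf(0.5, 4, cal.q_hat)
        assert cal.ucl == pytest.approx(expected)

    def test_deterministic_given_seed(self):
        a = calibrate_limits(4, 200, n_mc=200, seed=5)
        b = calibrate_limits(4, 200, n_mc=200, seed=5)
        assert (a.d_hat, a.q_hat, a.ucl) == (b.d_hat, b.q_hat, b.ucl)

    def test_validation(self):
        with pytest.raises(ValueError):
            calibrate_limits(4, 200, n_mc=50, seed=1)
        with pytest.raises(ValueError):
            calibrate_limits(4, 200, alpha=1.5, n_mc=200, seed=1)
        with pytest.raises(ValueError):
            ChartCalibration(d_hat=1.0, q_hat=3.0, ucl=1.0, alpha=0.05,
                             p=4, n=100, n_mc=200)

    def test_json_round_trip(self, tmp_path):
        cal = calibrate_limits(4, 200, n_mc=200, seed=7)
        cal.to_json(tmp_path / "cal.json")
        back = ChartCalibration.from_json(tmp_path / "cal.json")
        assert back.ucl == cal.ucl and back.q_hat == cal.q_hat


class TestRunRules:
    def test_rule1_three_consecutive(self):
        stats = np.zeros(100)
        stats[[10, 11, 12]] = 5.0
        calls = apply_run_rules(stats, ucl=1.0)
        assert len(calls) == 1
        c = calls[0]
        assert (c.start_idx, c.end_idx) == (10, 12) and c.rules == {1}

    def test_rule2_boundary_call_spans_600bp(self):
        stats = np.zeros(100)
        stats[0] = 5.0
        calls = apply_run_rules(stats, ucl=1.0, window_bp=200)
        assert len(calls) == 1
        assert calls[0].rules == {2}
        assert calls[0].span_bp == 600

    def test_rule2_last_point(self):
        stats = np.zeros(50)
        stats[-1] = 9.0
        calls = apply_run_rules(stats, ucl=1.0)
        assert calls[0].start_idx == 47 and calls[0].end_idx == 49

    def test_rule3_merges_short_gap(self):
        stats = np.zeros(100)
        stats[[10, 11, 14, 15]] = 5.0  # two points between the runs
        calls = apply_run_rules(stats, ucl=1.0)
        assert len(calls) == 1
        c = calls[0]
        assert (c.start_idx, c.end_idx) == (10, 15) and 3 in c.rules

    def test_three_point_gap_not_merged_no_call(self):
        stats = np.zeros(100)
        stats[[10, 11, 15, 16]] = 5.0  # three points between
        assert apply_run_rules(stats, ucl=1.0) == []

    def test_empty_stats_raise(self):
        with pytest.raises(ValueError):
            apply_run_rules([], ucl=1.0)

    @given(st.integers(0, 100), st.floats(0.1, 10.0))
    def test_invariant_under_joint_positive_scaling(self, seed, factor):
        stats = np.random.default_rng(seed).exponential(1.0, 80)
        a = apply_run_rules(stats, ucl=1.5)
        b = apply_run_rules(stats * factor, ucl=1.5 * factor)
        assert [(c.start_idx, c.end_idx, c.rules) for c in a] == \
            [(c.start_idx, c.end_idx, c.rules) for c in b]

    @given(st.integers(0, 100))
    def test_lower_ucl_never_removes_called_bases(self, seed):
        stats = np.random.default_rng(seed).exponential(1.0, 80)
        hi = apply_run_rules(stats, ucl=2.0)
        lo = apply_run_rules(stats, ucl=1.0)
        covered_hi = set()
        for c in hi:
            covered_hi.update(range(c.start_idx, c.end_idx + 1))
        covered_lo = set()
        for c in lo:
            covered_lo.update(range(c.start_idx, c.end_idx + 1))
        assert covered_hi <= covered_lo


class TestFilterTrainingSet:
    def _candidates(self):
        return pd.DataFrame({
            "start": [0, 1000, 5000, 9000],
            "end": [500, 1500, 5500, 9500],
            "label": [1, 0, 1, 0],
        })

    def test_open_candidate_needs_overlap(self):
        out = filter_training_set(self._candidates(), [(100, 300)])
        # open candidate at [0,500) overlaps; open at [5000,5500) does not
        assert (out["start"] == 0).any()
        assert not (out["start"] == 5000).any()

    def test_closed_candidate_needs_no_overlap(self):
        out = filter_training_set(self._candidates(), [(1200, 1300)])
        assert not (out["start"] == 1000).any()  # closed overlapping: removed
        assert (out["start"] == 9000).any()  # closed disjoint: retained

    def test_abutting_interval_is_not_overlap(self):
        # call ends exactly where the candidate starts (half-open coords)
        out = filter_training_set(self._candidates(), [(500, 1000)])
        assert not (out["start"] == 0).any()  # open, zero overlap -> removed
        assert (out["start"] == 1000).any()  # closed, zero overlap -> retained

    def test_balance_downsamples_majority(self):
        cand = pd.DataFrame({
            "start": np.arange(10) * 1000,
            "end": np.arange(10) * 1000 + 100,
            "label": [1, 1, 0, 0, 0, 0, 0, 0, 0, 0],
        })
        calls = [(0, 150), (1000, 1150)]
        out = filter_training_set(cand, calls, balance=True, seed=0)
        assert (out["label"] == 1).sum() == (out["label"] == 0).sum() == 2
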