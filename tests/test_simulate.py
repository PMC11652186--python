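"""Synthetic cfDNA generator: periodicity, depletion, mixing, labeling."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cfocr import (IntervalFeatureMatrix, SimParams, compute_coverage,
                   make_dataset, simulate_fragments, simulate_pocr_features,
                   simulate_sample)


class TestSimulateFragments:
    def test_zero_depth_gives_empty_set(self):
        params = SimParams(depth_ccr=0.0)
        fr = simulate_fragments(20_000, "CCR", params, seed=1)
        assert len(fr) == 0

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            simulate_fragments(100, "CCR", SimParams(), seed=1)  # < one period
        with pytest.raises(ValueError):
            simulate_fragments(20_000, "bogus", SimParams(), seed=1)
        with pytest.raises(ValueError):
            SimParams(ocr_depletion=1.5)

    def test_closed_state_coverage_is_periodic(self):
        """Coverage autocorrelation peaks at the nucleosome repeat
        (within +-10 bp of 190), computed by direct summation."""
        fr = simulate_fragments(20_000, "CCR", SimParams(), seed=1)
        cov = compute_coverage(fr).astype(float)
        x = cov - cov.mean()
        # direct autocorrelation over candidate lags
        lags = np.arange(150, 231)
        ac = np.array([np.sum(x[:-l] * x[l:]) for l in lags])
        peak = lags[np.argmax(ac)]
        assert 180 <= peak <= 200

    def test_open_state_coverage_is_depleted(self):
        """Monte-Carlo: mean open coverage below closed, 20 replicate seeds."""
        params = SimParams()
        ccr, ocr = [], []
        for s in range(20):
            ccr.append(compute_coverage(simulate_fragments(20_000, "CCR", params, seed=s)).mean())
            ocr.append(compute_coverage(simulate_fragments(20_000, "OCR", params, seed=s)).mean())
        assert np.mean(ocr) < np.mean(ccr)

    def test_coverage_ratio_converges_to_depletion(self):
        """OCR/CCR expected coverage ratio -> ocr_depletion at depth
        giving <5% standard error (heterogeneity off)."""
        params = SimParams(depth_cv=0.0)
        ccr = np.mean([compute_coverage(simulate_fragments(20_000, "CCR", params, seed=s)).mean()
                       for s in range(10)])
        ocr = np.mean([compute_coverage(simulate_fragments(20_000, "OCR", params, seed=s)).mean()
                       for s in range(10)])
        assert ocr / ccr == pytest.approx(params.ocr_depletion, rel=0.05)

    def test_identical_seeds_bit_identical(self):
        a = simulate_fragments(20_000, "CCR", SimParams(), seed=7)
        b = simulate_fragments(20_000, "CCR", SimParams(), seed=7)
        np.testing.assert_array_equal(a.intervals, b.intervals)

    def test_fragments_within_segment(self):
        fr = simulate_fragments(5_000, "OCR", SimParams(), seed=3)
        assert fr.starts.min() >= 0 and fr.ends.max() <= 5_000
        assert (fr.ends > fr.starts).all()


class TestSimulateSample:
    def test_open_sample_has_central_span(self):
        params = SimParams(seed=0)
        fr, span = simulate_sample(20_000, "OCR", params, np.random.default_rng(1))
        assert span is not None
        lo, hi = span
        assert params.ocr_width_min_bp <= hi - lo <= params.ocr_width_max_bp
        cov = compute_coverage(fr).astype(float)
        inside = cov[lo:hi].mean()
        outside = np.concatenate([cov[:lo], cov[hi:]]).mean()
        assert inside < 0.6 * outside

    def test_closed_sample_has_no_span(self):
        _, span = simulate_sample(20_000, "CCR", SimParams(), np.random.default_rng(1))
        assert span is None


class TestPocrMixing:
    def _pair(self, seed=0, shape=(100, 4)):
        rng = np.random.default_rng(seed)
        o = IntervalFeatureMatrix(rng.random(shape))
        c = IntervalFeatureMatrix(rng.random(shape))
        return o, c

    def test_tau_one_returns_open_exactly(self):
        o, c = self._pair()
        np.testing.assert_array_equal(simulate_pocr_features(o, c, 1.0).values, o.values)

    def test_midpoint(self):
        o = IntervalFeatureMatrix(np.full((10, 4), 2.0))
        c = IntervalFeatureMatrix(np.zeros((10, 4)))
        np.testing.assert_allclose(simulate_pocr_features(o, c, 0.5).values, 1.0)

    def test_regression_recovers_tau(self):
        """Least squares on (open, closed) recovers the composite rate
        exactly."""
        o, c = self._pair(3)
        mix = simulate_pocr_features(o, c, 0.7)
        A = np.stack([o.values.ravel(), c.values.ravel()], axis=1)
        coef, *_ = np.linalg.lstsq(A, mix.values.ravel(), rcond=None)
        assert coef[0] == pytest.approx(0.7, abs=1e-8)
        assert coef[1] == pytest.approx(0.3, abs=1e-8)

    def test_shape_mismatch_raises(self):
        o, _ = self._pair()
        c = IntervalFeatureMatrix(np.zeros((5, 4)))
        with pytest.raises(ValueError):
            simulate_pocr_features(o, c, 0.7)

    @given(st.integers(0, 500), st.floats(0.05, 0.95))
    def test_mix_is_convex_combination(self, seed, tau):
        o, c = self._pair(seed, shape=(8, 4))
        mix = simulate_pocr_features(o, c, tau).values
        lo = np.minimum(o.values, c.values)
        hi = np.maximum(o.values, c.values)
        assert (mix >= lo - 1e-12).all() and (mix <= hi + 1e-12).all()


class TestMakeDataset:
    def test_zero_noise_labels_match(self, quick_params):
        data = make_dataset(10, noise_rate=0.0, params=quick_params, seed=1,
                            segment_bp=2_000)
        binary = data.true < 2
        np.testing.assert_array_equal(data.observed[binary], data.true[binary])

    def test_flip_fraction_matches_noise_rate(self, quick_params):
        data = make_dataset(1, n_ocr=1000, n_ccr=1000, n_pocr=0,
                            noise_rate=0.2, params=quick_params, seed=2,
                            segment_bp=2_000)
        flipped = np.mean(data.observed != data.true)
        assert flipped == pytest.approx(0.2, abs=0.03)

    def test_pocr_observed_labels_are_random_binary(self, quick_params):
        data = make_dataset(50, tau=0.7, noise_rate=0.0, params=quick_params,
                            seed=3, segment_bp=2_000)
        pocr_obs = data.observed[data.true == 2]
        assert set(np.unique(pocr_obs)) == {0, 1}

    def test_dataset_determinism(self, quick_params):
        a = make_dataset(5, params=quick_params, seed=9, segment_bp=2_000)
        b = make_dataset(5, params=quick_params, seed=9, segment_bp=2_000)
        np.testing.assert_array_equal(a.observed, b.observed)
        for fa, fb in zip(a.features, b.features):
            np.testing.assert_array_equal(fa.values, fb.values)

    def test_invalid_arguments(self, quick_params):
        with pytest.raises(ValueError):
            make_dataset(0, params=quick_params)
        with pytest.raises(ValueError):
            make_dataset(5, noise_rate=0.6, params=quick_params)

    def test_fragment_level_pocr_mode(self, quick_params):
        data = make_dataset(4, params=quick_params, seed=5, segment_bp=2_000,
                            pocr_mode="fragment")
        pocr_idx = np.flatnonzero(data.true == 2)
        assert all(data.fragments[i] is not None for i in pocr_idx)
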