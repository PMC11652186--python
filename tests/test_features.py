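"""Per-base tracks, windowed matrices, summary vectors, image encoding."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cfocr import (FragmentSet, ImageConfig, IntervalFeatureMatrix, SignalTracks,
                   SimParams, compute_coverage, compute_end_signals, compute_wps,
                   encode_image, featurize_fragments, simulate_fragments,
                   summarize_std, window_average)


def frag_set(intervals, L=None):
    return FragmentSet("chr1", np.asarray(intervals, dtype=np.int64).reshape(-1, 2),
                       segment_length=L)


def random_frags(rng, n=200, L=2000):
    starts = rng.integers(0, L - 150, n)
    lengths = rng.integers(100, 150, n)
    iv = np.stack([starts, np.minimum(starts + lengths, L)], axis=1)
    return frag_set(iv, L)


class TestCoverage:
    def test_no_fragments_all_zero(self):
        cov = compute_coverage(frag_set(np.empty((0, 2)), 20))
        np.testing.assert_array_equal(cov, np.zeros(20))

    def test_single_fragment(self):
        cov = compute_coverage(frag_set([(0, 10)], 20))
        np.testing.assert_array_equal(cov, [1] * 10 + [0] * 10)

    def test_matches_per_base_membership_oracle(self, rng):
        fr = random_frags(rng)
        cov = compute_coverage(fr)
        brute = np.array([np.sum((fr.starts <= i) & (fr.ends > i)) for i in range(2000)])
        np.testing.assert_array_equal(cov, brute)

    def test_coverage_conservation(self, rng):
        fr = random_frags(rng)
        assert compute_coverage(fr).sum() == fr.lengths().sum()


class TestWPS:
    def test_no_fragments_all_zero(self):
        np.testing.assert_array_equal(compute_wps(frag_set(np.empty((0, 2)), 500)),
                                      np.zeros(500))

    def test_spanning_window_scores_plus_one(self):
        # window [40,160) lies inside the fragment, no endpoint within
        wps = compute_wps(frag_set([(0, 200)], 400), w=120)
        assert wps[100] == 1

    def test_endpoint_in_window_scores_minus_one(self):
        # window [-50,70) contains the fragment start at 0
        wps = compute_wps(frag_set([(0, 200)], 400), w=120)
        assert wps[10] == -1

    def test_matches_definition_oracle(self, rng):
        fr = random_frags(rng, n=60, L=600)
        wps = compute_wps(fr, w=120)
        hw = 60
        s, e = fr.starts, fr.ends
        for i in range(0, 600, 7):
            lo, hi = i - hw, i + hw
            span = np.sum((s <= lo) & (e >= hi))
            endpoints = np.sum((s >= lo) & (s < hi)) + np.sum((e - 1 >= lo) & (e - 1 < hi))
            assert wps[i] == span - endpoints

    def test_window_larger_than_segment_raises(self):
        with pytest.raises(ValueError):
            compute_wps(frag_set([(0, 10)], 50), w=120)


class TestEndSignals:
    def test_single_fragment_ends(self):
        uend, dend = compute_end_signals(frag_set([(5, 10)], 20))
        assert uend[5] == 1 and uend.sum() == 1
        assert dend[9] == 1 and dend.sum() == 1

    def test_no_fragments(self):
        uend, dend = compute_end_signals(frag_set(np.empty((0, 2)), 20))
        assert uend.sum() == dend.sum() == 0

    def test_matches_brute_force_tally(self, rng):
        fr = random_frags(rng)
        uend, dend = compute_end_signals(fr)
        bu = np.zeros(2000, dtype=int)
        bd = np.zeros(2000, dtype=int)
        for s, e in fr.intervals:
            bu[s] += 1
            bd[e - 1] += 1
        np.testing.assert_array_equal(uend, bu)
        np.testing.assert_array_equal(dend, bd)

    def test_end_sums_equal_fragment_count(self, rng):
        fr = random_frags(rng)
        uend, dend = compute_end_signals(fr)
        assert uend.sum() == dend.sum() == len(fr)


class TestWindowAverage:
    def test_default_segment_gives_100_by_4(self):
        fr = simulate_fragments(20_000, "CCR", SimParams(depth_ccr=5.0), seed=1)
        m = featurize_fragments(fr)
        assert m.values.shape == (100, 4)

    def test_constant_tracks(self):
        tracks = SignalTracks(wps=np.full(600, 2.0), coverage=np.full(600, 3.0),
                              uend=np.ones(600), dend=np.zeros(600))
        m = window_average(tracks, 200)
        np.testing.assert_allclose(m.values, np.tile([2.0, 3.0, 1.0, 0.0], (3, 1)))

    def test_matches_slice_mean_oracle(self, rng):
        arrs = rng.random((4, 1000))
        tracks = SignalTracks(*arrs)
        m = window_average(tracks, 200)
        for k in range(5):
            np.testing.assert_allclose(
                m.values[k], arrs[:, 200 * k : 200 * (k + 1)].mean(axis=1))

    def test_partial_window_dropped(self, rng):
        arrs = rng.random((4, 1050))
        assert window_average(SignalTracks(*arrs), 200).n_windows == 5

    def test_bad_window_raises(self, rng):
        with pytest.raises(ValueError):
            window_average(SignalTracks(*rng.random((4, 100))), 0)


class TestSummarizeStd:
    def test_constant_columns_zero(self):
        m = IntervalFeatureMatrix(np.ones((10, 4)))
        np.testing.assert_allclose(summarize_std(m), [0.0, 0.0])

    def test_two_point_sd(self):
        v = np.zeros((2, 4))
        v[1, 0] = 2.0  # WPS column (0, 2): population sd 1
        assert summarize_std(IntervalFeatureMatrix(v))[0] == pytest.approx(1.0)

    def test_matches_formula_oracle(self, rng):
        v = rng.random((30, 4))
        sv = summarize_std(IntervalFeatureMatrix(v))
        for j in range(2):
            mu = v[:, j].mean()
            assert sv[j] == pytest.approx(np.sqrt(np.mean((v[:, j] - mu) ** 2)))

    def test_single_row_raises(self):
        with pytest.raises(ValueError):
            summarize_std(IntervalFeatureMatrix(np.ones((1, 4))))


class TestEncodeImage:
    def test_no_fragments_zero_channels(self):
        img = encode_image(frag_set(np.empty((0, 2)), 2000))
        assert img.primary.sum() == 0

    def test_single_fragment_single_count(self):
        img = encode_image(frag_set([(450, 617)], 2000))  # length 167 at 450
        assert img.primary.sum() == 1
        assert img.primary[450 // 200, 167 - 100] == 1

    def test_channel_sum_is_fragment_count(self, rng):
        fr = random_frags(rng)
        img = encode_image(fr)
        assert img.primary.sum() == len(fr)


class TestStateContrast:
    def test_closed_state_has_larger_wps_variance(self):
        """Over 20 seeds the WPS column variance of closed-lattice
        matrices exceeds that of depth-matched open simulations."""
        params = SimParams()
        wins = 0
        for s in range(20):
            mc = featurize_fragments(simulate_fragments(20_000, "CCR", params, seed=s))
            mo = featurize_fragments(simulate_fragments(20_000, "OCR", params, seed=s))
            wins += mc.values[:, 0].var() > mo.values[:, 0].var()
        assert wins >= 18

    @given(st.integers(0, 200))
    def test_featurization_deterministic(self, seed):
        fr = simulate_fragments(2_000, "CCR", SimParams(depth_ccr=5.0), seed=seed)
        a = featurize_fragments(fr)
        b = featurize_fragments(fr)
        np.testing.assert_array_equal(a.values, b.values)
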