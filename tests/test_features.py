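"""The six feature extractors against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import find_peaks

from synthprint import (
    AnalysisError,
    FEATURE_NAMES,
    extract_features,
    frequency_feature,
    global_gray_features,
    gray_profile,
    harris_feature,
    ridge_distance_at,
    ridge_distance_features,
    segment_foreground,
    estimate_orientation,
)
from synthprint.features import GrayProfile, _peak_mask, _smooth3, extract_table

from .conftest import grating
from .oracles import annulus_mean_magnitude, gray_mean_var, harris_count, mann_whitney_auc


class TestGrayProfile:
    def test_constant_image_gives_flat_profile(self):
        prof = gray_profile(np.full((96, 96), 128.0), (48, 48), 0.7)
        assert prof.valid
        assert prof.S.shape == (32,)
        assert np.allclose(prof.S, 128.0)

    def test_profile_periodic_with_grating_period(self):
        """Columns march across the ridges, so S repeats with the period."""
        img = grating(8, 0, size=96, phase=0.0)
        prof = gray_profile(img, (48.0, 48.0), 0.0)  # ridges along rows
        assert prof.valid
        assert np.allclose(prof.S[8:], prof.S[:-8], atol=1.0)  # period 8
        s = prof.S - prof.S.mean()
        ac = np.correlate(s, s, mode="full")[len(s) - 1 :]
        assert ac[8] == ac[1:16].max()  # autocorrelation peak at lag 8

    def test_center_near_border_is_invalid(self):
        prof = gray_profile(np.zeros((96, 96)), (5, 48), 0.0)
        assert not prof.valid


class TestRidgeDistanceAt:
    def test_pure_sinusoid_period_nine(self):
        k = np.arange(32)
        prof = GrayProfile(S=128 + 50 * np.cos(2 * np.pi * k / 9), center=(0, 0), theta=0.0)
        sample = ridge_distance_at(prof)
        assert sample.valid
        assert sample.D == pytest.approx(9.0)

    def test_monotone_ramp_is_invalid(self):
        prof = GrayProfile(S=4.0 * np.arange(32), center=(0, 0), theta=0.0)
        assert not ridge_distance_at(prof).valid

    def test_noisy_sinusoid_period_ten(self):
        rng = np.random.default_rng(17)
        k = np.arange(32)
        for _ in range(10):
            S = 128 + 50 * np.cos(2 * np.pi * k / 10) + rng.uniform(-1, 1, 32)
            sample = ridge_distance_at(GrayProfile(S=S, center=(0, 0), theta=0.0))
            assert sample.valid
            assert abs(sample.D - 10.0) <= 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_peak_rule_matches_find_peaks(self, seed):
        """The vectorized peak/prominence rule agrees with scipy's peak
        finder (prominence >= 2 after 3-point smoothing) on random profiles."""
        rng = np.random.default_rng(seed)
        S = rng.uniform(0, 255, 32)
        smoothed = _smooth3(S)
        mine = np.flatnonzero(_peak_mask(smoothed, 2.0)[0])
        ref, _ = find_peaks(smoothed, prominence=2.0)
        assert np.array_equal(mine, ref)


class TestRidgeDistanceFeatures:
    def test_constant_period_grating(self):
        img = grating(9, 0, size=160)
        summary = ridge_distance_features(
            img, estimate_orientation(img), segment_foreground(img)
        )
        assert 8.5 <= summary.q_disavg <= 9.5
        assert summary.q_disstd <= 0.5
        assert summary.n_candidates == 9216

    def test_mixed_period_halves_raise_spread(self):
        """Top half period 8, bottom half period 12: the pooled mean sits
        between and the spread reflects the two populations."""
        size = 224
        img = np.empty((size, size))
        img[: size // 2] = grating(8, 0, size=size)[: size // 2]
        img[size // 2 :] = grating(12, 0, size=size)[size // 2 :]
        summary = ridge_distance_features(
            img, estimate_orientation(img), segment_foreground(img)
        )
        assert 8.0 < summary.q_disavg < 12.0
        assert abs(summary.q_disavg - 10.0) <= 1.0
        assert summary.q_disstd >= 1.5

    def test_no_ridge_structure_raises(self):
        # a steep ramp: enough variance to count as foreground, coherent
        # orientation, but monotone profiles with no peaks anywhere
        img = np.tile(2.5 * np.arange(96), (96, 1))
        with pytest.raises(AnalysisError, match="ridge structure"):
            ridge_distance_features(
                img, estimate_orientation(img), segment_foreground(img)
            )


class TestGlobalGrayFeatures:
    def test_closed_forms(self):
        avg, var = global_gray_features(np.full((50, 40), 200.0))
        assert (avg, var) == (200.0, 0.0)
        img = np.zeros((10, 10))
        img[:5] = 255.0
        avg, var = global_gray_features(img)
        assert avg == 127.5
        assert var == 16256.25

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(9)
        img = rng.integers(0, 256, (64, 64)).astype(float)
        avg, var = global_gray_features(img)
        o_avg, o_var = gray_mean_var(img)
        assert avg == pytest.approx(o_avg, rel=1e-9)
        assert var == pytest.approx(o_var, rel=1e-9)


class TestFrequencyFeature:
    def test_constant_image_has_no_annulus_energy(self):
        assert frequency_feature(np.full((64, 64), 90.0)) == 0.0

    def test_low_frequency_cosine_excluded_by_ring(self):
        # spatial frequency 8/64 cycles/px -> DFT radius 8 < r0 = 16
        y, x = np.mgrid[0:64, 0:64].astype(float)
        img = 128 + 50 * np.cos(2 * np.pi * 8 * x / 64)
        assert frequency_feature(img) == pytest.approx(0.0, abs=1e-9)

    def test_matches_per_bin_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(5):
            img = rng.integers(0, 256, (64, 64)).astype(float)
            assert frequency_feature(img) == pytest.approx(
                annulus_mean_magnitude(img), rel=1e-6
            )


class TestHarrisFeature:
    def test_constant_image_has_no_corners(self):
        assert harris_feature(np.full((64, 64), 128.0)) == 0

    def test_white_square_corners_match_oracle(self):
        """Every geometric corner of a white square fires, and the count
        agrees exactly with the from-scratch R map + decision rule."""
        img = np.zeros((64, 64))
        img[20:36, 20:36] = 255.0
        count = harris_feature(img)
        assert count == harris_count(img)
        assert count >= 4

    def test_random_images_match_oracle_exactly(self):
        rng = np.random.default_rng(31)
        for _ in range(5):
            img = rng.integers(0, 256, (64, 64)).astype(float)
            assert harris_feature(img) == harris_count(img)


class TestExtractFeatures:
    def test_vector_has_six_features_in_fixed_order(self):
        img = grating(9, 30, size=160)
        vec = extract_features(img)
        arr = vec.as_array()
        assert arr.shape == (6,)
        assert list(FEATURE_NAMES) == [
            "q_disavg",
            "q_disstd",
            "q_grayavg",
            "q_grayvar",
            "q_fft",
            "q_harris",
        ]
        assert arr[0] == vec.q_disavg and arr[5] == vec.q_harris

    def test_constant_image_has_no_foreground(self):
        with pytest.raises(AnalysisError, match="no foreground"):
            extract_features(np.full((128, 128), 100.0))

    def test_batch_table_rows_align_with_images(self):
        imgs = [grating(8, 0, size=160), grating(12, 45, size=160)]
        table = extract_table(imgs, labels=["real", "synthetic"])
        assert list(table.columns) == ["path", "label", *FEATURE_NAMES]
        assert len(table) == 2
        assert table.loc[0, "q_disavg"] == pytest.approx(8.0, abs=1.0)
        assert table.loc[1, "q_disavg"] == pytest.approx(12.0, abs=1.0)

    def test_gray_shift_covariance(self):
        """Adding a constant gray offset shifts q_grayavg by that constant
        and leaves the variance and ridge-distance features unchanged."""
        img = grating(10, 20, size=160, amplitude=50, mean=110)
        a = extract_features(img).as_array()
        b = extract_features(img + 20.0).as_array()
        assert b[2] == pytest.approx(a[2] + 20.0)
        assert b[3] == pytest.approx(a[3], rel=1e-9)
        assert b[0] == pytest.approx(a[0], rel=1e-6)
        assert b[1] == pytest.approx(a[1], abs=1e-6)

    def test_rotation_robustness_of_ridge_distance(self):
        """Orientation-compensated windows keep q_disavg within 5% under a
        30-degree rotation of the ridge pattern."""
        a = extract_features(grating(10, 0, size=160)).as_array()
        b = extract_features(grating(10, 30, size=160)).as_array()
        assert abs(b[0] - a[0]) / a[0] <= 0.05
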