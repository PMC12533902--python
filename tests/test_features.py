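"""Feature extractors against brute-force oracles and closed-form limits."""

import numpy as np
import pytest

from cilad import features as ft
from cilad import synthetic_data as sd


class TestHrvSdnn:
    def test_forced_values(self):
        assert ft.hrv_sdnn([800, 800, 800]) == 0.0
        assert ft.hrv_sdnn([790, 810]) == pytest.approx(10.0)

    def test_matches_direct_population_sd(self):
        vals = [812.0, 795.0, 830.0, 801.0, 788.0]
        m = sum(vals) / len(vals)
        expected = (sum((v - m) ** 2 for v in vals) / len(vals)) ** 0.5
        assert ft.hrv_sdnn(vals) == pytest.approx(expected, abs=1e-12)

    def test_too_few_intervals(self):
        with pytest.raises(ValueError):
            ft.hrv_sdnn([800])


class TestQrsDuration:
    def test_rectangular_pulse(self):
        beat = np.zeros(64)
        beat[20:30] = 1.0  # 10 samples at fs=125 -> 80 ms
        assert ft.qrs_duration(beat, fs=125) == pytest.approx(80.0)

    @pytest.mark.parametrize("cls", [0, 1, 4])
    def test_matches_generator_ground_truth(self, cls):
        # classes with an isolated R bump; the wide-QRS classes overlap deep
        # S deflections by design, which distorts the above-threshold region
        beat = sd.class_template(cls, 187)
        truth = sd.qrs_truth_ms(cls)
        tol = 2 * 1000.0 / 125  # two samples
        assert ft.qrs_duration(beat, fs=125) == pytest.approx(truth, abs=tol)

    @pytest.mark.parametrize("width_ms", [48.0, 80.0, 120.0])
    def test_isolated_gaussian_bump_width(self, width_ms):
        fs = 125.0
        width_factor = 2 * np.sqrt(2 * np.log(5.0))  # theta = 0.2
        sd_samples = (width_ms / 1000 * fs) / width_factor
        t = np.arange(187)
        beat = np.exp(-0.5 * ((t - 93) / sd_samples) ** 2)
        tol = 2 * 1000.0 / fs
        assert ft.qrs_duration(beat, fs=fs) == pytest.approx(width_ms, abs=tol)

    def test_flat_beat_raises(self):
        with pytest.raises(ft.UndefinedQRSError):
            ft.qrs_duration(np.zeros(32), fs=125)


class TestPeriodogram:
    def test_pure_sinusoid_mass_concentrates_at_grid_bin(self):
        fs, n = 125.0, 187
        k = 15  # exact grid frequency k * fs / n
        x = np.sin(2 * np.pi * k * np.arange(n) / n)
        freqs, power = ft.psd_periodogram(x, fs)
        bin_nearest = np.argmin(np.abs(freqs - k * fs / n))
        assert power[bin_nearest] / power.sum() >= 0.9

    def test_zero_signal_zero_power(self):
        _, power = ft.psd_periodogram(np.zeros(64), 125.0)
        assert np.allclose(power, 0.0)

    def test_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        freqs, power = ft.psd_periodogram(x, fs=125.0)
        df = freqs[1] - freqs[0]
        assert power.sum() * df == pytest.approx(np.mean(x ** 2), abs=1e-8)

    def test_band_powers_partition_total(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 187)
        freqs, power = ft.psd_periodogram(x, 125.0)
        bands = ((0.0, 20.0), (20.0, 40.0), (40.0, 63.0))
        bp = ft.band_powers(freqs, power, bands)
        df = freqs[1] - freqs[0]
        assert sum(bp.values()) == pytest.approx(power.sum() * df, rel=1e-9)


class TestShapeFeatures:
    @staticmethod
    def _disk(radius, size=None):
        size = size or 2 * radius + 5
        yy, xx = np.mgrid[0:size, 0:size]
        c = (size - 1) / 2
        return (yy - c) ** 2 + (xx - c) ** 2 <= radius ** 2

    def test_circle_has_zero_eccentricity_and_unit_aspect(self):
        f = ft.shape_features(self._disk(20))
        assert f["eccentricity"] == pytest.approx(0.0, abs=0.05)
        assert f["aspect_ratio"] == pytest.approx(1.0)

    def test_disk_circularity_near_one(self):
        f = ft.shape_features(self._disk(30))
        assert 0.85 <= f["circularity"] <= 1.1

    def test_elongated_ellipse_is_eccentric(self):
        yy, xx = np.mgrid[0:41, 0:81]
        mask = ((xx - 40) / 35) ** 2 + ((yy - 20) / 12) ** 2 <= 1
        f = ft.shape_features(mask)
        expected = np.sqrt(1 - (12 / 35) ** 2)
        assert f["eccentricity"] == pytest.approx(expected, abs=0.03)
        assert f["aspect_ratio"] > 2

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            ft.shape_features(np.zeros((5, 5), dtype=bool))


class TestGLCM:
    def test_constant_image_limits(self):
        f = ft.glcm_features(np.full((8, 8), 7))
        assert f["energy"] == pytest.approx(1.0)
        assert f["contrast"] == pytest.approx(0.0)
        assert f["homogeneity"] == pytest.approx(1.0)
        assert f["entropy"] == pytest.approx(0.0)

    def test_checkerboard_hand_enumeration(self):
        # 2x2 checkerboard, distance 1, angle 0, levels 2: the two horizontal
        # pairs are (0,1) and (1,0); symmetric normalized matrix has
        # P(0,1) = P(1,0) = 1/2, so contrast = 1, energy = 1/2,
        # homogeneity = 1/2, entropy = ln 2 and correlation = -1.
        img = np.array([[0, 1], [1, 0]])
        spec = ft.GLCMSpec(distance=1, angles=(0.0,), levels=2)
        f = ft.glcm_features(img, spec)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["energy"] == pytest.approx(0.5)
        assert f["homogeneity"] == pytest.approx(0.5)
        assert f["entropy"] == pytest.approx(np.log(2))
        assert f["correlation"] == pytest.approx(-1.0)

    def test_alternating_stripes_correlation_sign(self):
        stripes = np.tile([0, 1], (8, 8))
        spec1 = ft.GLCMSpec(distance=1, angles=(0.0,), levels=2)
        spec2 = ft.GLCMSpec(distance=2, angles=(0.0,), levels=2)
        assert ft.glcm_features(stripes, spec1)["correlation"] == pytest.approx(-1.0, abs=1e-9)
        assert ft.glcm_features(stripes, spec2)["correlation"] == pytest.approx(1.0, abs=1e-9)

    def test_matches_pair_enumeration_oracle(self):
        rng = np.random.default_rng(4)
        img = rng.integers(0, 4, (6, 6))
        spec = ft.GLCMSpec(distance=1, angles=(0.0,), levels=4)
        # oracle: enumerate horizontal pairs explicitly
        P = np.zeros((4, 4))
        for r in range(6):
            for c in range(5):
                P[img[r, c], img[r, c + 1]] += 1
        P = P + P.T
        P /= P.sum()
        i, j = np.meshgrid(np.arange(4), np.arange(4), indexing="ij")
        f = ft.glcm_features(img, spec)
        assert f["contrast"] == pytest.approx((P * (i - j) ** 2).sum(), abs=1e-12)
        assert f["energy"] == pytest.approx((P ** 2).sum(), abs=1e-12)
        nz = P[P > 0]
        assert f["entropy"] == pytest.approx(-(nz * np.log(nz)).sum(), abs=1e-12)


class TestLBP:
    def test_constant_image_all_codes_255(self):
        hist = ft.lbp_histogram(np.ones((5, 5)), radius=1, points=8)
        assert hist[255] == pytest.approx(1.0)

    def test_bright_center_codes_zero(self):
        img = np.zeros((3, 3))
        img[1, 1] = 10.0
        codes = ft.lbp_codes(img)
        assert codes[0, 0] == 0

    def test_codes_match_per_pixel_loop_oracle(self):
        rng = np.random.default_rng(2)
        img = rng.integers(0, 10, (5, 5)).astype(float)
        codes = ft.lbp_codes(img, radius=1, points=8)
        offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1),
                   (0, -1), (1, -1), (1, 0), (1, 1)]  # east, counter-clockwise
        for y in range(1, 4):
            for x in range(1, 4):
                code = 0
                for bit, (dy, dx) in enumerate(offsets):
                    if img[y + dy, x + dx] >= img[y, x]:
                        code |= 1 << bit
                assert codes[y - 1, x - 1] == code

    def test_histogram_sums_to_one(self):
        rng = np.random.default_rng(3)
        hist = ft.lbp_histogram(rng.integers(0, 256, (16, 16)))
        assert hist.sum() == pytest.approx(1.0)


class TestStatMoments:
    def test_symmetric_sequence_zero_skewness(self):
        assert ft.stat_moments([1, 2, 3, 4, 5])["skewness"] == pytest.approx(0.0)

    def test_forced_two_point_values(self):
        m = ft.stat_moments([2, 4])
        assert (m["mean"], m["median"], m["sd"]) == (3.0, 3.0, 1.0)

    def test_standard_normal_excess_kurtosis_near_zero(self):
        rng = np.random.default_rng(0)
        m = ft.stat_moments(rng.normal(0, 1, 100_000))
        assert abs(m["kurtosis"]) < 0.05


class TestExtractAll:
    def test_ecg_schema_and_finiteness(self, small_beats):
        table = ft.extract_all("ecg", small_beats)
        assert table.names[:5] == ["beat_mean", "beat_median", "beat_sd",
                                   "beat_skewness", "beat_kurtosis"]
        assert table.n_features == 11
        assert np.isfinite(table.values).all()

    def test_image_schema_and_finiteness(self, small_images):
        table = ft.extract_all("image", small_images)
        assert table.n_features == 10
        assert np.isfinite(table.values).all()

    def test_tabular_appends_row_moments(self, records):
        table = ft.extract_all("tabular", records)
        assert table.n_features == 13 + 5
        assert table.names[-5:] == ["row_mean", "row_median", "row_sd",
                                    "row_skewness", "row_kurtosis"]

    def test_names_deterministic_across_runs(self, small_beats):
        a = ft.extract_all("ecg", small_beats)
        b = ft.extract_all("ecg", small_beats)
        assert a.names == b.names
        assert np.array_equal(a.values, b.values)

    def test_unknown_modality(self, small_beats):
        with pytest.raises(ValueError):
            ft.extract_all("audio", small_beats)
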