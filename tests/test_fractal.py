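"""Tests of the FD estimators: Higuchi/FDC, spectral, box counting."""

import warnings

import numpy as np
import pytest

from retfdc.errors import ConstantSeriesError, DegenerateInputError, ParameterError
from retfdc.fractal import (
    HiguchiParams,
    binarize_for_bc,
    box_counting_fd,
    fdc,
    higuchi_fd,
    spectral_fd,
)
from retfdc.scanpath import CircleProfile
from retfdc.synth import gen_power_law_image, gen_sierpinski

from ._oracles import higuchi_bruteforce


def _profile(samples, zone, radius=60.0):
    return CircleProfile(radius=radius, zone=zone, samples=np.asarray(samples, float))


class TestHiguchi:
    def test_linear_ramp_dimension_one(self):
        assert higuchi_fd(np.arange(1000.0)) == pytest.approx(1.0, abs=0.01)

    def test_matches_bruteforce_transcription(self, rng):
        for _ in range(10):
            x = np.cumsum(rng.standard_normal(500))
            assert higuchi_fd(x, clamp=False) == pytest.approx(
                higuchi_bruteforce(x, 8), abs=1e-12
            )

    def test_affine_invariance(self, rng):
        x = np.cumsum(rng.standard_normal(600))
        a = higuchi_fd(x, clamp=False)
        b = higuchi_fd(-3.0 * x + 11.0, clamp=False)
        assert a == pytest.approx(b, abs=1e-9)

    def test_periodic_variant_is_cut_invariant(self, rng):
        x = np.cumsum(rng.standard_normal(512))
        fds = [higuchi_fd(np.roll(x, s), periodic=True, clamp=False) for s in (0, 37, 200)]
        assert max(fds) - min(fds) < 1e-12

    def test_constant_series_undefined(self):
        with pytest.raises(ConstantSeriesError):
            higuchi_fd(np.full(200, 4.0))

    def test_short_series_rejected(self):
        with pytest.raises(ParameterError):
            higuchi_fd(np.arange(20.0), HiguchiParams(k_max=8))

    def test_clamp_warns_outside_range(self, rng):
        x = rng.standard_normal(2000)  # white noise estimates can exceed 2
        vals = []
        for seed in range(10):
            y = np.random.default_rng(seed).standard_normal(2000)
            vals.append(higuchi_fd(y, clamp=False))
        if max(vals) > 2.0:
            y = np.random.default_rng(int(np.argmax(vals))).standard_normal(2000)
            with pytest.warns(UserWarning, match="clamped"):
                assert higuchi_fd(y) <= 2.0


class TestFDC:
    def test_identical_profiles_give_equal_zone_means(self, rng):
        samples = np.cumsum(rng.standard_normal(256))
        profiles = [
            _profile(samples, z, radius=50.0 + i) for i, z in enumerate(["A"] * 3 + ["B"] * 3 + ["C"] * 3)
        ]
        res = fdc(profiles)
        vals = set(round(v, 12) for v in res.zone_means.values())
        assert len(vals) == 1

    def test_balanced_combination_identity(self, rng):
        profiles = []
        for i, z in enumerate(["A"] * 4 + ["B"] * 4 + ["C"] * 4):
            profiles.append(_profile(np.cumsum(rng.standard_normal(256)), z, radius=40.0 + i))
        res = fdc(profiles)
        zm = res.zone_means
        assert zm["AB"] == pytest.approx((zm["A"] + zm["B"]) / 2, abs=1e-12)
        assert zm["AC"] == pytest.approx((zm["A"] + zm["C"]) / 2, abs=1e-12)
        assert zm["ABC"] == pytest.approx((zm["A"] + zm["B"] + zm["C"]) / 3, abs=1e-12)

    def test_abc_mean_between_zone_extremes(self, rng):
        profiles = []
        for i, z in enumerate(["A"] * 5 + ["B"] * 5 + ["C"] * 5):
            profiles.append(_profile(np.cumsum(rng.standard_normal(200)), z, radius=30.0 + i))
        res = fdc(profiles)
        zones = [res.zone_means[z] for z in "ABC"]
        assert min(zones) <= res.zone_means["ABC"] <= max(zones)

    def test_constant_profiles_skipped_and_counted(self, rng):
        good = _profile(np.cumsum(rng.standard_normal(200)), "A", radius=31.0)
        flat = _profile(np.full(200, 2.0), "B", radius=32.0)
        with pytest.warns(UserWarning, match="skipped"):
            res = fdc([good, flat])
        assert res.n_skipped == 1
        assert "B" in res.missing
        assert np.isnan(res.zone_means["B"])
        assert not np.isnan(res.zone_means["A"])


class TestSpectral:
    @pytest.mark.parametrize("beta", [1.5, 2.5])
    def test_recovers_constructed_slope(self, beta):
        # log-power slope -beta corresponds to log-magnitude slope -beta/2
        slopes = [spectral_fd(gen_power_law_image(beta, 128, seed=s)).slope for s in range(10)]
        assert 2 * abs(np.mean(slopes)) == pytest.approx(beta, rel=0.1)

    def test_transposition_invariant(self, rng):
        img = rng.random((128, 128))
        assert spectral_fd(img).value == pytest.approx(spectral_fd(img.T).value, abs=1e-9)

    def test_affine_remapping(self, rng):
        img = gen_power_law_image(2.0, 128, seed=0)
        raw = spectral_fd(img)
        mapped = spectral_fd(img, affine_map=(1.0, 0.5))
        assert mapped.value == pytest.approx(1.0 + 0.5 * raw.value)

    def test_constant_image_degenerate(self):
        with pytest.raises(DegenerateInputError):
            spectral_fd(np.full((128, 128), 3.0))


class TestBinarize:
    def test_otsu_separates_bimodal(self, rng):
        img = np.where(rng.random((64, 64)) < 0.3, 200, 20).astype(np.uint8)
        binary = binarize_for_bc(img, skeletonize=False)
        np.testing.assert_array_equal(binary, img > 100)

    def test_skeleton_thins_bar_preserving_length(self):
        img = np.zeros((64, 64), dtype=np.uint8)
        img[30:35, 4:60] = 255  # 5 px wide bar
        sk = binarize_for_bc(img, method="fixed", threshold=100, skeletonize=True)
        cols = np.nonzero(sk)[1]
        assert np.all(np.bincount(cols) <= 1)  # one pixel per column: 1 px wide
        assert 56 - 6 <= sk.sum() <= 56  # same length up to end effects

    def test_empty_foreground_error(self):
        with pytest.raises(DegenerateInputError):
            binarize_for_bc(np.zeros((32, 32), dtype=np.uint8), method="fixed", threshold=10)


class TestBoxCounting:
    def test_filled_square(self):
        assert box_counting_fd(np.ones((128, 128), bool)).value == pytest.approx(2.0, abs=0.05)

    def test_single_line(self):
        img = np.zeros((128, 128), bool)
        img[64, :] = True
        assert box_counting_fd(img).value == pytest.approx(1.0, abs=0.05)

    def test_sierpinski_similarity_dimension(self):
        fd = box_counting_fd(gen_sierpinski(7)).value
        assert fd == pytest.approx(np.log(3) / np.log(2), abs=0.05)

    def test_translation_invariance_by_largest_box(self):
        img = np.zeros((128, 128), bool)
        img[10:40, 12:45] = np.random.default_rng(5).random((30, 33)) > 0.5
        shifted = np.roll(np.roll(img, 32, axis=0), 32, axis=1)
        a, b = box_counting_fd(img), box_counting_fd(shifted)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_single_pixel_warns_fd_zero(self):
        img = np.zeros((32, 32), bool)
        img[5, 5] = True
        with pytest.warns(UserWarning, match="single foreground"):
            assert box_counting_fd(img).value == 0.0

    def test_empty_rejected(self):
        with pytest.raises(DegenerateInputError):
            box_counting_fd(np.zeros((32, 32), bool))


class TestDirectionality:
    def test_circular_scan_prefers_radial_structure(self):
        """Circular profiles cross radial spokes along their cross-section,
        producing rough, high-FD series, while concentric rings are constant
        along the scan path (over a smooth baseline) and yield near-smooth,
        low-FD profiles."""
        from retfdc.preprocess import ODAnnotation
        from retfdc.scanpath import scan_all

        size, d_od = 256, 64.0
        c = (size - 1) / 2
        yy, xx = np.mgrid[0:size, 0:size].astype(float)
        r = np.hypot(xx - c, yy - c)
        theta = np.arctan2(yy - c, xx - c)
        baseline = 0.2 * xx / size  # smooth gradient so no profile is constant
        n_lines = 12
        spoke_means, ring_means = [], []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            phase = rng.uniform(0, 2 * np.pi)
            spokes = (np.cos(n_lines * (theta - phase)) > 0.95).astype(float)
            rings = (np.cos(2 * np.pi * r / (size / (2 * n_lines)) + phase) > 0.95).astype(float)
            od = ODAnnotation(c, c, d_od)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fd_s = fdc(scan_all(spokes + baseline, od)).zone_means["ABC"]
                fd_r = fdc(scan_all(rings + baseline, od)).zone_means["ABC"]
            spoke_means.append(fd_s)
            ring_means.append(fd_r)
        assert np.mean(spoke_means) > np.mean(ring_means)
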