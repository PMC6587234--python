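"""Unit and property tests for the raster primitives."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import oracles as orc
from motilityq import imcore as ic


def img(arr, px=1.0):
    return ic.CalibratedImage(np.asarray(arr, dtype=float), px_size=px)


# ---------------------------------------------------------------------------
# to_8bit
# ---------------------------------------------------------------------------

class TestTo8bit:
    def test_constant_maps_to_zero(self):
        out = ic.to_8bit(img(np.full((4, 4), 7.0)))
        assert out.pixels.dtype == np.uint8
        assert not out.pixels.any()

    def test_linear_map_definition(self):
        vals = np.array([[0.0, 255.0, 510.0, 1020.0]])
        out = ic.to_8bit(img(vals))
        expected = np.floor(vals * 255.0 / 1020.0 + 0.5)
        assert np.array_equal(out.pixels, expected)

    def test_two_valued_hits_endpoints(self):
        out = ic.to_8bit(img([[10.0, 200.0], [200.0, 10.0]]))
        assert set(np.unique(out.pixels)) == {0, 255}

    @given(arrays(np.float64, (6, 7), elements=st.floats(0, 4000)))
    def test_idempotent_up_to_rounding(self, arr):
        once = ic.to_8bit(img(arr))
        twice = ic.to_8bit(once)
        assert np.array_equal(once.pixels, twice.pixels)


# ---------------------------------------------------------------------------
# edge magnitude / blur
# ---------------------------------------------------------------------------

class TestEdgeMagnitude:
    def test_constant_is_zero(self):
        out = ic.edge_magnitude(img(np.full((5, 5), 9.0)))
        assert np.allclose(out.pixels, 0.0)

    def test_too_small_rejected(self):
        with pytest.raises(ic.InvalidInputError):
            ic.edge_magnitude(img(np.ones((2, 5))))

    def test_matches_direct_convolution_everywhere(self, rng):
        arr = rng.uniform(0, 255, (12, 15))
        got = ic.edge_magnitude(img(arr)).pixels
        assert np.allclose(got, orc.sobel_magnitude_ref(arr))

    def test_vertical_step_response(self):
        arr = np.zeros((9, 9))
        arr[:, 5:] = 255.0
        got = ic.edge_magnitude(img(arr)).pixels
        assert np.allclose(got, orc.sobel_magnitude_ref(arr))

    def test_commutes_with_transpose(self, rng):
        arr = rng.uniform(0, 100, (8, 13))
        a = ic.edge_magnitude(img(arr.T)).pixels
        b = ic.edge_magnitude(img(arr)).pixels.T
        assert np.allclose(a, b)


class TestGaussianBlur:
    def test_sigma_zero_is_identity(self, rng):
        arr = rng.uniform(0, 10, (6, 6))
        assert np.array_equal(ic.gaussian_blur(img(arr), 0).pixels, arr)

    def test_constant_unchanged(self):
        out = ic.gaussian_blur(img(np.full((10, 10), 3.5)), 2.0)
        assert np.allclose(out.pixels, 3.5)

    def test_impulse_response_is_discrete_kernel(self):
        arr = np.zeros((41, 41))
        arr[20, 20] = 1.0
        out = ic.gaussian_blur(img(arr), 2.0).pixels
        k = orc.gaussian_kernel_1d(2.0)
        expected = np.outer(k, k)
        r = (len(k) - 1) // 2
        assert np.allclose(out[20 - r : 20 + r + 1, 20 - r : 20 + r + 1], expected)

    def test_negative_sigma_rejected(self):
        with pytest.raises(ic.InvalidInputError):
            ic.gaussian_blur(img(np.ones((4, 4))), -1)

    def test_commutes_with_transpose(self, rng):
        arr = rng.uniform(0, 50, (9, 14))
        a = ic.gaussian_blur(img(arr.T), 1.5).pixels
        b = ic.gaussian_blur(img(arr), 1.5).pixels.T
        assert np.allclose(a, b)


# ---------------------------------------------------------------------------
# thresholds
# ---------------------------------------------------------------------------

def _image_from_counts(counts):
    """Raster realising exactly this 256-bin histogram (padded into it)."""
    counts = counts.copy()
    total = counts.sum()
    side = int(np.ceil(np.sqrt(total)))
    counts[255] += side * side - total  # pad the top bin to a square raster
    vals = np.repeat(np.arange(256), counts).astype(np.uint8)
    return ic.CalibratedImage(vals.reshape(side, side)), counts


def _bimodal_counts(rng, lo_mean=60, hi_mean=190):
    n1, n2 = rng.integers(500, 2500, 2)
    a = np.clip(rng.normal(lo_mean, 12, n1), 0, 255)
    b = np.clip(rng.normal(hi_mean, 18, n2), 0, 255)
    counts = np.bincount(np.concatenate([a, b]).astype(np.uint8), minlength=256)
    counts[0] += 1
    counts[255] += 1  # pin the range so 8-bit rescaling is the identity
    return counts


class TestAutoThreshold:
    def test_constant_image_raises(self):
        with pytest.raises(ic.NoThresholdError):
            ic.auto_threshold(img(np.full((8, 8), 3.0)), "minimum")

    def test_minimum_lies_between_modes(self):
        px = np.concatenate([np.full(32, 10.0), np.full(32, 200.0)]).reshape(8, 8)
        t = ic.auto_threshold(img(px), "minimum")
        # levels rescale to {0, 255}; the cut must separate the two classes
        assert 0 <= t < 255

    @pytest.mark.parametrize("method,ref", [
        ("minimum", orc.minimum_threshold_ref),
        ("yen", orc.yen_threshold_ref),
        ("triangle", orc.triangle_threshold_ref),
    ])
    def test_matches_exhaustive_reference(self, rng, method, ref):
        for _ in range(8):
            image, counts = _image_from_counts(_bimodal_counts(rng))
            assert ic.auto_threshold(image, method) == ref(counts)

    def test_yen_agrees_with_skimage(self, rng):
        from skimage.filters import threshold_yen

        for _ in range(5):
            image, _ = _image_from_counts(_bimodal_counts(rng))
            assert ic.auto_threshold(image, "yen") == int(threshold_yen(image.pixels))

    def test_minimum_symmetric_bimodal_near_midpoint(self, rng):
        # symmetric two-mode histogram: cut within +-1 bin of the reference
        counts = np.zeros(256, np.int64)
        offsets = np.arange(-10, 11)
        weights = np.exp(-0.5 * (offsets / 4.0) ** 2) * 1000
        counts[64 + offsets] += weights.astype(np.int64)
        counts[192 + offsets] += weights.astype(np.int64)
        counts[0] += 1
        counts[255] += 1
        image, counts = _image_from_counts(counts)
        t = ic.auto_threshold(image, "minimum")
        assert abs(t - 128) <= 1
        assert t == orc.minimum_threshold_ref(counts)

    def test_triangle_unimodal_right_tail(self, rng):
        # unimodal peak with a long right tail: brute-force chord construction
        counts = np.zeros(256, np.int64)
        counts[20:40] = 5000
        counts[40:200] = np.linspace(3000, 10, 160).astype(np.int64)
        counts[0] += 1
        counts[255] += 1
        image, counts = _image_from_counts(counts)
        t = ic.auto_threshold(image, "triangle")
        assert t == orc.triangle_threshold_ref(counts)

    def test_classes_nonempty_for_any_nonconstant_image(self, rng):
        for _ in range(10):
            arr = rng.integers(0, 256, (16, 16)).astype(np.uint8)
            if arr.min() == arr.max():
                continue
            image = ic.CalibratedImage(arr)
            for method in ("minimum", "yen", "triangle", "otsu"):
                try:
                    t = ic.auto_threshold(image, method)
                except ic.NoThresholdError:
                    continue
                img8 = ic.to_8bit(image).pixels
                assert (img8 <= t).any() and (img8 > t).any()


class TestThresholdMask:
    def test_level_255_below_keeps_all(self):
        m = ic.threshold_mask(ic.to_8bit(img([[1.0, 2.0], [3.0, 4.0]])), 255, "below")
        assert m.pixels.all()

    def test_level_0_above_on_positive(self):
        image = ic.CalibratedImage(np.array([[1, 200], [90, 255]], np.uint8))
        assert ic.threshold_mask(image, 0, "above").pixels.all()

    def test_selects_exact_class(self):
        image = ic.CalibratedImage(np.array([[10, 200], [200, 10]], np.uint8))
        m = ic.threshold_mask(image, 100, "below")
        assert np.array_equal(m.pixels, image.pixels == 10)

    def test_requires_8bit(self):
        with pytest.raises(ic.InvalidInputError):
            ic.threshold_mask(img([[1.0, 2.0]] * 2), 100)


# ---------------------------------------------------------------------------
# binary morphology
# ---------------------------------------------------------------------------

class TestOpenMask:
    def test_small_speck_removed(self):
        m = np.zeros((64, 64), bool)
        m[30:32, 30:33] = True  # 5-ish px speck: no radius-20 disk fits
        out = ic.open_mask(ic.BinaryMask(m), 20)
        assert not out.pixels.any()

    def test_full_mask_unchanged(self):
        m = np.ones((32, 32), bool)
        assert ic.open_mask(ic.BinaryMask(m), 20).pixels.all()

    def test_band_survives_specks_removed(self, rng):
        m = np.zeros((80, 260), bool)
        m[:, 30:230] = True  # 200-px-wide band
        speck_rows = rng.integers(5, 75, 6)
        speck_cols = rng.integers(240, 255, 6)
        for r, c in zip(speck_rows, speck_cols):
            m[r : r + 2, c : c + 2] = True
        out = ic.open_mask(ic.BinaryMask(m), 20).pixels
        band = np.zeros_like(m)
        band[:, 30:230] = True
        assert np.array_equal(out, orc.disk_opening_ref(m, 20))
        assert np.array_equal(out, band)

    def test_matches_brute_force_on_random_masks(self, rng):
        for _ in range(4):
            m = rng.random((32, 32)) < 0.55
            for radius in (1, 2, 3.5):
                got = ic.open_mask(ic.BinaryMask(m), radius).pixels
                assert np.array_equal(got, orc.disk_opening_ref(m, radius))

    @given(arrays(np.bool_, (16, 16)))
    def test_antiextensive(self, m):
        out = ic.open_mask(ic.BinaryMask(m), 2).pixels
        assert not (out & ~m).any()

    def test_monotone_in_mask(self, rng):
        a = rng.random((24, 24)) < 0.4
        b = a | (rng.random((24, 24)) < 0.3)
        oa = ic.open_mask(ic.BinaryMask(a), 2).pixels
        ob = ic.open_mask(ic.BinaryMask(b), 2).pixels
        assert not (oa & ~ob).any()

    def test_commutes_with_transpose(self, rng):
        m = rng.random((20, 28)) < 0.6
        a = ic.open_mask(ic.BinaryMask(m.T), 3).pixels
        b = ic.open_mask(ic.BinaryMask(m), 3).pixels.T
        assert np.array_equal(a, b)


class TestBinaryPolish:
    def test_fill_holes_closes_annulus(self):
        yy, xx = np.mgrid[0:41, 0:41]
        d = np.hypot(yy - 20, xx - 20)
        ring = (d <= 15) & (d >= 10)
        out = ic.binary_polish(ic.BinaryMask(ring), ["fill_holes"]).pixels
        assert out[20, 20]
        assert out.sum() == (d <= 15).sum()

    def test_empty_steps_is_identity(self, rng):
        m = rng.random((10, 10)) < 0.5
        assert np.array_equal(ic.binary_polish(ic.BinaryMask(m), []).pixels, m)

    def test_erode_dilate_kills_isolated_pixel(self):
        m = np.zeros((15, 15), bool)
        m[7, 7] = True
        out = ic.binary_polish(ic.BinaryMask(m), ["erode", "dilate"]).pixels
        assert not out.any()

    def test_unknown_step_rejected(self):
        with pytest.raises(ic.InvalidInputError):
            ic.binary_polish(ic.BinaryMask(np.ones((3, 3), bool)), ["blur"])


# ---------------------------------------------------------------------------
# rolling ball
# ---------------------------------------------------------------------------

class TestRollingBall:
    def test_constant_maps_to_zero(self):
        out = ic.rolling_ball_subtract(img(np.full((20, 20), 80.0)), 10)
        assert np.allclose(out.pixels, 0.0)

    def test_matches_explicit_grey_opening(self, rng):
        arr = rng.uniform(0, 200, (20, 20))
        got = ic.rolling_ball_subtract(img(arr), 4.0).pixels
        bg = orc.rolling_ball_background_ref(arr, 4.0)
        assert np.allclose(got, np.clip(arr - bg, 0, None))

    def test_spot_on_ramp_amplitude_preserved(self):
        yy, xx = np.mgrid[0:60, 0:60]
        ramp = 0.2 * xx
        arr = ramp.copy()
        arr[29:32, 29:32] += 100.0  # 3-px bright spot, much narrower than the ball
        out = ic.rolling_ball_subtract(img(arr), 10).pixels
        assert abs(out[30, 30] - 100.0) <= 10.0

    def test_smooth_background_residual_small(self):
        yy, xx = np.mgrid[0:80, 0:80]
        bg = 100.0 + 20.0 * np.sin(xx / 40.0) + 10.0 * np.cos(yy / 50.0)
        out = ic.rolling_ball_subtract(img(bg), 10).pixels
        assert out.max() < 0.05 * (bg.max() - bg.min() + 1e-9) + 1.0

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ic.InvalidInputError):
            ic.rolling_ball_subtract(img(np.ones((5, 5))), 0)

    def test_commutes_with_transpose(self, rng):
        arr = rng.uniform(0, 150, (16, 22))
        a = ic.rolling_ball_subtract(img(arr.T), 3).pixels
        b = ic.rolling_ball_subtract(img(arr), 3).pixels.T
        assert np.allclose(a, b)


# ---------------------------------------------------------------------------
# find_maxima
# ---------------------------------------------------------------------------

def _gauss_spot(shape, r, c, amp, sigma):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return amp * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma**2))


class TestFindMaxima:
    def test_constant_gives_empty(self):
        assert ic.find_maxima(img(np.full((10, 10), 4.0)), 0) == []

    def test_two_blobs_two_peaks(self):
        arr = _gauss_spot((64, 64), 20, 20, 100, 3) + _gauss_spot((64, 64), 20, 50, 100, 3)
        peaks = ic.find_maxima(img(np.round(arr)), 10)
        assert len(peaks) == 2
        found = sorted((p.row, p.col) for p in peaks)
        for (r, c), (tr, tc) in zip(found, [(20, 20), (20, 50)]):
            assert np.hypot(r - tr, c - tc) <= 1.0

    def test_shoulder_below_tolerance_suppressed(self):
        arr = _gauss_spot((50, 50), 25, 20, 100, 4)
        arr += _gauss_spot((50, 50), 25, 30, 5, 2)  # small shoulder bump
        peaks = ic.find_maxima(img(np.round(arr * 10) / 10), 10)
        assert len(peaks) == 1

    def test_plateau_reports_centroid(self):
        arr = np.zeros((11, 11))
        arr[4:7, 4:7] = 50.0  # 3x3 plateau centred at (5, 5)
        (peak,) = ic.find_maxima(img(arr), 5)
        assert (peak.row, peak.col) == (5.0, 5.0)

    def test_matches_bruteforce_oracle_on_random_rasters(self, rng):
        for _ in range(8):
            px = rng.integers(0, 64, (32, 32)).astype(float)
            for tol in (0.0, 5.0):
                got = [
                    (p.row, p.col, p.height, p.prominence)
                    for p in ic.find_maxima(img(px), tol)
                ]
                assert got == orc.prominence_peaks_ref(px, tol)

    def test_count_monotone_in_tolerance(self, rng):
        px = rng.integers(0, 256, (48, 48)).astype(float)
        counts = [len(ic.find_maxima(img(px), t)) for t in (0, 5, 20, 80, 300)]
        assert counts == sorted(counts, reverse=True)

    def test_sorted_by_descending_height(self, rng):
        px = rng.integers(0, 256, (32, 32)).astype(float)
        heights = [p.height for p in ic.find_maxima(img(px), 5)]
        assert heights == sorted(heights, reverse=True)


# ---------------------------------------------------------------------------
# watershed + particles
# ---------------------------------------------------------------------------

def _disk_mask(shape, centers, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    m = np.zeros(shape, bool)
    for r, c in centers:
        m |= np.hypot(yy - r, xx - c) <= radius
    return m


class TestWatershedSplit:
    def test_single_disk_one_label(self):
        m = _disk_mask((40, 40), [(20, 20)], 10)
        assert ic.watershed_split(ic.BinaryMask(m)).n_labels == 1

    def test_empty_mask_no_labels(self):
        lm = ic.watershed_split(ic.BinaryMask(np.zeros((10, 10), bool)))
        assert lm.n_labels == 0

    def test_overlapping_disks_split_in_two(self):
        m = _disk_mask((50, 60), [(25, 22), (25, 37)], 10)
        lm = ic.watershed_split(ic.BinaryMask(m))
        assert lm.n_labels == 2

    def test_never_merges_disconnected_components(self, rng):
        from scipy import ndimage as ndi

        m = rng.random((48, 48)) < 0.35
        lm = ic.watershed_split(ic.BinaryMask(m))
        _, n_in = ndi.label(m, structure=np.ones((3, 3), bool))
        assert lm.n_labels >= n_in
        # every output label stays inside one input component
        lab_in, _ = ndi.label(m, structure=np.ones((3, 3), bool))
        for k in range(1, lm.n_labels + 1):
            parents = np.unique(lab_in[lm.pixels == k])
            assert len(parents) == 1

    def test_labels_contiguous(self):
        m = _disk_mask((60, 90), [(20, 20), (20, 60), (45, 40)], 8)
        lm = ic.watershed_split(ic.BinaryMask(m))
        present = np.unique(lm.pixels)
        assert np.array_equal(present, np.arange(0, lm.n_labels + 1))


class TestAnalyzeParticles:
    def _label_map(self):
        lab = np.zeros((40, 40), np.int32)
        lab[0:5, 0:10] = 1     # 50 px
        lab[10:20, 0:15] = 2   # 150 px
        lab[20:40, 10:30] = 3  # 400 px
        return ic.LabelMap(lab, px_size=2.0)

    def test_min_area_filter(self):
        parts = ic.analyze_particles(self._label_map(), 100)
        assert [p.label for p in parts] == [2, 3]

    def test_empty_map(self):
        assert ic.analyze_particles(ic.LabelMap(np.zeros((5, 5), np.int32))) == []

    def test_area_conservation_and_units(self):
        lm = self._label_map()
        parts = ic.analyze_particles(lm, 0)
        assert sum(p.area_px for p in parts) == int((lm.pixels > 0).sum())
        for p in parts:
            assert p.area_um2 == p.area_px * 4.0

    def test_centroid_exact(self):
        lab = np.zeros((10, 10), np.int32)
        lab[2:4, 4:8] = 1
        (p,) = ic.analyze_particles(ic.LabelMap(lab))
        assert p.centroid == (2.5, 5.5)
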