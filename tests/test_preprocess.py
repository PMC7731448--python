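"""Calibration, Otsu segmentation, hot-spot/rim removal, spectrum extraction."""

import numpy as np
import pytest
import scipy.ndimage as ndi
from skimage.morphology import disk

from seedspec import (
    HyperCube,
    PhantomConfig,
    ReferenceFrame,
    SeedMask,
    SegmentationConfig,
    build_roi,
    correct_reflectance,
    extract_hotspot,
    extract_mean_spectra,
    otsu_threshold,
    process_scene,
    render_scene,
    segment_seeds,
)
from seedspec.preprocess import (
    DegenerateImageError,
    DegenerateReferenceError,
    SegmentationError,
)


def _cube(data, kind="raw"):
    data = np.asarray(data, dtype=float)
    wl = np.linspace(400, 1000, data.shape[2])
    return HyperCube(data, wl, kind=kind)


# ---------------------------------------------------------------------------
# Reflectance calibration
# ---------------------------------------------------------------------------

class TestCorrectReflectance:
    def setup_method(self):
        rng = np.random.default_rng(0)
        self.white = rng.uniform(3000, 4000, size=(4, 4, 3))
        self.dark = rng.uniform(50, 100, size=(4, 4, 3))

    def test_raw_equals_white_gives_ones(self):
        out = correct_reflectance(
            _cube(self.white), ReferenceFrame(self.white), ReferenceFrame(self.dark, role="dark")
        )
        np.testing.assert_array_equal(out.data, np.ones_like(self.white))
        assert out.kind == "reflectance"

    def test_raw_equals_dark_gives_zeros(self):
        out = correct_reflectance(
            _cube(self.dark), ReferenceFrame(self.white), ReferenceFrame(self.dark, role="dark")
        )
        np.testing.assert_array_equal(out.data, np.zeros_like(self.dark))

    def test_midpoint_gives_half(self):
        mid = (self.white + self.dark) / 2
        out = correct_reflectance(
            _cube(mid), ReferenceFrame(self.white), ReferenceFrame(self.dark, role="dark")
        )
        np.testing.assert_allclose(out.data, 0.5, rtol=0, atol=1e-15)

    def test_degenerate_reference_names_position(self):
        white = self.white.copy()
        white[1, 2, 0] = self.dark[1, 2, 0]
        with pytest.raises(DegenerateReferenceError, match=r"\(1, 2, 0\)"):
            correct_reflectance(
                _cube(self.dark), ReferenceFrame(white), ReferenceFrame(self.dark, role="dark")
            )

    def test_affine_gain_invariance(self):
        """Scaling raw, white and dark by one positive gain leaves R fixed."""
        rng = np.random.default_rng(1)
        raw = rng.uniform(100, 3000, size=(4, 4, 3))
        base = correct_reflectance(
            _cube(raw), ReferenceFrame(self.white), ReferenceFrame(self.dark, role="dark")
        )
        for gain in (0.25, 3.7, 1e3):
            scaled = correct_reflectance(
                _cube(raw * gain),
                ReferenceFrame(self.white * gain),
                ReferenceFrame(self.dark * gain, role="dark"),
            )
            np.testing.assert_allclose(scaled.data, base.data, rtol=1e-12)


# ---------------------------------------------------------------------------
# Otsu threshold
# ---------------------------------------------------------------------------

def _otsu_brute_force(image, nbins=256):
    """Exhaustive search over candidate thresholds (bin centers) maximizing
    the between-class variance of the 256-bin histogram."""
    counts, edges = np.histogram(image.ravel(), bins=nbins)
    centers = (edges[:-1] + edges[1:]) / 2
    best_t, best_var = None, -1.0
    total = counts.sum()
    for cut in range(1, nbins):
        w0 = counts[:cut].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (counts[:cut] * centers[:cut]).sum() / w0
        mu1 = (counts[cut:] * centers[cut:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var = var
            best_t = centers[cut - 1]
    return best_t


class TestOtsu:
    def test_bimodal_image_split_exactly(self):
        img = np.concatenate([np.full(128, 0.2), np.full(128, 0.8)]).reshape(16, 16)
        t = otsu_threshold(img)
        assert 0.2 < t < 0.8
        np.testing.assert_array_equal(img > t, img == 0.8)

    def test_binary_image_reproduced(self):
        rng = np.random.default_rng(2)
        img = (rng.random((20, 20)) > 0.5).astype(float)
        t = otsu_threshold(img)
        np.testing.assert_array_equal(img > t, img == 1.0)

    def test_three_level_matches_brute_force(self):
        rng = np.random.default_rng(3)
        img = rng.choice([0.1, 0.5, 0.9], p=[0.5, 0.25, 0.25], size=(32, 32))
        assert otsu_threshold(img) == pytest.approx(_otsu_brute_force(img))

    @pytest.mark.parametrize("seed", range(5))
    def test_random_images_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        img = rng.normal(0.4, 0.2, size=(25, 25))
        assert otsu_threshold(img) == pytest.approx(_otsu_brute_force(img))
        assert img.min() < otsu_threshold(img) < img.max()

    def test_constant_image_rejected(self):
        with pytest.raises(DegenerateImageError):
            otsu_threshold(np.full((8, 8), 0.5))


# ---------------------------------------------------------------------------
# Segmentation and ROI
# ---------------------------------------------------------------------------

def _scene_with_ellipses(centers, axes=(8, 6), shape=(80, 80), value=0.7):
    img = np.full(shape, 0.05)
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    for r0, c0 in centers:
        img[((rr - r0) / axes[0]) ** 2 + ((cc - c0) / axes[1]) ** 2 <= 1] = value
    return img


class TestSegmentSeeds:
    cfg = SegmentationConfig()

    def test_three_ellipses_three_components(self):
        img = _scene_with_ellipses([(20, 20), (20, 60), (60, 40)])
        mask = segment_seeds(img, self.cfg)
        assert ndi.label(mask.mask)[1] == 3

    def test_speck_removed_by_opening(self):
        img = _scene_with_ellipses([(20, 20)])
        img[60, 60] = 0.9  # isolated bright pixel
        mask = segment_seeds(img, self.cfg)
        assert ndi.label(mask.mask)[1] == 1
        assert not mask.mask[60, 60]

    def test_only_speck_raises_no_seed(self):
        img = np.full((40, 40), 0.05)
        img[20, 20] = 0.9
        with pytest.raises(SegmentationError):
            segment_seeds(img, self.cfg)

    def test_thin_bridge_broken(self):
        """A 1-px bridge between two seeds is thinner than the disk element,
        so opening must split them; cross-checked against the morphology
        oracle on the explicit grid."""
        img = _scene_with_ellipses([(20, 15), (20, 55)])
        img[20, 15:56] = np.maximum(img[20, 15:56], 0.7)  # 1-px bridge
        mask = segment_seeds(img, self.cfg)
        assert ndi.label(mask.mask)[1] == 2
        oracle = ndi.binary_opening(img > otsu_threshold(img), structure=disk(2))
        assert ndi.label(oracle)[1] == 2


class TestHotspotAndRoi:
    cfg = SegmentationConfig(hotspot_method="quantile", hotspot_quantile=0.8)

    def _seed_with_core(self):
        img = _scene_with_ellipses([(20, 20)], axes=(10, 8), shape=(41, 41), value=0.5)
        rr, cc = np.ogrid[:41, :41]
        core = (rr - 20) ** 2 + (cc - 20) ** 2 <= 3**2
        img[core] = 0.9
        return img, core

    def test_quantile_hotspot_recovers_core_exactly(self):
        img, core = self._seed_with_core()
        mask = segment_seeds(img, self.cfg)
        hot = extract_hotspot(img, mask, self.cfg)
        np.testing.assert_array_equal(hot, core & mask.mask)

    def test_second_otsu_hotspot_recovers_core(self):
        img, core = self._seed_with_core()
        cfg = SegmentationConfig(hotspot_method="second_otsu")
        mask = segment_seeds(img, cfg)
        hot = extract_hotspot(img, mask, cfg)
        np.testing.assert_array_equal(hot, core & mask.mask)

    def test_uniform_seed_has_empty_hotspot(self):
        img = _scene_with_ellipses([(20, 20)])
        mask = segment_seeds(img, self.cfg)
        assert not extract_hotspot(img, mask, self.cfg).any()

    def test_hotspot_subset_of_mask(self):
        rng = np.random.default_rng(4)
        img = _scene_with_ellipses([(20, 20), (60, 60)], shape=(81, 81))
        img += rng.normal(0, 0.02, img.shape)
        mask = segment_seeds(img, self.cfg)
        hot = extract_hotspot(img, mask, self.cfg)
        assert not (hot & ~mask.mask).any()

    def test_roi_identity_when_nothing_removed(self):
        img = _scene_with_ellipses([(20, 20)])
        cfg = SegmentationConfig(edge_erosion_px=0)
        mask = segment_seeds(img, cfg)
        roi = build_roi(mask, np.zeros_like(mask.mask), cfg)
        np.testing.assert_array_equal(roi.mask, mask.mask)
        assert roi.stage == "roi"

    def test_erosion_matches_scipy_oracle(self):
        """ROI of an 11-px disk with 2-px edge erosion equals the erosion of
        the explicit pixel grid computed by an independent implementation
        (the concentric 7-px-diameter disk region)."""
        mask_arr = np.zeros((21, 21), dtype=bool)
        mask_arr[5:16, 5:16] = disk(5).astype(bool)  # 11-px-diameter disk
        cfg = SegmentationConfig(edge_erosion_px=2, min_roi_px=1)
        roi = build_roi(SeedMask(mask_arr, "opened"), np.zeros_like(mask_arr), cfg)
        oracle = ndi.binary_erosion(mask_arr, structure=disk(2), border_value=0)
        np.testing.assert_array_equal(roi.mask, oracle)
        # the oracle itself is the concentric disk of diameter 7
        inner = np.zeros((21, 21), dtype=bool)
        inner[7:14, 7:14] = disk(3).astype(bool)
        np.testing.assert_array_equal(oracle, inner)

    def test_roi_disjoint_from_hotspot_and_nested_in_opened(self):
        rng = np.random.default_rng(5)
        for seed in range(5):
            cfg = PhantomConfig(
                n_varieties=3, seeds_per_variety=4, n_bands=20,
                scene_seeds=4, rng_seed=seed,
            )
            raw, white, dark, _ = render_scene(cfg)
            refl = correct_reflectance(raw, white, dark)
            band = refl.data[:, :, refl.band_nearest(640)]
            seg = SegmentationConfig(
                hotspot_method="quantile", hotspot_quantile=0.9, min_roi_px=1
            )
            opened = segment_seeds(band, seg)
            hot = extract_hotspot(band, opened, seg)
            roi = build_roi(opened, hot, seg)
            binarized = band > otsu_threshold(band)
            assert not (roi.mask & hot).any()
            assert not (roi.mask & ~opened.mask).any()
            assert not (opened.mask & ~binarized).any()


# ---------------------------------------------------------------------------
# Mean-spectrum extraction
# ---------------------------------------------------------------------------

class TestExtractMeanSpectra:
    def _roi_two_seeds(self, shape=(20, 20)):
        m = np.zeros(shape, dtype=bool)
        m[2:6, 2:6] = True
        m[12:16, 12:16] = True
        return SeedMask(m, "roi")

    def test_constant_seed_recovers_spectrum(self):
        v = np.array([0.1, 0.2, 0.3])
        data = np.tile(v, (20, 20, 1))
        roi = SeedMask(np.zeros((20, 20), dtype=bool), "roi")
        roi.mask[5:10, 5:10] = True
        table = extract_mean_spectra(_cube(data, kind="reflectance"), roi)
        np.testing.assert_allclose(table.spectra, v[None, :])

    def test_two_seeds_two_rows_raster_order(self):
        u, v = np.array([0.1, 0.4]), np.array([0.3, 0.2])
        data = np.zeros((20, 20, 2))
        data[2:6, 2:6] = u
        data[12:16, 12:16] = v
        table = extract_mean_spectra(_cube(data, kind="reflectance"), self._roi_two_seeds())
        np.testing.assert_allclose(table.spectra[0], u)
        np.testing.assert_allclose(table.spectra[1], v)

    def test_half_and_half_averages(self):
        u, w = np.array([0.2, 0.6]), np.array([0.4, 0.0])
        data = np.zeros((10, 10, 2))
        data[2:4, 2:6] = u
        data[4:6, 2:6] = w
        roi = SeedMask(np.zeros((10, 10), dtype=bool), "roi")
        roi.mask[2:6, 2:6] = True
        table = extract_mean_spectra(_cube(data, kind="reflectance"), roi)
        np.testing.assert_allclose(table.spectra[0], (u + w) / 2)

    def test_means_bounded_by_pixel_range(self, rng):
        data = rng.random((12, 12, 5))
        roi = self._roi_two_seeds(shape=(12, 12))
        roi.mask[12:16, 12:16] = False
        roi = SeedMask(roi.mask[:12, :12], "roi")
        table = extract_mean_spectra(_cube(data, kind="reflectance"), roi)
        px = data[roi.mask]
        assert np.all(table.spectra >= px.min(axis=0) - 1e-12)
        assert np.all(table.spectra <= px.max(axis=0) + 1e-12)


def test_hotspot_removal_improves_recovery():
    """On phantom scenes with specular contamination, extracted means are
    closer (L2) to the true seed spectra with hot-spot/rim removal than
    without."""
    cfg = PhantomConfig(
        n_varieties=5, seeds_per_variety=5, n_bands=40, scene_seeds=5, rng_seed=11
    )
    raw, white, dark, truth = render_scene(cfg)
    refl = correct_reflectance(raw, white, dark)
    with_removal, _ = process_scene(raw, white, dark, SegmentationConfig())
    band = refl.data[:, :, refl.band_nearest(640)]
    opened = segment_seeds(band, SegmentationConfig())
    naive = extract_mean_spectra(refl, SeedMask(opened.mask, "roi"))
    err_with = np.linalg.norm(with_removal.spectra - truth.true_spectra)
    err_without = np.linalg.norm(naive.spectra - truth.true_spectra)
    assert err_with < err_without
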