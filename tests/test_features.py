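import numpy as np
import pytest

from pathomics.features import (colocalization, extract_tile_features, glcm,
                                granularity_spectrum, haralick,
                                haralick_from_glcm, image_quality,
                                intensity_features, neighbor_features,
                                radial_distribution, shape_features,
                                zernike_indices, zernike_magnitudes,
                                zernike_shape)
from pathomics.segmentation import LabelMask

from oracles import (naive_granularity, naive_haralick, naive_intensity_stats,
                     naive_neighbors, naive_radial, zernike_quadrature)


def _disk_mask(size, cy, cx, r, label=1):
    yy, xx = np.mgrid[0:size, 0:size]
    m = np.zeros((size, size), np.int32)
    m[np.hypot(yy - cy, xx - cx) <= r] = label
    return m


class TestIntensity:
    def test_constant_object(self):
        m = LabelMask(_disk_mask(20, 10, 10, 5))
        img = np.full((20, 20), 0.7)
        t = intensity_features(m, img, prefix="x")
        area = (m.labels == 1).sum()
        assert t.loc[1, "x_integrated"] == pytest.approx(0.7 * area)
        assert t.loc[1, "x_std"] == pytest.approx(0.0, abs=1e-12)
        assert t.loc[1, "x_mean"] == pytest.approx(0.7)

    def test_two_pixel_object(self):
        m = np.zeros((4, 4), np.int32)
        m[1, 1] = m[1, 2] = 1
        img = np.zeros((4, 4))
        img[1, 1], img[1, 2] = 0.2, 0.4
        t = intensity_features(LabelMask(m), img, prefix="x")
        assert t.loc[1, "x_mean"] == pytest.approx(0.3)
        assert t.loc[1, "x_min"] == pytest.approx(0.2)
        assert t.loc[1, "x_max"] == pytest.approx(0.4)

    def test_against_bruteforce(self):
        rng = np.random.default_rng(0)
        m = _disk_mask(24, 11, 13, 6)
        img = rng.uniform(0, 1, (24, 24))
        t = intensity_features(LabelMask(m), img, prefix="x")
        oracle = naive_intensity_stats(m, img, 1)
        for name, val in oracle.items():
            assert t.loc[1, f"x_{name}"] == pytest.approx(val, abs=1e-9), name


class TestRadialDistribution:
    def test_uniform_disk(self):
        m = LabelMask(_disk_mask(41, 20, 20, 15))
        img = np.full((41, 41), 0.5)
        t = radial_distribution(m, img, prefix="r")
        for b in range(1, 5):
            assert t.loc[1, f"r_meanfrac_{b}"] == pytest.approx(1.0)
            assert t.loc[1, f"r_radialcv_{b}"] == pytest.approx(0.0)

    def test_point_mass_at_centroid(self):
        m = LabelMask(_disk_mask(21, 10, 10, 6))
        img = np.zeros((21, 21))
        img[10, 10] = 3.0
        t = radial_distribution(m, img, prefix="r")
        assert t.loc[1, "r_fracatd_1"] == pytest.approx(1.0)
        for b in range(2, 5):
            assert t.loc[1, f"r_fracatd_{b}"] == pytest.approx(0.0)

    def test_against_binning_oracle(self):
        rng = np.random.default_rng(1)
        m = np.zeros((30, 30), np.int32)
        m[8:22, 5:25] = 1   # eccentric blob
        m[14:20, 20:28] = 1
        img = rng.uniform(0, 1, (30, 30))
        t = radial_distribution(LabelMask(m), img, prefix="r")
        oracle = naive_radial(m, img, 1)
        for b in range(4):
            frac, mean_frac, cv = oracle[b]
            assert t.loc[1, f"r_fracatd_{b+1}"] == pytest.approx(frac, abs=1e-9)
            assert t.loc[1, f"r_meanfrac_{b+1}"] == pytest.approx(mean_frac, abs=1e-9)
            assert t.loc[1, f"r_radialcv_{b+1}"] == pytest.approx(cv, abs=1e-9)


class TestHaralick:
    def test_constant_region_convention(self):
        out = haralick(np.full((8, 8), 0.3))
        names = ["asm", "contrast", "correlation", "variance", "idm",
                 "sum_average", "sum_variance", "sum_entropy", "entropy",
                 "difference_variance", "difference_entropy", "infomeas1",
                 "infomeas2"]
        d = dict(zip(names, out))
        assert d["difference_entropy"] == 0.0
        assert d["contrast"] == 0.0
        assert d["correlation"] == 0.0

    def test_checkerboard_glcm(self):
        cb = np.array([[0, 1], [1, 0]])
        p = glcm(cb, (0, 1), 2)
        assert p[0, 1] + p[1, 0] == pytest.approx(1.0)
        f = haralick_from_glcm(p)
        assert f[1] == pytest.approx(1.0)  # contrast

    def test_against_literature_oracle(self):
        rng = np.random.default_rng(2)
        img = rng.uniform(0, 1, (16, 16))
        region = np.ones((16, 16), bool)
        ours = haralick(img, region)
        ref = naive_haralick(img, region)
        assert np.abs(ours - ref).max() < 1e-6

    def test_masked_region_against_oracle(self):
        rng = np.random.default_rng(3)
        img = rng.uniform(0, 1, (16, 16))
        region = _disk_mask(16, 8, 8, 6).astype(bool)
        assert np.abs(haralick(img, region) - naive_haralick(img, region)).max() < 1e-6


class TestZernike:
    def test_full_disk_orthogonality(self):
        yy, xx = np.mgrid[0:201, 0:201]
        disk = (yy - 100) ** 2 + (xx - 100) ** 2 <= 100 ** 2
        z = zernike_magnitudes(disk)
        idx = zernike_indices(9)
        assert z[0] > 0
        assert max(z[i] for i, (n, m) in enumerate(idx) if n >= 1) < 1e-3

    def test_rotation_invariance(self):
        blob = np.zeros((40, 40), bool)
        blob[10:30, 12:25] = True
        blob[15:20, 25:32] = True
        d = np.abs(zernike_magnitudes(blob) - zernike_magnitudes(np.rot90(blob)))
        assert d.max() < 1e-3

    def test_ellipse_against_quadrature_oracle(self):
        yy, xx = np.mgrid[0:231, 0:231]
        ell = (((yy - 115) / 100.0) ** 2 + ((xx - 115) / 60.0) ** 2) <= 1
        d = np.abs(zernike_magnitudes(ell) - zernike_quadrature(ell))
        assert d.max() < 1e-3

    def test_count_at_degree_nine(self):
        m = LabelMask(_disk_mask(21, 10, 10, 6))
        t = zernike_shape(m, max_degree=9, prefix="z")
        assert t.shape[1] == 30


class TestShape:
    def test_square(self):
        m = np.zeros((14, 14), np.int32)
        m[2:12, 2:12] = 1
        t = shape_features(LabelMask(m), prefix="s")
        assert t.loc[1, "s_area"] == 100
        assert t.loc[1, "s_extent"] == pytest.approx(1.0)

    def test_circle_form_factor(self):
        m = _disk_mask(121, 60, 60, 50)
        t = shape_features(LabelMask(m), prefix="s")
        assert t.loc[1, "s_form_factor"] > 0.95

    def test_convex_solidity(self):
        m = _disk_mask(41, 20, 20, 14)
        t = shape_features(LabelMask(m), prefix="s")
        assert t.loc[1, "s_solidity"] == pytest.approx(1.0, abs=0.02)


class TestNeighbors:
    def test_single_object(self):
        t = neighbor_features(LabelMask(_disk_mask(30, 15, 15, 5)), 5.0,
                              prefix="n")
        assert t.loc[1, "n_count"] == 0
        assert t.loc[1, "n_percent_touching"] == 0.0

    def test_pair_within_distance(self):
        m = np.zeros((20, 30), np.int32)
        m[8:12, 5:10] = 1
        m[8:12, 13:18] = 2   # 3 px gap
        t = neighbor_features(LabelMask(m), 5.0, prefix="n")
        assert t.loc[1, "n_count"] == 1
        assert t.loc[2, "n_count"] == 1

    def test_constellation_against_bruteforce(self):
        rng = np.random.default_rng(4)
        m = np.zeros((40, 40), np.int32)
        for i, (cy, cx, r) in enumerate(
                [(8, 8, 3), (12, 20, 4), (30, 10, 3), (28, 30, 5), (8, 33, 2)],
                start=1):
            yy, xx = np.mgrid[0:40, 0:40]
            m[(np.hypot(yy - cy, xx - cx) <= r) & (m == 0)] = i
        t = neighbor_features(LabelMask(m), 6.0, prefix="n")
        oracle = naive_neighbors(m, 6.0)
        for k, (count, pct) in oracle.items():
            assert t.loc[k, "n_count"] == count
            assert t.loc[k, "n_percent_touching"] == pytest.approx(pct)


class TestGranularity:
    def test_blank_image(self):
        assert (granularity_spectrum(np.zeros((16, 16)), 4) == 0).all()

    def test_disks_concentrate_at_their_radius(self):
        img = np.zeros((48, 48))
        for cy, cx in ((12, 12), (12, 36), (36, 12), (36, 36)):
            yy, xx = np.mgrid[0:48, 0:48]
            img[np.hypot(yy - cy, xx - cx) <= 3] = 1.0
        spec = granularity_spectrum(img, 6)
        assert np.argmax(spec) + 1 in (3, 4)
        assert spec.sum() == pytest.approx(100.0, abs=1e-6)

    def test_spectrum_bounds(self):
        rng = np.random.default_rng(5)
        spec = granularity_spectrum(rng.uniform(0, 1, (32, 32)), 8)
        assert (spec >= 0).all()
        assert spec.sum() <= 100.0 + 1e-9

    def test_against_bruteforce_opening(self):
        rng = np.random.default_rng(6)
        img = np.round(rng.uniform(0, 1, (20, 20)), 2)
        ours = granularity_spectrum(img, 3)
        ref = naive_granularity(img, 3)
        assert np.abs(ours - ref).max() < 1e-9


class TestColocalization:
    def test_identical_channels(self):
        rng = np.random.default_rng(7)
        h = rng.uniform(0, 1, (32, 32))
        out = colocalization(h, h.copy())
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["overlap"] == pytest.approx(1.0)

    def test_independent_channels(self):
        rng = np.random.default_rng(8)
        out = colocalization(rng.uniform(0, 1, (1000, 1000)),
                             rng.uniform(0, 1, (1000, 1000)))
        assert abs(out["pearson_r"]) < 0.05

    def test_hand_computed_five_pixels(self):
        h = np.array([[0.1, 0.2, 0.3, 0.4, 0.5]])
        e = np.array([[0.5, 0.4, 0.3, 0.2, 0.1]])
        out = colocalization(h, e)
        # Pearson r of a perfectly anti-ordered pair is -1
        assert out["pearson_r"] == pytest.approx(-1.0)
        overlap = (h * e).sum() / np.sqrt((h ** 2).sum() * (e ** 2).sum())
        assert out["overlap"] == pytest.approx(float(overlap))

    def test_zero_variance_convention(self):
        out = colocalization(np.full((4, 4), 0.5), np.zeros((4, 4)))
        assert out["pearson_r"] == 0.0


class TestImageQuality:
    def test_blur_lowers_focus(self, clean_tile):
        from scipy import ndimage

        tile, _ = clean_tile
        sharp = image_quality(tile.pixels)["focus_score"]
        blurred = ndimage.gaussian_filter(tile.pixels.astype(float), (5, 5, 0))
        assert image_quality(blurred)["focus_score"] < sharp

    def test_saturated_tile(self):
        out = image_quality(np.full((16, 16, 3), 255, np.uint8))
        assert out["percent_saturated"] == 100.0

    def test_checkerboard_sharper_than_constant(self):
        cb = np.indices((32, 32)).sum(axis=0) % 2 * 255.0
        cb = np.stack([cb] * 3, axis=-1)
        flat = np.full((32, 32, 3), 128.0)
        assert (image_quality(cb)["focus_score"]
                > image_quality(flat)["focus_score"])


class TestTileAssembly:
    def test_all_values_finite(self, clean_tile, clean_pair, segmented):
        tile, _ = clean_tile
        img, nuc, cyto = extract_tile_features(tile, clean_pair, segmented,
                                               n_scales=4)
        for table in (img, nuc, cyto):
            assert np.isfinite(table.to_numpy(dtype=float)).all()
        assert len(nuc) == segmented.nuclei.n_objects

    def test_translation_invariance(self):
        rng = np.random.default_rng(9)
        img = rng.uniform(0, 1, (40, 40))
        m = _disk_mask(40, 14, 14, 6)
        shifted_img = np.roll(img, (7, 5), axis=(0, 1))
        shifted_m = np.roll(m, (7, 5), axis=(0, 1))
        for fn in (lambda mm, ii: intensity_features(LabelMask(mm), ii, "x"),
                   lambda mm, ii: radial_distribution(LabelMask(mm), ii, prefix="x"),
                   lambda mm, ii: shape_features(LabelMask(mm), "x"),
                   lambda mm, ii: zernike_shape(LabelMask(mm), prefix="x")):
            a = fn(m, img).loc[1]
            b = fn(shifted_m, shifted_img).loc[1]
            assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)

    def test_rotation_invariants(self):
        m = np.zeros((30, 30), np.int32)
        m[8:20, 10:17] = 1
        m[12:16, 17:24] = 1
        a = shape_features(LabelMask(m), "s").loc[1]
        b = shape_features(LabelMask(np.rot90(m).copy()), "s").loc[1]
        for col in ("s_area", "s_solidity", "s_eccentricity"):
            assert a[col] == pytest.approx(b[col], abs=1e-9)
        rng = np.random.default_rng(10)
        img = rng.uniform(0, 1, (30, 30))
        h1 = haralick(img, m.astype(bool))
        h2 = haralick(np.rot90(img).copy(), np.rot90(m).astype(bool).copy())
        assert np.allclose(h1, h2, atol=1e-9)
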