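"""Mask morphometry: region measurements and the four shape descriptors."""

import math

import numpy as np
import pytest

from buscad import geometry as geo

from conftest import oracle_boundary_walk, oracle_convex_area, random_small_mask


def disk_mask(r, size=None, center=None):
    size = size or 2 * r + 5
    cy = cx = size // 2 if center is None else center
    yy, xx = np.mgrid[:size, :size]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def rect_mask(h, w, pad=2):
    m = np.zeros((h + 2 * pad, w + 2 * pad), bool)
    m[pad : pad + h, pad : pad + w] = True
    return m


# ------------------------------------------------------- largest_component --


class TestLargestComponent:
    def test_single_blob_is_identity(self):
        m = disk_mask(5)
        assert (geo.largest_component(m) == m).all()

    def test_selects_maximal_area(self):
        m = np.zeros((12, 24), bool)
        m[1:3, 1:6] = True  # area 10
        m[8:9, 20:23] = True  # area 3
        out = geo.largest_component(m)
        assert out.sum() == 10 and out[1, 1] and not out[8, 20]

    def test_tie_breaks_to_first_in_scan_order(self):
        m = np.zeros((10, 10), bool)
        m[6:7, 0:5] = True  # area 5, first pixel (6,0)
        m[2:3, 5:10] = True  # area 5, first pixel (2,5) -> earlier scan order
        out = geo.largest_component(m)
        assert out[2, 5] and not out[6, 0]

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError, match="empty"):
            geo.largest_component(np.zeros((4, 4), bool))

    def test_connectivity_4_splits_diagonal_blobs(self):
        m = np.eye(4, dtype=bool)
        assert geo.largest_component(m, connectivity=8).sum() == 4
        assert geo.largest_component(m, connectivity=4).sum() == 1


# ------------------------------------------------------------------ measure --


class TestMeasure:
    def test_solid_square_symmetry(self):
        g = geo.measure(rect_mask(10, 10))
        assert g.area == 100
        assert g.bbox_area == 100
        assert g.convex_area == 100
        assert g.major_axis == pytest.approx(g.minor_axis)

    def test_thin_line_moments_match_direct_oracle(self):
        # 1x20 line: oracle = direct second moments of the 20 pixel centers
        # plus the 1/12 per-pixel variance convention
        g = geo.measure(rect_mask(1, 20))
        var_long = np.var(np.arange(20)) + 1.0 / 12.0
        var_short = 1.0 / 12.0
        assert g.bbox_area == 20
        assert g.major_axis == pytest.approx(4 * math.sqrt(var_long))
        assert g.minor_axis == pytest.approx(4 * math.sqrt(var_short))
        assert g.minor_axis > 0
        assert geo.eccentricity(g) == pytest.approx(
            math.sqrt(1 - var_short / var_long)
        )

    def test_disk_perimeter_within_3pct_of_circumference(self):
        g = geo.measure(disk_mask(32))
        assert g.perimeter == pytest.approx(2 * math.pi * 32, rel=0.03)

    def test_raw_chain_backend_is_uncorrected(self):
        m = disk_mask(16)
        corrected = geo.measure(m).perimeter
        raw = geo.measure(m, perimeter_backend="chain").perimeter
        assert corrected == pytest.approx(raw * geo.KULPA)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            geo.measure(np.zeros((3, 3), bool))


# ------------------------------------------------------------- descriptors --


class TestDescriptors:
    def test_circularity_exact_circle_is_one(self):
        r = 10.0
        value, clamped = geo.circularity(area=math.pi * r**2, perimeter=2 * math.pi * r)
        assert value == pytest.approx(1.0)
        assert not clamped

    def test_circularity_continuous_square(self):
        s = 7.0
        value, _ = geo.circularity(area=s * s, perimeter=4 * s)
        assert value == pytest.approx(math.pi / 4)

    def test_circularity_rasterized_disk_in_band(self):
        value, _ = geo.circularity(geo.measure(disk_mask(32)))
        assert 0.95 <= value <= 1.0

    def test_circularity_clamp_flags(self):
        value, clamped = geo.circularity(area=100.0, perimeter=10.0)
        assert value == 1.0 and clamped

    def test_circularity_zero_perimeter_raises(self):
        with pytest.raises(ValueError):
            geo.circularity(area=1.0, perimeter=0.0)

    def test_solidity_convex_region_is_one(self):
        assert geo.solidity(geo.measure(rect_mask(6, 11))) == 1.0

    def test_solidity_corner_cut_square_matches_hull_oracle(self):
        m = rect_mask(5, 5)
        m[2:4, 5:7] = False  # remove a 2x2 corner block
        region = geo.largest_component(m)
        g = geo.measure(region)
        assert g.area == 21
        assert g.convex_area == oracle_convex_area(region)
        assert geo.solidity(g) == pytest.approx(21 / g.convex_area)
        assert geo.solidity(g) < 1.0

    def test_eccentricity_closed_forms(self):
        g = geo.measure(rect_mask(8, 8))
        assert geo.eccentricity(g) == pytest.approx(0.0, abs=1e-9)
        assert geo.eccentricity(a=2.0, b=1.0) == pytest.approx(math.sqrt(3) / 2)
        with pytest.raises(ValueError, match="mislabeled"):
            geo.eccentricity(a=1.0, b=2.0)

    def test_eccentricity_rasterized_ellipse_converges(self):
        yy, xx = np.mgrid[:100, :180]
        ell = ((yy - 50) / 20.0) ** 2 + ((xx - 90) / 40.0) ** 2 <= 1.0  # 80x40
        assert geo.eccentricity(geo.measure(ell)) == pytest.approx(
            math.sqrt(3) / 2, abs=0.01
        )

    def test_extent_rectangle_fills_box(self):
        assert geo.extent(geo.measure(rect_mask(4, 9))) == 1.0

    def test_extent_right_triangle_closed_form(self):
        n = 20
        tri = np.tril(np.ones((n, n), dtype=bool))
        assert geo.extent(geo.measure(tri)) == pytest.approx((n * n + n) / 2 / n**2)

    def test_extent_disk_approaches_pi_over_4(self):
        # convergence is O(1/r): the digital box is (2r+1) wide, not 2r
        errs = [abs(geo.extent(geo.measure(disk_mask(r))) - math.pi / 4)
                for r in (25, 50, 100)]
        assert errs == sorted(errs, reverse=True)
        assert errs[-1] <= 0.01


# --------------------------------------------------------- extract_features --


class TestExtractFeatures:
    def test_disk_limits(self):
        f = geo.extract_features(disk_mask(40))
        assert f.circularity == pytest.approx(1.0, abs=0.05)
        assert f.solidity == pytest.approx(1.0, abs=0.02)
        assert f.eccentricity == pytest.approx(0.0, abs=0.05)
        assert f.extent == pytest.approx(math.pi / 4, abs=0.02)

    def test_rectangle_2to1_matches_moment_oracle(self):
        f = geo.extract_features(rect_mask(20, 40))
        assert f.solidity == 1.0
        assert f.extent == 1.0
        # +1/12 convention makes the raster variances exactly n^2/12
        assert f.eccentricity == pytest.approx(math.sqrt(3) / 2)

    def test_feature_order_and_vector(self):
        f = geo.extract_features(disk_mask(10))
        v = f.as_array()
        assert v.tolist() == [f.circularity, f.solidity, f.eccentricity, f.extent]

    def test_uses_largest_component(self):
        m = disk_mask(12, size=64)
        m[1, 1] = True  # clutter pixel
        f_clutter = geo.extract_features(m)
        f_clean = geo.extract_features(disk_mask(12, size=64))
        assert f_clutter == f_clean

    def test_union_mode_differs_for_multi_region(self):
        m = np.zeros((30, 30), bool)
        m[2:8, 2:8] = True
        m[20:26, 20:26] = True
        f_union = geo.extract_features(m, multi_region="union")
        f_largest = geo.extract_features(m, multi_region="largest")
        assert f_union.solidity < f_largest.solidity

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            geo.extract_features(np.zeros((5, 5), bool))


# ----------------------------------------------------- invariance properties --


class TestInvariances:
    @pytest.fixture()
    def blob(self):
        m = disk_mask(9, size=40)
        m |= np.roll(disk_mask(6, size=40), (6, 8), axis=(0, 1))
        return geo.largest_component(m)

    def test_translation_invariance(self, blob):
        f0 = geo.extract_features(blob).as_array()
        shifted = np.roll(np.pad(blob, 10), (7, -4), axis=(0, 1))
        f1 = geo.extract_features(shifted).as_array()
        # identical up to float associativity in the centroid sums
        np.testing.assert_allclose(f1, f0, rtol=1e-9)

    def test_rotation_90_invariance(self, blob):
        f0 = geo.extract_features(blob).as_array()
        f90 = geo.extract_features(np.rot90(blob)).as_array()
        np.testing.assert_allclose(f90, f0, rtol=1e-12)

    def test_scale_convergence_of_circularity(self):
        values = [geo.extract_features(disk_mask(r)).circularity for r in (8, 16, 32, 64)]
        errors = [abs(v - 1.0) for v in values]
        assert errors[-1] <= 0.01
        assert max(errors) <= 0.08

    def test_oracle_equivalence_random_masks(self):
        """Production hull area and boundary-walk perimeter agree with the
        independent gift-wrap / from-scratch-walk oracles on random masks
        up to 12x12."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            region = geo.largest_component(random_small_mask(rng))
            g = geo.measure(region, perimeter_backend="chain")
            assert g.perimeter == pytest.approx(oracle_boundary_walk(region))
            assert g.convex_area == oracle_convex_area(region)
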