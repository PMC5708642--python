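import numpy as np
import pytest
from skimage.draw import disk

from hevcells._shape import nucleus_shape, polygon_perimeter, vcell_shape
from hevcells.errors import EmptyRegionError
from hevcells.features import (FEATURE_COLUMNS, build_feature_table,
                               colour_stats, standardise)
from hevcells.segmentation import VCellMap


def disc_mask(radius, pad=4):
    size = 2 * radius + 2 * pad + 1
    m = np.zeros((size, size), dtype=bool)
    rr, cc = disk((size // 2, size // 2), radius + 0.5)
    m[rr, cc] = True
    return m


def shapely_hull(mask):
    """Independent convex-hull oracle: union of pixel squares via shapely."""
    from shapely.geometry import box
    from shapely.ops import unary_union

    rs, cs = np.nonzero(mask)
    squares = [box(r - 0.5, c - 0.5, r + 0.5, c + 0.5) for r, c in zip(rs, cs)]
    return unary_union(squares).convex_hull


class TestColourStats:
    def test_constant_region_degenerate(self):
        s = colour_stats(np.full(50, 100, dtype=np.uint8))
        assert s["mean"] == s["median"] == s["mode"] == s["min"] == s["max"] == 100
        assert s["variance"] == 0 and s["stddev"] == 0 and s["entropy"] == 0
        assert s["skewness"] == 0 and s["kurtosis"] == 0

    def test_two_point_mass_brute_force(self):
        vals = np.array([0, 0, 255, 255], dtype=np.uint8)
        s = colour_stats(vals)
        assert s["mean"] == pytest.approx(127.5)
        assert s["variance"] == pytest.approx(np.mean((vals - 127.5) ** 2))
        assert s["avgdev"] == pytest.approx(127.5)
        assert s["entropy"] == pytest.approx(1.0)  # two equiprobable levels: 1 bit

    def test_symmetric_sample_zero_skew(self):
        vals = np.array([10, 20, 30, 40, 50], dtype=np.uint8)
        assert colour_stats(vals)["skewness"] == pytest.approx(0.0, abs=1e-9)

    def test_empty_region_raises(self):
        with pytest.raises(EmptyRegionError):
            colour_stats(np.array([], dtype=np.uint8))


class TestVCellShape:
    def test_disc_limits(self):
        f = vcell_shape(disc_mask(40))
        assert f["circularity"] == pytest.approx(1.0, abs=0.1)
        assert f["sphericity"] == pytest.approx(1.0, abs=0.05)
        assert f["solidity"] == pytest.approx(1.0, abs=0.02)
        assert f["roundness"] == pytest.approx(1.0, abs=0.1)
        assert f["aspect_ratio"] == pytest.approx(1.0, abs=0.05)
        assert f["area"] == pytest.approx(np.pi * 40.5 ** 2, rel=0.02)

    def test_square_closed_forms(self):
        a = 61
        m = np.zeros((a + 8, a + 8), dtype=bool)
        m[4:4 + a, 4:4 + a] = True
        f = vcell_shape(m)
        assert f["area"] == a * a
        assert f["perimeter"] == pytest.approx(4 * (a - 1))  # boundary-pixel polygon
        assert f["circularity"] == pytest.approx(np.pi / 4, rel=0.05)
        assert f["feret"] == pytest.approx(a * np.sqrt(2), rel=0.02)  # diagonal
        assert f["rectangularity"] == pytest.approx(a * a / f["arbbox"])
        assert f["arbbox"] == pytest.approx(f["feret"] * f["breadth"])

    def test_concave_region_solidity_below_one(self):
        c = np.zeros((40, 40), dtype=bool)
        c[5:35, 5:35] = True
        c[12:28, 15:35] = False  # carve a "C"
        f = vcell_shape(c)
        assert f["solidity"] < 0.85
        assert vcell_shape(np.ones((20, 20), dtype=bool))["solidity"] == pytest.approx(1.0, abs=0.02)

    def test_algebraic_identities(self):
        for mask in (disc_mask(12), np.ones((9, 17), dtype=bool)):
            f = vcell_shape(mask)
            assert f["arbbox"] == pytest.approx(f["feret"] * f["breadth"])
            assert f["aspect_ratio"] == pytest.approx(f["feret"] / f["breadth"])
            assert f["shape"] == pytest.approx(f["perimeter"] ** 2 / f["area"])
            assert f["circularity"] == pytest.approx(4 * np.pi * f["area"] / f["perimeter"] ** 2)
            assert f["area_eq_diameter"] == pytest.approx(np.sqrt(4 / np.pi * f["area"]))
            assert f["perimeter_eq_diameter"] == pytest.approx(f["perimeter"] / np.pi)
            assert f["eq_ellipse_area"] == pytest.approx(np.pi * f["feret"] * f["breadth"] / 4)
            assert f["compactness"] == pytest.approx(f["area_eq_diameter"] / f["feret"])
            assert f["rfactor"] == pytest.approx(f["chull_perimeter"] / (f["feret"] * np.pi))
            assert f["modification_ratio"] == pytest.approx(2 * f["minr"] / f["feret"])
            assert f["rectangularity"] == pytest.approx(f["area"] / f["arbbox"])

    def test_scale_behaviour(self):
        small, big = disc_mask(15), disc_mask(30)
        fs, fb = vcell_shape(small), vcell_shape(big)
        assert fb["area"] / fs["area"] == pytest.approx(4.0, rel=0.1)
        assert fb["perimeter"] / fs["perimeter"] == pytest.approx(2.0, rel=0.1)
        for name in ("circularity", "roundness", "solidity", "sphericity",
                     "aspect_ratio", "rectangularity"):
            assert fb[name] == pytest.approx(fs[name], abs=0.06)

    def test_single_pixel_fallbacks(self):
        m = np.zeros((5, 5), dtype=bool)
        m[2, 2] = True
        f = vcell_shape(m)
        assert f["perimeter"] == 4.0 and f["area"] == 1.0
        assert f["sphericity"] == 0.0  # zero-denominator ratios report 0
        assert np.isfinite(list(f.values())).all()


class TestNucleusShape:
    def test_convex_nucleus_near_zero_concavity(self):
        f = nucleus_shape(disc_mask(10))
        assert f["concavity"] == pytest.approx(0.0, abs=0.1 * f["area"])
        assert f["convexity"] == pytest.approx(1.0, abs=0.1)

    def test_crescent_concavity_matches_hull_oracle(self):
        m = disc_mask(12)
        bite = disc_mask(12)
        shifted = np.roll(bite, 9, axis=1)
        crescent = m & ~shifted
        f = nucleus_shape(crescent)
        hull = shapely_hull(crescent)
        assert f["chull_area"] == pytest.approx(hull.area, rel=0.05)
        assert f["concavity"] == pytest.approx(hull.area - crescent.sum(), rel=0.15)
        assert f["concavity"] > 20

    def test_identity_concavity(self):
        for mask in (disc_mask(8), np.ones((6, 11), dtype=bool)):
            f = nucleus_shape(mask)
            assert f["concavity"] == pytest.approx(f["chull_area"] - f["area"])
            assert f["shape"] == pytest.approx(f["perimeter"] ** 2 / f["area"])


class TestFeatureTable:
    def _toy_vcells(self):
        labels = np.zeros((30, 60), dtype=np.int32)
        labels[5:25, 5:25] = 1
        labels[5:25, 35:55] = 2
        nuclei = np.zeros_like(labels)
        nuclei[10:18, 10:18] = 1
        nuclei[10:18, 40:48] = 2
        return VCellMap(labels, nuclei)

    def test_shape_and_columns(self, rng):
        vc = self._toy_vcells()
        stain = rng.integers(0, 256, (30, 60, 3)).astype(np.uint8)
        table = build_feature_table(vc, stain)
        assert table.shape == (2, 63)
        assert tuple(table.columns) == FEATURE_COLUMNS
        assert not table.isna().any().any()

    def test_translated_copies_identical_rows(self):
        vc = self._toy_vcells()
        stain = np.full((30, 60, 3), 120, dtype=np.uint8)
        table = build_feature_table(vc, stain)
        assert np.allclose(table.iloc[0].to_numpy(), table.iloc[1].to_numpy())

    def test_id_shuffle_reorders_rows(self, rng):
        vc = self._toy_vcells()
        stain = rng.integers(0, 256, (30, 60, 3)).astype(np.uint8)
        t1 = build_feature_table(vc, stain)
        swapped = VCellMap(np.where(vc.labels > 0, 3 - vc.labels, 0),
                           np.where(vc.nuclei > 0, 3 - vc.nuclei, 0))
        t2 = build_feature_table(swapped, stain)
        assert np.allclose(t1.iloc[0].to_numpy(), t2.iloc[1].to_numpy())
        assert np.allclose(t1.iloc[1].to_numpy(), t2.iloc[0].to_numpy())

    def test_standardise_zero_mean_unit_sd(self, rng):
        vc = self._toy_vcells()
        stain = rng.integers(0, 256, (30, 60, 3)).astype(np.uint8)
        table = build_feature_table(vc, stain)
        x = standardise(table)
        assert x.shape == (2, 63)
        assert np.allclose(x.mean(axis=0), 0, atol=1e-9)
        sd = x.std(axis=0)
        assert np.all((np.isclose(sd, 1) | np.isclose(sd, 0)))
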