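"""Overlap indices, raster alignment, dyad and site-fidelity construction."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proxrange.io_grid import KinshipTable
from proxrange.overlap import (
    Dyad,
    OverlapResult,
    bhattacharyya,
    build_dyads,
    common_raster,
    conditional_truncate,
    overlap_indices,
    site_fidelity_pairs,
    udoi,
)
from proxrange.ud_estimation import UDRaster, isopleth

from conftest import gaussian_raster, uniform_raster


def _random_raster(rng, shape=(20, 20), cell=5.0, origin=(0.0, 0.0)) -> UDRaster:
    dens = rng.random(shape)
    dens /= dens.sum() * cell**2
    return UDRaster(origin[0], origin[1], cell, dens)


def _brute_ba(a: UDRaster, b: UDRaster) -> float:
    total = 0.0
    for i in range(a.density.shape[0]):
        for j in range(a.density.shape[1]):
            total += math.sqrt(a.density[i, j] * b.density[i, j]) * a.cell_size**2
    return total


def _brute_udoi(a: UDRaster, b: UDRaster) -> float:
    area = 0.0
    integral = 0.0
    for i in range(a.density.shape[0]):
        for j in range(a.density.shape[1]):
            if a.density[i, j] > 0 and b.density[i, j] > 0:
                area += a.cell_size**2
            integral += a.density[i, j] * b.density[i, j] * a.cell_size**2
    return area * integral


class TestIndices:
    def test_identical_uds_are_fully_affine(self):
        ud = gaussian_raster(50.0, (100, 100), (-100, -100), (80, 80))
        assert bhattacharyya(ud, ud) == pytest.approx(1.0, abs=1e-6)

    def test_identical_uniform_udoi_is_one(self):
        ud = uniform_raster(10, 10)
        assert udoi(ud, ud) == pytest.approx(1.0, abs=1e-6)

    def test_disjoint_supports_are_zero(self):
        a = uniform_raster(4, 4, origin=(0.0, 0.0))
        b = uniform_raster(4, 4, origin=(100.0, 0.0))
        a2, b2 = common_raster(a, b)
        assert bhattacharyya(a2, b2) == 0.0
        assert udoi(a2, b2) == 0.0

    def test_matches_brute_force_on_random_rasters(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = _random_raster(rng)
            b = _random_raster(rng)
            assert bhattacharyya(a, b) == pytest.approx(_brute_ba(a, b), abs=1e-12)
            assert udoi(a, b) == pytest.approx(_brute_udoi(a, b), abs=1e-12)

    def test_gaussian_closed_form(self):
        # equal-covariance isotropic Gaussians: BA = exp(−d²/(8σ²))
        sigma, d = 50.0, 100.0
        shape, origin = (120, 140), (-250.0, -250.0)
        a = gaussian_raster(sigma, (0.0, 0.0), origin, shape)
        b = gaussian_raster(sigma, (d, 0.0), origin, shape)
        expected = math.exp(-(d**2) / (8 * sigma**2))
        assert bhattacharyya(a, b) == pytest.approx(expected, rel=0.01)

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a = _random_raster(rng, shape=(8, 8))
        b = _random_raster(rng, shape=(8, 8))
        assert bhattacharyya(a, b) == bhattacharyya(b, a)
        assert udoi(a, b) == udoi(b, a)

    def test_ba_bounded_by_one(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            a = _random_raster(rng, shape=(10, 10))
            b = _random_raster(rng, shape=(10, 10))
            assert bhattacharyya(a, b) <= 1.0

    def test_indices_decrease_with_separation(self):
        sigma = 50.0
        shape, origin = (120, 160), (-300.0, -300.0)
        prev_ba, prev_udoi = np.inf, np.inf
        for d in (0.0, 40.0, 80.0, 120.0, 160.0):
            a = gaussian_raster(sigma, (0.0, 0.0), origin, shape)
            b = gaussian_raster(sigma, (d, 0.0), origin, shape)
            ba = bhattacharyya(a, b)
            ud = udoi(a, b)
            assert ba < prev_ba or d == 0.0
            assert ud < prev_udoi or d == 0.0
            prev_ba, prev_udoi = ba, ud

    def test_concentrated_identical_ud_udoi_exceeds_one(self):
        ud = gaussian_raster(50.0, (0.0, 0.0), (-200.0, -200.0), (80, 80))
        trunc = conditional_truncate(ud, isopleth(ud, 0.95))
        assert udoi(trunc, trunc) > 1.0

    def test_unnormalized_input_rejected(self):
        ud = uniform_raster(5, 5)
        bad = UDRaster(ud.origin_x, ud.origin_y, ud.cell_size, ud.density * 2)
        with pytest.raises(ValueError, match="not normalized"):
            bhattacharyya(ud, bad)
        with pytest.raises(ValueError, match="not normalized"):
            udoi(bad, ud)


class TestCommonRaster:
    def test_identical_extents_unchanged(self):
        a = uniform_raster(6, 6)
        b = uniform_raster(6, 6)
        a2, b2 = common_raster(a, b)
        np.testing.assert_array_equal(a2.density, a.density)
        assert a2.origin_x == a.origin_x and a2.shape == a.shape

    def test_disjoint_extents_mass_preserved(self):
        a = uniform_raster(4, 4, origin=(0.0, 0.0))
        b = uniform_raster(4, 4, origin=(200.0, 300.0))
        a2, b2 = common_raster(a, b)
        assert a2.shape == b2.shape
        assert a2.total_mass() == pytest.approx(1.0, abs=1e-9)
        assert b2.total_mass() == pytest.approx(1.0, abs=1e-9)

    def test_mismatched_cell_size_errors(self):
        a = uniform_raster(4, 4, cell=5.0)
        b = uniform_raster(4, 4, cell=2.5)
        with pytest.raises(ValueError, match="cell size"):
            common_raster(a, b)

    def test_subcell_offset_errors(self):
        a = uniform_raster(4, 4, origin=(0.0, 0.0))
        b = uniform_raster(4, 4, origin=(2.0, 0.0))
        with pytest.raises(ValueError, match="misaligned"):
            common_raster(a, b)


class TestConditionalTruncate:
    def test_renormalizes_and_shrinks_support(self):
        ud = gaussian_raster(30.0, (0.0, 0.0), (-100.0, -100.0), (40, 40))
        hr = isopleth(ud, 0.95)
        trunc = conditional_truncate(ud, hr)
        assert trunc.total_mass() == pytest.approx(1.0, abs=1e-9)
        assert (trunc.density > 0).sum() < (ud.density > 0).sum()

    def test_idempotent(self):
        ud = gaussian_raster(30.0, (0.0, 0.0), (-100.0, -100.0), (40, 40))
        hr = isopleth(ud, 0.5)
        once = conditional_truncate(ud, hr)
        twice = conditional_truncate(once, hr)
        np.testing.assert_allclose(twice.density, once.density, atol=1e-12)

    def test_point_mass_unchanged(self):
        dens = np.zeros((5, 5))
        dens[2, 2] = 1 / 25.0
        ud = UDRaster(0.0, 0.0, 5.0, dens)
        hr = isopleth(ud, 0.5)
        np.testing.assert_array_equal(conditional_truncate(ud, hr).density, dens)

    def test_empty_mask_errors(self):
        ud = uniform_raster(3, 3)
        hr = isopleth(ud, 0.5)
        hr.cell_mask[:] = False
        with pytest.raises(ValueError, match="empty"):
            conditional_truncate(ud, hr)


class TestDyads:
    @pytest.mark.parametrize("n,expected", [(11, 55), (7, 21), (1, 0), (2, 1)])
    def test_pair_counts(self, n, expected):
        ids = [f"b{i}" for i in range(n)]
        assert len(build_dyads({"batch": ids})) == expected

    def test_kinship_labels(self):
        kin = KinshipTable([("a", "c", "mother-daughter")])
        dyads = build_dyads({"May": ["a", "b", "c"]}, kin)
        rel = {frozenset((d.id_a, d.id_b)): d.relation for d in dyads}
        assert rel[frozenset(("a", "c"))] == "mother-daughter"
        assert rel[frozenset(("a", "b"))] == "non-related"

    def test_duplicate_individual_errors(self):
        with pytest.raises(ValueError, match="twice"):
            build_dyads({"May": ["a", "b", "a"]})

    def test_self_dyad_rejected_for_space_sharing(self):
        with pytest.raises(ValueError, match="distinct"):
            Dyad("a", "a")


class TestSiteFidelity:
    def _ud(self, cx):
        return gaussian_raster(40.0, (cx, 0.0), (-200.0, -200.0), (80, 100))

    def test_within_and_between_year_labels(self):
        uds = {
            "batA": {"May-24": self._ud(0.0), "Aug-24": self._ud(20.0), "May-25": self._ud(40.0)},
            "batB": {"May-24": self._ud(0.0)},
        }
        years = {"May-24": 2024, "Aug-24": 2024, "May-25": 2025}
        results = site_fidelity_pairs(uds, years)
        assert len(results) == 3  # batB tagged once → no pairs
        spans = sorted(r.span for r in results)
        assert spans == ["between-year", "between-year", "within-year"]
        for r in results:
            assert r.dyad.kind == "site-fidelity"
            assert 0.0 < r.ba <= 1.0

    def test_shifted_ud_overlaps_less_than_identical(self):
        years = {"p1": 2024, "p2": 2025}
        same = site_fidelity_pairs({"b": {"p1": self._ud(0.0), "p2": self._ud(0.0)}}, years)
        far = site_fidelity_pairs({"b": {"p1": self._ud(0.0), "p2": self._ud(120.0)}}, years)
        assert same[0].ba > far[0].ba


def test_overlap_result_validation():
    d = Dyad("a", "b")
    with pytest.raises(ValueError, match="BA"):
        OverlapResult(d, 0.95, 0.5, 1.2)
    with pytest.raises(ValueError, match="UDOI"):
        OverlapResult(d, 0.95, -0.1, 0.5)


def test_overlap_indices_conditional_vs_full():
    a = gaussian_raster(50.0, (0.0, 0.0), (-250.0, -250.0), (100, 100))
    b = gaussian_raster(50.0, (60.0, 0.0), (-250.0, -250.0), (100, 100))
    udoi_c, ba_c = overlap_indices(a, b, level=0.95, conditional=True)
    udoi_f, ba_f = overlap_indices(a, b, conditional=False)
    for v in (udoi_c, udoi_f):
        assert v > 0
    assert 0 < ba_c <= 1 and 0 < ba_f <= 1
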