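"""Shrink policy, per-slice shrinkage, slice filters, and the full STV pipeline."""

import numpy as np
import pytest
from shapely.geometry import Point, Polygon

from scartstv.contour import ContourSlice, polygon_area
from scartstv.errors import InvalidGapError, InvalidWidthError, StvEmptyError, UnsupportedDoseError
from scartstv.generator import (
    StvParams,
    apply_is_gap,
    filter_min_radius,
    generate_stv,
    make_control_ring,
    shrink_ratio,
    shrink_slice,
)
from scartstv.metrics import structure_volume, volume_ratio
from scartstv.phantoms import make_egg, make_sphere
from scartstv.polar import RefineParams, to_polar

from .conftest import circle_slice


class TestShrinkRatio:
    @pytest.mark.parametrize(
        "dose,expected_pct", [(15, 33), (18, 28), (21, 24), (24, 21)]
    )
    def test_formula_mode_integer_percent(self, dose, expected_pct):
        assert round(100 * shrink_ratio(dose, 5, "formula")) == expected_pct

    def test_formula_15gy_exact(self):
        assert shrink_ratio(15, 5, "formula") == pytest.approx(1 / 3)

    @pytest.mark.parametrize("dose,ratio", [(15, 0.36), (18, 0.27), (21, 0.24), (24, 0.21)])
    def test_table_mode_tabulated(self, dose, ratio):
        assert shrink_ratio(dose, 5, "table") == ratio

    def test_table_mode_linear_interpolation(self):
        assert shrink_ratio(16.5, 5, "table") == pytest.approx(0.315)
        assert shrink_ratio(22.5, 5, "table") == pytest.approx(0.225)

    def test_table_mode_out_of_range_rejected(self):
        for dose in (14.9, 24.1, 30):
            with pytest.raises(UnsupportedDoseError):
                shrink_ratio(dose, 5, "table")

    def test_table_mode_nonstandard_border_rejected(self):
        with pytest.raises(UnsupportedDoseError):
            shrink_ratio(18, 4, "table")

    def test_dose_ordering_enforced(self):
        with pytest.raises(UnsupportedDoseError):
            shrink_ratio(5, 5, "formula")


class TestShrinkSlice:
    def test_circle_scales_about_center(self):
        out = shrink_slice(circle_slice(50.0), 0.36)
        d = np.linalg.norm(out.vertices, axis=1)
        np.testing.assert_allclose(d, 18.0, atol=1e-6)

    def test_area_scales_by_ratio_squared(self, pacman):
        """For any slice, output area / polar-region area = ratio^2."""
        refine = RefineParams(n_angles=360)
        for s in (circle_slice(30.0), pacman):
            from scartstv.polar import from_polar, refine_center

            center = refine_center(s, refine)
            polar_region = from_polar(to_polar(s, center, 360))
            out = shrink_slice(s, 0.27, refine)
            ratio = polygon_area(out) / polygon_area(polar_region)
            assert ratio == pytest.approx(0.27**2, rel=1e-6)

    def test_egg_output_inside_input(self):
        egg = make_egg(30, 15, 25, spacing=5)
        for s in egg.slices:
            out = shrink_slice(s, 0.36)
            poly = Polygon(s.vertices)
            assert all(poly.contains(Point(p)) for p in out.vertices)

    def test_invalid_ratio_rejected(self, unit_square):
        for r in (0.0, 1.0, 1.5, -0.2):
            with pytest.raises(ValueError):
                shrink_slice(circle_slice(30.0), r)


class TestFilterMinRadius:
    def test_threshold_on_equivalent_radius(self):
        kept = filter_min_radius([circle_slice(19.0), circle_slice(21.0)], 20.0)
        assert len(kept) == 1
        assert np.sqrt(polygon_area(kept[0]) / np.pi) == pytest.approx(21.0, abs=0.01)

    def test_zero_threshold_is_identity(self):
        slices = [circle_slice(r) for r in (1.0, 5.0, 30.0)]
        assert filter_min_radius(slices, 0.0) == slices

    def test_order_preserved(self):
        slices = [circle_slice(30, z=z) for z in (0, 2, 4)]
        kept = filter_min_radius(slices, 20.0)
        assert [s.z for s in kept] == [0, 2, 4]


class TestApplyIsGap:
    def test_trim_arithmetic(self):
        zs = np.arange(0, 100.0 + 1e-9, 2.5)
        slices = [circle_slice(30, z=z) for z in zs]
        kept = apply_is_gap(slices, 0.0, 100.0, 10.0)
        kept_z = [s.z for s in kept]
        assert kept_z[0] == 10.0 and kept_z[-1] == 90.0
        assert len(kept) == len(zs) - 8  # 4 removed at each end

    def test_gap_bounds_enforced(self):
        slices = [circle_slice(30, z=z) for z in (0, 10, 20)]
        for gap in (4.0, 15.1):
            with pytest.raises(InvalidGapError):
                apply_is_gap(slices, 0, 20, gap)

    def test_small_extent_empties(self):
        slices = [circle_slice(30, z=z) for z in (0, 6, 12, 18)]
        assert apply_is_gap(slices, 0.0, 18.0, 10.0) == []


class TestGenerateStv:
    def test_sphere_untrimmed_ratio_squared(self):
        gtv = make_sphere(60, 2)
        params = StvParams(scart_dose=15, trim_enabled=False, min_radius=0)
        stv = generate_stv(gtv, params)
        assert stv.name == "STV_15Gy"
        assert len(stv) == len(gtv)
        assert volume_ratio(stv, gtv) == pytest.approx(0.36**2, rel=0.005)

    def test_dose_monotonicity(self):
        gtv = make_sphere(60, 4)
        vols = []
        for dose in (15, 18, 21, 24):
            stv = generate_stv(
                gtv, StvParams(scart_dose=dose, trim_enabled=False, min_radius=0)
            )
            vols.append(structure_volume(stv))
        assert all(a > b for a, b in zip(vols, vols[1:]))

    def test_small_sphere_high_dose_empty(self):
        gtv = make_sphere(25, 2)
        with pytest.raises(StvEmptyError, match="too small"):
            generate_stv(gtv, StvParams(scart_dose=24))

    def test_scale_equivariance(self):
        """Scaling GTV coordinates by k scales the STV by k when the
        min-radius and gap thresholds are scaled along."""
        k = 2.0
        gtv1 = make_sphere(30, 3)
        gtv2 = make_sphere(30 * k, 3 * k)
        p1 = StvParams(scart_dose=15, min_radius=5.0, gap=5.0)
        p2 = StvParams(scart_dose=15, min_radius=5.0 * k, gap=10.0)
        stv1 = generate_stv(gtv1, p1)
        stv2 = generate_stv(gtv2, p2)
        assert len(stv1) == len(stv2)
        for a, b in zip(stv1.slices, stv2.slices):
            assert b.z == pytest.approx(k * a.z, abs=1e-9)
            np.testing.assert_allclose(b.vertices, k * a.vertices, atol=1e-6)

    def test_stv_slices_keep_gtv_z_positions(self):
        gtv = make_sphere(60, 5)
        stv = generate_stv(gtv, StvParams(scart_dose=15, trim_enabled=False, min_radius=0))
        np.testing.assert_array_equal(stv.z_values, gtv.z_values)

    def test_too_few_slices_rejected(self):
        from scartstv.contour import Structure
        from scartstv.errors import DegenerateContourError

        gtv = Structure("GTV", [circle_slice(30, z=0), circle_slice(30, z=2)])
        with pytest.raises(DegenerateContourError):
            generate_stv(gtv, StvParams(scart_dose=15))


class TestControlRing:
    def test_circle_annulus_area(self):
        ptv = make_sphere(30, 5, n_angles=720)
        ring = make_control_ring(ptv, 3.0, RefineParams(n_angles=720))
        mid = len(ptv) // 2
        outer_a = polygon_area(ring.outer.slices[mid])
        inner_a = polygon_area(ptv.slices[mid])
        r = np.sqrt(30**2 - ptv.slices[mid].z ** 2)
        assert outer_a - inner_a == pytest.approx(np.pi * ((r + 3) ** 2 - r**2), rel=2e-4)
        assert ring.inner is ptv
        assert ring.width == 3.0

    def test_square_radial_expansion_bound(self):
        """Radial expansion of a square lies between width*cos(45 deg) and
        width from the boundary."""
        square = ContourSlice(0.0, [(-30, -30), (30, -30), (30, 30), (-30, 30)])
        from scartstv.contour import Structure

        ring = make_control_ring(Structure("PTV", [square], declared_spacing=2), 3.0)
        boundary = Polygon(square.vertices)
        for p in ring.outer.slices[0].vertices:
            d = boundary.exterior.distance(Point(p))
            assert not boundary.contains(Point(p))
            assert 3 * np.cos(np.pi / 4) - 1e-6 <= d <= 3.0 + 1e-6

    def test_invalid_width_rejected(self):
        ptv = make_sphere(30, 5)
        for w in (0.0, -1.0):
            with pytest.raises(InvalidWidthError):
                make_control_ring(ptv, w)
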