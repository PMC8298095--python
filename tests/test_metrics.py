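"""Morphometry: areas, perimeters, equivalent diameters, g-ratio, counting."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from myeltrace.contours import Contour, extract_contours
from myeltrace.errors import (
    DegenerateGeometryError,
    EmptyCountError,
    NestingViolationError,
)
from myeltrace.grouping import FiberGroup
from myeltrace.metrics import (
    MyelinationCount,
    PixelScale,
    compute_g_ratio,
    equivalent_diameter,
    measure_fiber,
    measure_manual_polygon,
    percent_myelinated,
    polygon_area,
    polygon_perimeter,
)
from oracles import star_polygon, supersampled_area

UNIT_SQUARE = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
TRIANGLE_345 = np.array([[0, 0], [4, 0], [0, 3]], float)


def square(cx, cy, side, cid=0):
    h = side / 2.0
    return Contour(
        vertices=np.array(
            [[cx - h, cy - h], [cx + h, cy - h], [cx + h, cy + h], [cx - h, cy + h]], float
        ),
        id=cid,
    )


class TestPolygonMeasures:
    def test_unit_square(self):
        assert polygon_area(UNIT_SQUARE) == 1.0
        assert polygon_perimeter(UNIT_SQUARE) == 4.0

    def test_345_triangle(self):
        assert polygon_area(TRIANGLE_345) == 6.0
        assert polygon_perimeter(TRIANGLE_345) == 12.0

    def test_area_matches_supersampled_raster_on_random_polygons(self, rng):
        for _ in range(10):
            poly = star_polygon(rng, n_vertices=20)
            assert polygon_area(poly) == pytest.approx(supersampled_area(poly), rel=0.02)

    @given(st.integers(0, 17), st.booleans(),
           st.integers(-50, 50), st.integers(-50, 50))
    def test_invariance_to_start_vertex_reversal_and_translation(self, k, rev, dx, dy):
        poly = star_polygon(np.random.default_rng(7), n_vertices=18)
        v = np.roll(poly, k, axis=0)
        if rev:
            v = v[::-1]
        v = v + [dx, dy]
        assert polygon_area(v) == pytest.approx(polygon_area(poly), abs=1e-9)
        assert polygon_perimeter(v) == pytest.approx(polygon_perimeter(poly), abs=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            polygon_area(np.array([[0, 0], [1, 1]], float))
        with pytest.raises(DegenerateGeometryError):
            polygon_perimeter(np.array([[0, 0], [1, 1]], float))

    def test_extracted_disk_perimeter_near_circumference(self):
        yy, xx = np.mgrid[0:64, 0:64]
        mask = np.where((xx - 32) ** 2 + (yy - 32) ** 2 <= 400, 0, 255).astype(np.uint8)
        (c,) = extract_contours(mask)
        assert polygon_perimeter(c) == pytest.approx(2 * math.pi * 20, rel=0.05)

    def test_isoperimetric_inequality_on_extracted_contours(self, scenarios):
        from myeltrace.preprocess import binarize, smooth

        sc = scenarios["dense_field"]
        mask = binarize(smooth(sc.image), sc.myelin_threshold)
        for c in extract_contours(mask):
            assert polygon_perimeter(c) ** 2 >= 4 * math.pi * polygon_area(c)


class TestEquivalentDiameter:
    @pytest.mark.parametrize("area,expected", [(math.pi, 2.0), (100 * math.pi, 20.0), (0.0, 0.0)])
    def test_closed_forms(self, area, expected):
        assert equivalent_diameter(area) == pytest.approx(expected, rel=1e-15)

    def test_negative_area_rejected(self):
        with pytest.raises(ValueError):
            equivalent_diameter(-1.0)

    @given(st.floats(0.1, 1e6), st.floats(0.1, 1e6))
    def test_monotone(self, a, b):
        lo, hi = sorted([a, b])
        assert equivalent_diameter(lo) <= equivalent_diameter(hi)


class TestGRatio:
    def test_equal_areas_give_one(self):
        assert compute_g_ratio(10.0, 10.0) == 1.0

    def test_quarter_area_conventions(self):
        assert compute_g_ratio(25.0, 100.0, mode="diameter") == 0.5
        assert compute_g_ratio(25.0, 100.0, mode="area") == 0.25

    def test_consistent_with_diameters(self):
        inner_a, outer_a = 312.7, 811.4
        g = compute_g_ratio(inner_a, outer_a)
        assert g * equivalent_diameter(outer_a) == pytest.approx(
            equivalent_diameter(inner_a), rel=1e-15
        )

    def test_nesting_violation(self):
        with pytest.raises(NestingViolationError):
            compute_g_ratio(11.0, 10.0)

    def test_zero_outer_area(self):
        with pytest.raises(DegenerateGeometryError):
            compute_g_ratio(0.0, 0.0)

    def test_annulus_phantom_recovers_point_eight(self):
        yy, xx = np.mgrid[0:64, 0:64]
        d2 = (xx - 32) ** 2 + (yy - 32) ** 2
        mask = np.where((d2 <= 100) & (d2 > 64), 0, 255).astype(np.uint8)
        outer, inner = sorted(extract_contours(mask), key=lambda c: -c.area)
        g = compute_g_ratio(polygon_area(inner), polygon_area(outer))
        assert g == pytest.approx(0.80, abs=0.02)


class TestMeasureFiber:
    def _group(self):
        return FiberGroup(
            axon=square(10, 10, 6, 0),
            inner=square(10, 10, 8, 1),
            outer=square(10, 10, 10, 2),
            selection_index=3,
        )

    def test_concentric_squares(self):
        m = measure_fiber(self._group())
        assert m.g_ratio == 0.8  # sqrt(64/100)
        assert m.axon_area == 36.0 and m.inner_area == 64.0 and m.outer_area == 100.0
        assert m.selection_index == 3 and m.unit == "px"

    def test_micron_scaling(self):
        m = measure_fiber(self._group(), scale=PixelScale(0.005))
        assert m.unit == "um"
        assert m.outer_perimeter == pytest.approx(40 * 0.005)
        assert m.outer_area == pytest.approx(100 * 0.005**2)

    @given(st.floats(1e-3, 10))
    def test_g_ratio_scale_invariant(self, mpp):
        assert measure_fiber(self._group(), scale=PixelScale(mpp)).g_ratio == 0.8

    def test_axonless_group(self):
        g = FiberGroup(inner=square(0, 0, 8, 1), outer=square(0, 0, 10, 2))
        m = measure_fiber(g)
        assert m.axon_area is None and m.axon_diameter is None and m.g_ratio == 0.8

    def test_error_carries_selection_index(self):
        bad = FiberGroup(
            inner=square(0, 0, 10, 1), outer=square(0, 0, 8, 2), selection_index=7
        )
        with pytest.raises(NestingViolationError, match="fiber 7"):
            measure_fiber(bad)


class TestManualTraceAndCounting:
    def test_unit_square_trace(self):
        area, perim, diam = measure_manual_polygon([(0, 0), (1, 0), (1, 1), (0, 1)])
        assert area == 1.0 and perim == 4.0
        assert diam == pytest.approx(2 * math.sqrt(1 / math.pi))

    def test_duplicate_points_collapsed(self):
        pts = [(0, 0), (0, 0), (4, 0), (4, 0), (4, 3), (0, 3), (0, 3)]
        area, perim, _ = measure_manual_polygon(pts)
        assert area == 12.0 and perim == 14.0

    def test_manual_trace_matches_automatic_contour(self, scenarios):
        sc = scenarios["clean_isolated"]
        fiber = sc.truth.fibers[1]
        angles = np.linspace(0, 2 * math.pi, 72, endpoint=False)
        trace = [
            (fiber.center[0] + fiber.r_outer * math.cos(a),
             fiber.center[1] + fiber.r_outer * math.sin(a))
            for a in angles
        ]
        area, _, _ = measure_manual_polygon(trace)
        assert area == pytest.approx(fiber.outer_area, rel=0.05)

    def test_too_few_distinct_points(self):
        with pytest.raises(DegenerateGeometryError):
            measure_manual_polygon([(0, 0), (1, 1)])
        with pytest.raises(DegenerateGeometryError):
            measure_manual_polygon([(0, 0), (0, 0), (1, 1), (1, 1)])

    @pytest.mark.parametrize(
        "m,u,expected", [(50, 50, 50.0), (174, 0, 100.0), (1, 3, 25.0)]
    )
    def test_percent_myelinated(self, m, u, expected):
        assert percent_myelinated(MyelinationCount(m, u)) == expected

    def test_zero_total_rejected(self):
        with pytest.raises(EmptyCountError):
            percent_myelinated(MyelinationCount(0, 0))
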