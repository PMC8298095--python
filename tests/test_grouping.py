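"""Point-in-polygon, nesting tests and fiber assembly."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from myeltrace.contours import Contour
from myeltrace.errors import AmbiguousNestingError, DegenerateGeometryError
from myeltrace.grouping import assemble_fibers, nests_within, point_in_polygon
from oracles import rasterized_nesting, star_polygon, winding_classification

UNIT_SQUARE = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)


def square(cx, cy, side, cid=0):
    h = side / 2.0
    return Contour(
        vertices=np.array(
            [[cx - h, cy - h], [cx + h, cy - h], [cx + h, cy + h], [cx - h, cy + h]], float
        ),
        id=cid,
    )


class TestPointInPolygon:
    @pytest.mark.parametrize(
        "point,expected",
        [((0.5, 0.5), "inside"), ((5, 5), "outside"), ((-0.1, 0.5), "outside"),
         ((0.0, 0.5), "boundary"), ((1.0, 1.0), "boundary")],
    )
    def test_unit_square(self, point, expected):
        assert point_in_polygon(point, UNIT_SQUARE) == expected

    def test_degenerate_polygon_rejected(self):
        collapsed = np.array([[0, 0], [1, 1], [2, 2]], float)
        with pytest.raises(DegenerateGeometryError):
            point_in_polygon((0.5, 0.5), collapsed)

    @given(st.floats(-3, 3), st.floats(-3, 3))
    def test_reversal_invariance(self, x, y):
        poly = np.array([[0, 0], [2, 0.5], [2.5, 2], [1, 3], [-0.5, 1.5]], float)
        assert point_in_polygon((x, y), poly) == point_in_polygon((x, y), poly[::-1])

    def test_matches_winding_oracle_on_random_dodecagons(self, rng):
        for _ in range(25):
            poly = star_polygon(rng, n_vertices=12, radius_range=(5.0, 15.0))
            pts = rng.uniform(-18, 18, size=(40, 2))
            for p in pts:
                assert point_in_polygon(p, poly) == winding_classification(p, poly)


class TestNestsWithin:
    def test_concentric_squares(self):
        assert nests_within(square(5, 5, 2), square(5, 5, 10))
        assert not nests_within(square(5, 5, 10), square(5, 5, 2))

    def test_disjoint_squares(self):
        assert not nests_within(square(0, 0, 1), square(10, 10, 1))

    def test_half_overlapping_congruent_squares(self):
        a, b = square(0, 0, 4), square(2, 0, 4)
        assert not nests_within(a, b) and not nests_within(b, a)
        assert not rasterized_nesting(a.vertices, b.vertices)

    def test_partial_overlap_strict_mode_matches_raster_oracle(self):
        inner, outer = square(1.5, 0, 2), square(0, 0, 4)  # pokes out on the right
        assert nests_within(inner, outer, strict=True) == rasterized_nesting(
            inner.vertices, outer.vertices
        )

    def test_degenerate_rejected(self):
        line = Contour(vertices=np.array([[0, 0], [1, 0], [2, 0]], float), id=9)
        with pytest.raises(DegenerateGeometryError):
            nests_within(line, square(0, 0, 4))


def triple(cx, cy, base_id):
    """axon, inner, outer concentric squares at (cx, cy)."""
    return (
        square(cx, cy, 4, base_id),
        square(cx, cy, 6, base_id + 1),
        square(cx, cy, 8, base_id + 2),
    )


class TestAssembleFibers:
    def test_two_disjoint_triples(self):
        a1, i1, o1 = triple(10, 10, 0)
        a2, i2, o2 = triple(40, 40, 10)
        groups, unmatched = assemble_fibers([a1, a2], [i1, i2], [o1, o2])
        assert len(groups) == 2 and unmatched == []
        assert [g.selection_index for g in groups] == [1, 2]
        assert groups[0].axon is a1 and groups[0].inner is i1 and groups[0].outer is o1

    def test_selection_order_follows_axon_list(self):
        a1, i1, o1 = triple(10, 10, 0)
        a2, i2, o2 = triple(40, 40, 10)
        groups, _ = assemble_fibers([a2, a1], [i1, i2], [o1, o2])
        assert groups[0].axon is a2 and groups[1].axon is a1

    def test_inner_without_outer_is_unmatched(self):
        _, i1, _ = triple(10, 10, 0)
        groups, unmatched = assemble_fibers([], [i1], [])
        assert groups == [] and len(unmatched) == 1
        assert unmatched[0].role == "inner" and unmatched[0].contour is i1

    def test_smallest_containing_outer_wins(self):
        big = square(20, 20, 30, 0)
        small = square(20, 20, 12, 1)
        inner = square(20, 20, 6, 2)
        groups, unmatched = assemble_fibers([], [inner], [big, small])
        assert len(groups) == 1 and groups[0].outer is small
        assert {u.contour.id for u in unmatched} == {0}  # big outer left over

    def test_axonless_group_allowed(self):
        _, i1, o1 = triple(10, 10, 0)
        groups, unmatched = assemble_fibers([], [i1], [o1])
        assert len(groups) == 1 and groups[0].axon is None and unmatched == []

    def test_ambiguous_inners_raise_by_default(self):
        outer = square(20, 20, 20, 0)
        in_a, in_b = square(16, 20, 4, 1), square(24, 20, 4, 2)
        with pytest.raises(AmbiguousNestingError) as exc:
            assemble_fibers([], [in_a, in_b], [outer])
        assert exc.value.child_ids == [1, 2]

    def test_ambiguity_policy_first_keeps_first_selected(self):
        outer = square(20, 20, 20, 0)
        in_a, in_b = square(16, 20, 4, 1), square(24, 20, 4, 2)
        groups, unmatched = assemble_fibers([], [in_b, in_a], [outer], on_ambiguity="first")
        assert len(groups) == 1 and groups[0].inner is in_b
        assert [u.contour.id for u in unmatched] == [in_a.id]

    def test_every_contour_appears_exactly_once(self, rng):
        axons, inners, outers = [], [], []
        cid = 0
        for k in range(6):
            a, i, o = triple(15 + 30 * k, 15, cid)
            cid += 10
            axons.append(a)
            inners.append(i)
            outers.append(o)
        # add strays: an inner with no outer, an outer with no inner, a lone axon
        inners.append(square(300, 300, 6, 100))
        outers.append(square(400, 400, 8, 101))
        axons.append(square(500, 500, 4, 102))
        groups, unmatched = assemble_fibers(axons, inners, outers)
        placed = []
        for g in groups:
            placed += [c.id for c in (g.axon, g.inner, g.outer) if c is not None]
        placed += [u.contour.id for u in unmatched]
        everything = [c.id for c in axons + inners + outers]
        assert sorted(placed) == sorted(everything)
        assert len(groups) <= min(len(inners), len(outers))

    def test_permutation_invariance_of_grouping(self, rng):
        axons, inners, outers = [], [], []
        for k in range(5):
            a, i, o = triple(15 + 30 * k, 15, 10 * k)
            axons.append(a)
            inners.append(i)
            outers.append(o)
        base, _ = assemble_fibers(axons, inners, outers)
        perm_in = [inners[j] for j in rng.permutation(5)]
        perm_out = [outers[j] for j in rng.permutation(5)]
        shuffled, _ = assemble_fibers(axons, perm_in, perm_out)
        base_sets = [(g.axon.id, g.inner.id, g.outer.id) for g in base]
        shuf_sets = [(g.axon.id, g.inner.id, g.outer.id) for g in shuffled]
        assert base_sets == shuf_sets  # axon order fixes group order

    def test_fiber_count_on_phantom_scenarios(self, scenarios):
        from myeltrace.contours import contour_depths, extract_contours, filter_contours
        from myeltrace.preprocess import binarize, smooth

        sc = scenarios["clean_isolated"]
        smoothed = smooth(sc.image)
        axon_mask = binarize(smoothed, sc.axon_threshold)
        myelin_mask = binarize(smoothed, sc.myelin_threshold)
        ax = extract_contours(axon_mask)
        my = extract_contours(myelin_mask)
        ax_d, my_d = contour_depths(ax), contour_depths(my)
        axons = [c for c in filter_contours(ax, sc.constraints) if ax_d[c.id] % 2 == 1]
        outers = [c for c in filter_contours(my, sc.constraints) if my_d[c.id] % 2 == 0]
        inners = [c for c in filter_contours(my, sc.constraints) if my_d[c.id] % 2 == 1]
        groups, unmatched = assemble_fibers(axons, inners, outers)
        assert len(groups) == len(sc.truth.fibers)
        assert all(g.axon is not None for g in groups)
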