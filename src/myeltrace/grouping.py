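"""Assembly of axon / inner-myelin / outer-myelin contours into fibers.

A myelinated fiber in cross-section is three nested closed curves: the axon
membrane, the inner (adaxonal) myelin boundary and the outer (abaxonal) myelin
boundary, with the periaxonal space between axon and inner myelin. Grouping is
purely geometric: each inner boundary is assigned to the smallest outer
boundary it nests within, and each axon to the smallest matched inner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple, Optional

from shapely.geometry import Polygon as _ShPolygon

from .contours import Contour
from .errors import AmbiguousNestingError, DegenerateGeometryError
from .geometry import point_location, shoelace_area

__all__ = [
    "FiberGroup",
    "Unmatched",
    "point_in_polygon",
    "nests_within",
    "assemble_fibers",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class FiberGroup:
    """One fiber: nested (axon?, inner, outer) contours.

    ``axon`` may be None (e.g. an obscured axon membrane); the g-ratio only
    needs the myelin pair. ``selection_index`` is the 1-based order in which
    the fiber's axon was selected and fixes CSV row order and overlay labels.
    """

    inner: Contour
    outer: Contour
    axon: Optional[Contour] = None
    selection_index: int = 1


class Unmatched(NamedTuple):
    """A selected contour that could not be placed in any fiber group."""

    role: str  # "axon" | "inner" | "outer"
    contour: Contour
    reason: str


def point_in_polygon(point, contour) -> str:
    """Tri-state containment test: ``"inside"``, ``"outside"`` or ``"boundary"``.

    Even-odd ray casting with an explicit on-edge check; the classification is
    invariant under reversal of the vertex order.
    """
    verts = contour.vertices if isinstance(contour, Contour) else contour
    return point_location(point, verts)


def _rep_point(verts):
    """A point strictly interior to the polygon (robust for non-convex shapes)."""
    p = _ShPolygon(verts).representative_point()
    return (p.x, p.y)


def nests_within(inner, outer, strict: bool = False) -> bool:
    """True iff ``inner`` lies strictly inside ``outer``.

    Default test: a representative interior point of ``inner`` is inside
    ``outer`` and ``inner`` has the smaller area — sufficient for
    non-crossing contours from a single mask. ``strict=True`` additionally
    requires full polygon containment, guarding against partially overlapping
    hand-supplied polygons.
    """
    vi = inner.vertices if isinstance(inner, Contour) else inner
    vo = outer.vertices if isinstance(outer, Contour) else outer
    ai, ao = shoelace_area(vi), shoelace_area(vo)
    if ai <= 0 or ao <= 0:
        raise DegenerateGeometryError("zero-area polygon in nesting test")
    if ai >= ao:
        return False
    if point_location(_rep_point(vi), vo) != "inside":
        return False
    if strict:
        return _ShPolygon(vo).contains(_ShPolygon(vi))
    return True


def _match_to_smallest(children, parents, strict=False):
    """For each child, the index of the smallest-area parent it nests in."""
    parent_areas = [shoelace_area(p.vertices) for p in parents]
    out = []
    for child in children:
        best, best_area = None, float("inf")
        for j, parent in enumerate(parents):
            if parent_areas[j] < best_area and nests_within(child, parent, strict=strict):
                best, best_area = j, parent_areas[j]
        out.append(best)
    return out


def assemble_fibers(
    axons,
    inners,
    outers,
    *,
    on_ambiguity: str = "error",
    strict: bool = False,
):
    """Group selected contours into fibers by nesting.

    Each inner boundary is matched to the smallest outer it nests within, each
    axon to the smallest matched inner containing it. Groups are ordered by
    axon selection order (axonless groups follow, in inner selection order);
    every input contour comes back exactly once, either in a group or in the
    unmatched list.

    Two inners claiming the same outer is anatomically ambiguous (e.g. double
    myelination): ``on_ambiguity="error"`` raises
    :class:`AmbiguousNestingError`; ``"first"`` keeps the first-selected inner
    and reports the rest unmatched with a warning.

    Returns ``(groups, unmatched)``.
    """
    if on_ambiguity not in ("error", "first"):
        raise ValueError("on_ambiguity must be 'error' or 'first'")

    unmatched: list[Unmatched] = []

    inner_to_outer = _match_to_smallest(inners, outers, strict=strict)
    claims: dict[int, list[int]] = {}
    for i, j in enumerate(inner_to_outer):
        if j is None:
            unmatched.append(Unmatched("inner", inners[i], "no containing outer contour"))
            log.warning("inner contour %d nests in no outer contour", inners[i].id)
        else:
            claims.setdefault(j, []).append(i)

    pair_of_outer: dict[int, int] = {}
    for j, claimants in claims.items():
        if len(claimants) > 1:
            ids = [inners[i].id for i in claimants]
            if on_ambiguity == "error":
                raise AmbiguousNestingError(outers[j].id, ids)
            log.warning(
                "inner contours %s all nest in outer contour %d; keeping the "
                "first-selected (%d)",
                ids, outers[j].id, ids[0],
            )
            for i in claimants[1:]:
                unmatched.append(
                    Unmatched("inner", inners[i], f"outer contour {outers[j].id} already claimed")
                )
        pair_of_outer[j] = claimants[0]

    for j, outer in enumerate(outers):
        if j not in pair_of_outer:
            unmatched.append(Unmatched("outer", outer, "contains no inner contour"))
            log.warning("outer contour %d contains no inner contour", outer.id)

    matched_inner_idx = sorted(pair_of_outer.values())
    matched_inners = [inners[i] for i in matched_inner_idx]
    axon_to_inner = _match_to_smallest(axons, matched_inners, strict=strict)
    axon_of_inner: dict[int, int] = {}
    for a, k in enumerate(axon_to_inner):
        if k is None:
            unmatched.append(Unmatched("axon", axons[a], "no containing inner contour"))
            log.warning("axon contour %d nests in no matched inner contour", axons[a].id)
            continue
        i = matched_inner_idx[k]
        if i in axon_of_inner:
            unmatched.append(
                Unmatched("axon", axons[a], f"inner contour {inners[i].id} already has an axon")
            )
            log.warning(
                "axon contours %d and %d both nest in inner contour %d; keeping the first",
                axons[axon_of_inner[i]].id, axons[a].id, inners[i].id,
            )
        else:
            axon_of_inner[i] = a

    outer_of_inner = {i: j for j, i in pair_of_outer.items()}
    # axon selection order first, then axonless pairs in inner selection order
    with_axon = sorted(axon_of_inner.items(), key=lambda kv: kv[1])
    without_axon = [i for i in matched_inner_idx if i not in axon_of_inner]

    groups: list[FiberGroup] = []
    for i, a in with_axon:
        groups.append(
            FiberGroup(
                inner=inners[i],
                outer=outers[outer_of_inner[i]],
                axon=axons[a],
                selection_index=len(groups) + 1,
            )
        )
    for i in without_axon:
        groups.append(
            FiberGroup(
                inner=inners[i],
                outer=outers[outer_of_inner[i]],
                axon=None,
                selection_index=len(groups) + 1,
            )
        )
    return groups, unmatched
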