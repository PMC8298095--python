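"""Per-contour and per-fiber morphometry.

Area comes from the shoelace formula on the boundary polygon, perimeter from
the closed sum of edge lengths, and every diameter is the equivalent-circle
diameter 2*sqrt(A/pi) — the diameter of the perfect circle with the measured
area, which is the convention used for fiber calibers in EM morphometry.

The g-ratio of a fiber is by default the diameter ratio

    g = d / D = sqrt(A_inner / A_outer)

where d and D are the equivalent diameters of the inner and outer myelin
boundaries (typical healthy values ~0.6-0.8; higher means thinner myelin). A
raw area-ratio mode (``g = A_inner / A_outer``) is provided for replication of
outputs that report the un-rooted ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import (
    DegenerateGeometryError,
    EmptyCountError,
    NestingViolationError,
)
from .geometry import as_vertex_array, closed_perimeter, shoelace_area
from .grouping import FiberGroup

__all__ = [
    "PixelScale",
    "MyelinationCount",
    "FiberMeasurements",
    "polygon_area",
    "polygon_perimeter",
    "equivalent_diameter",
    "compute_g_ratio",
    "measure_fiber",
    "measure_manual_polygon",
    "percent_myelinated",
]


@dataclass(frozen=True)
class PixelScale:
    """Physical calibration; linear quantities scale by microns_per_pixel,
    areas by its square. Without a scale all outputs are in pixel units."""

    microns_per_pixel: float

    def __post_init__(self):
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be > 0")


@dataclass(frozen=True)
class MyelinationCount:
    """Tally for the myelinated-fraction counting tool."""

    n_myelinated: int
    n_unmyelinated: int

    def __post_init__(self):
        if self.n_myelinated < 0 or self.n_unmyelinated < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class FiberMeasurements:
    """Morphometry of one fiber; axon fields are None for axonless groups.

    ``unit`` is "px" (areas px^2) or "um" (areas um^2); the g-ratio is
    dimensionless and independent of calibration.
    """

    selection_index: int
    inner_area: float
    inner_perimeter: float
    inner_diameter: float
    outer_area: float
    outer_perimeter: float
    outer_diameter: float
    g_ratio: float
    axon_area: Optional[float] = None
    axon_perimeter: Optional[float] = None
    axon_diameter: Optional[float] = None
    unit: str = "px"


def polygon_area(contour) -> float:
    """Unsigned shoelace area of a closed polygon (contour or vertex array)."""
    return shoelace_area(_verts(contour))


def polygon_perimeter(contour) -> float:
    """Closed perimeter: sum of Euclidean edge lengths, including the closing
    edge; invariant to cyclic rotation and reversal of the vertex list."""
    return closed_perimeter(_verts(contour))


def _verts(contour):
    return getattr(contour, "vertices", contour)


def equivalent_diameter(area: float) -> float:
    """Diameter of the circle whose area equals ``area``: 2*sqrt(area/pi)."""
    if area < 0:
        raise ValueError(f"area must be non-negative, got {area}")
    return 2.0 * math.sqrt(area / math.pi)


def compute_g_ratio(inner_area: float, outer_area: float, mode: str = "diameter") -> float:
    """g-ratio from inner and outer myelin areas.

    mode="diameter" (default): sqrt(inner/outer), identical to the equivalent
    inner diameter divided by the equivalent outer diameter. mode="area": the
    raw area ratio.
    """
    if outer_area <= 0:
        raise DegenerateGeometryError("outer area must be positive")
    if inner_area <= 0:
        raise DegenerateGeometryError("inner area must be positive")
    if inner_area > outer_area:
        raise NestingViolationError(
            f"inner area {inner_area} exceeds outer area {outer_area}"
        )
    ratio = inner_area / outer_area
    if mode == "diameter":
        return math.sqrt(ratio)
    if mode == "area":
        return ratio
    raise ValueError(f"g_ratio mode must be 'diameter' or 'area', got {mode!r}")


def measure_fiber(
    group: FiberGroup,
    scale: Optional[PixelScale] = None,
    g_ratio_mode: str = "diameter",
) -> FiberMeasurements:
    """All measurements for one fiber group.

    Geometry errors are re-raised with the fiber's selection index attached so
    a bad fiber can be located in a large session.
    """
    lin = scale.microns_per_pixel if scale else 1.0
    try:
        inner_a = polygon_area(group.inner)
        outer_a = polygon_area(group.outer)
        g = compute_g_ratio(inner_a, outer_a, mode=g_ratio_mode)
        axon_fields = {}
        if group.axon is not None:
            axon_a = polygon_area(group.axon)
            axon_fields = dict(
                axon_area=axon_a * lin * lin,
                axon_perimeter=polygon_perimeter(group.axon) * lin,
                axon_diameter=equivalent_diameter(axon_a) * lin,
            )
        return FiberMeasurements(
            selection_index=group.selection_index,
            inner_area=inner_a * lin * lin,
            inner_perimeter=polygon_perimeter(group.inner) * lin,
            inner_diameter=equivalent_diameter(inner_a) * lin,
            outer_area=outer_a * lin * lin,
            outer_perimeter=polygon_perimeter(group.outer) * lin,
            outer_diameter=equivalent_diameter(outer_a) * lin,
            g_ratio=g,
            unit="um" if scale else "px",
            **axon_fields,
        )
    except (DegenerateGeometryError, NestingViolationError) as exc:
        raise type(exc)(f"fiber {group.selection_index}: {exc}") from exc


def measure_manual_polygon(points, scale: Optional[PixelScale] = None):
    """Area, perimeter and equivalent diameter of a hand-traced polygon.

    Duplicate consecutive points (zero-length edges) are collapsed before
    measurement; fewer than three distinct points is degenerate.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 3:
        raise DegenerateGeometryError(
            f"manual trace needs >= 3 (x, y) points, got shape {pts.shape}"
        )
    keep = np.any(pts != np.roll(pts, 1, axis=0), axis=1)
    pts = pts[keep]
    if len(pts) < 3:
        raise DegenerateGeometryError("manual trace has < 3 distinct points")
    v = as_vertex_array(pts)
    lin = scale.microns_per_pixel if scale else 1.0
    area = shoelace_area(v)
    return area * lin * lin, closed_perimeter(v) * lin, equivalent_diameter(area) * lin


def percent_myelinated(count: MyelinationCount) -> float:
    """Percentage of axons that are myelinated, 100 * m / (m + u)."""
    total = count.n_myelinated + count.n_unmyelinated
    if total == 0:
        raise EmptyCountError("cannot compute a percentage from zero counted axons")
    return 100.0 * count.n_myelinated / total
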