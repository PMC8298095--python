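"""Low-level polygon primitives shared across the package.

All polygons are arrays of ``(x, y)`` vertices in pixel coordinates
(x = column, y = row, origin at the top-left pixel center, 0-based). Polygons
are implicitly closed: the edge from the last vertex back to the first is
always included and callers never repeat the first vertex.
"""

from __future__ import annotations

import numpy as np

from .errors import DegenerateGeometryError

__all__ = [
    "as_vertex_array",
    "shoelace_area",
    "closed_perimeter",
    "polygon_centroid",
    "compress_collinear",
    "point_location",
]

#: squared-distance tolerance for "point lies on an edge"
_BOUNDARY_EPS = 1e-9


def as_vertex_array(vertices) -> np.ndarray:
    """Coerce a vertex sequence to a float ``(n, 2)`` array, validating shape."""
    arr = np.asarray(vertices, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise DegenerateGeometryError(
            f"polygon needs an (n>=3, 2) vertex array, got shape {arr.shape}"
        )
    return arr


def shoelace_area(vertices) -> float:
    """Unsigned polygon area by the shoelace formula.

    Independent of vertex orientation and of which vertex starts the chain.
    """
    v = as_vertex_array(vertices)
    x, y = v[:, 0], v[:, 1]
    cross = x * np.roll(y, -1) - np.roll(x, -1) * y
    return abs(float(cross.sum())) / 2.0


def closed_perimeter(vertices) -> float:
    """Sum of Euclidean edge lengths of the closed polygon."""
    v = as_vertex_array(vertices)
    d = np.roll(v, -1, axis=0) - v
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def polygon_centroid(vertices) -> tuple[float, float]:
    """Area-weighted centroid; falls back to the vertex mean for zero area."""
    v = as_vertex_array(vertices)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = float(cross.sum()) / 2.0
    if abs(a) < 1e-12:
        return float(x.mean()), float(y.mean())
    cx = float(((x + xn) * cross).sum()) / (6.0 * a)
    cy = float(((y + yn) * cross).sum()) / (6.0 * a)
    return cx, cy


def compress_collinear(vertices, tol: float = 1e-9) -> np.ndarray:
    """Drop interior vertices of collinear runs, keeping only run endpoints.

    Operates cyclically, so a run that wraps past the chain start is also
    compressed. Exactly repeated consecutive vertices are removed first.
    """
    v = np.asarray(vertices, dtype=float)
    if len(v) == 0:
        return v.reshape(0, 2)
    # collapse exact consecutive duplicates (cyclically)
    keep = np.any(v != np.roll(v, 1, axis=0), axis=1)
    if not keep.any():  # all vertices identical
        return v[:1]
    v = v[keep]
    if len(v) < 3:
        return v
    prev = np.roll(v, 1, axis=0)
    nxt = np.roll(v, -1, axis=0)
    d1 = v - prev
    d2 = nxt - v
    cross = d1[:, 0] * d2[:, 1] - d1[:, 1] * d2[:, 0]
    corner = np.abs(cross) > tol
    if corner.all():
        return v
    if not corner.any():
        return v[:2]
    return v[corner]


def point_location(point, vertices) -> str:
    """Classify ``point`` against the closed polygon: inside/outside/boundary.

    Uses even-odd ray casting with an explicit on-edge test; the result is
    invariant under reversal of the vertex order. Raises
    :class:`DegenerateGeometryError` for zero-area polygons.
    """
    v = as_vertex_array(vertices)
    if shoelace_area(v) <= 0.0:
        raise DegenerateGeometryError("zero-area polygon in point test")
    px, py = float(point[0]), float(point[1])
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)

    # boundary: squared distance from point to each closed edge
    ex, ey = xn - x, yn - y
    seg_len2 = ex * ex + ey * ey
    t = np.where(seg_len2 > 0, ((px - x) * ex + (py - y) * ey) / np.where(seg_len2 > 0, seg_len2, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    dx, dy = px - (x + t * ex), py - (y + t * ey)
    if float((dx * dx + dy * dy).min()) <= _BOUNDARY_EPS:
        return "boundary"

    # even-odd crossing count with the half-open rule on y
    cond = (y > py) != (yn > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        xint = x + (py - y) / (yn - y) * ex
    crossings = int(np.count_nonzero(cond & (px < xint)))
    return "inside" if crossings % 2 == 1 else "outside"
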