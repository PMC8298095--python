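"""Independent oracles used by the test suite.

Each oracle recomputes a quantity by a route disjoint from the library code it
checks: brute-force rasterization, direct double loops over the defining
formula, or signed-angle winding sums.
"""

from __future__ import annotations

import math

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage as ndi


def supersampled_area(vertices, factor: int = 10) -> float:
    """Polygon area by counting sample points on a ``factor``-times-finer grid."""
    v = np.asarray(vertices, dtype=float)
    x0, y0 = np.floor(v.min(axis=0)) - 1
    x1, y1 = np.ceil(v.max(axis=0)) + 1
    step = 1.0 / factor
    xs = np.arange(x0 + step / 2, x1, step)
    ys = np.arange(y0 + step / 2, y1, step)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    inside = MplPath(v).contains_points(pts)
    return inside.sum() * step * step


def winding_classification(point, vertices, eps: float = 1e-12) -> str:
    """Point-in-polygon by summing signed angles subtended by each edge."""
    v = np.asarray(vertices, dtype=float)
    d = v - np.asarray(point, dtype=float)
    dn = np.roll(d, -1, axis=0)
    cross = d[:, 0] * dn[:, 1] - d[:, 1] * dn[:, 0]
    dot = d[:, 0] * dn[:, 0] + d[:, 1] * dn[:, 1]
    r2 = d[:, 0] ** 2 + d[:, 1] ** 2
    if (r2 < eps).any() or ((np.abs(cross) < eps) & (dot <= 0)).any():
        return "boundary"
    total = np.arctan2(cross, dot).sum()
    return "inside" if abs(total) > math.pi else "outside"


def rasterized_nesting(inner_vertices, outer_vertices, factor: int = 8) -> bool:
    """Full-containment check: every supersampled interior point of the inner
    polygon lies inside the outer polygon, and the inner is strictly smaller."""
    vi = np.asarray(inner_vertices, dtype=float)
    vo = np.asarray(outer_vertices, dtype=float)
    ai, ao = supersampled_area(vi, factor), supersampled_area(vo, factor)
    if ai >= ao:
        return False
    x0, y0 = np.floor(vi.min(axis=0)) - 1
    x1, y1 = np.ceil(vi.max(axis=0)) + 1
    step = 1.0 / factor
    xs = np.arange(x0 + step / 2, x1, step)
    ys = np.arange(y0 + step / 2, y1, step)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    in_inner = MplPath(vi).contains_points(pts)
    if not in_inner.any():
        return False
    return bool(MplPath(vo).contains_points(pts[in_inner]).all())


def bilateral_reference(image, d: int, sigma_color: float, sigma_space: float) -> np.ndarray:
    """Direct double-loop evaluation of the bilateral-filter formula
    (circular window, replicate border)."""
    img = np.asarray(image, dtype=float)
    r = d // 2
    padded = np.pad(img, r, mode="edge")
    out = np.empty_like(img)
    h, w = img.shape
    for y in range(h):
        for x in range(w):
            center = img[y, x]
            num = den = 0.0
            for dy in range(-r, r + 1):
                for dx in range(-r, r + 1):
                    if dx * dx + dy * dy > r * r:
                        continue
                    val = padded[y + dy + r, x + dx + r]
                    wgt = math.exp(-(dx * dx + dy * dy) / (2 * sigma_space**2)) * math.exp(
                        -((val - center) ** 2) / (2 * sigma_color**2)
                    )
                    num += wgt * val
                    den += wgt
            out[y, x] = num / den
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def count_boundary_components(mask) -> int:
    """Expected number of black/white boundary contours of a binary mask.

    One contour per black component (4-connected, matching the tracer's
    feature connectivity) plus one per interior white component (8-connected),
    i.e. white regions not connected to a white frame around the image.
    """
    arr = np.asarray(mask)
    black = arr == 0
    n_black = ndi.label(black, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])[1]
    white_padded = np.pad(~black, 1, constant_values=True)
    labels, n_white = ndi.label(white_padded, structure=np.ones((3, 3)))
    border_label = labels[0, 0]
    interior_white = len(set(np.unique(labels[labels > 0])) - {border_label})
    return n_black + interior_white


def black_component_count(mask, connectivity: int = 1) -> int:
    """Number of black (0) connected components; connectivity 1 = 4-connected."""
    structure = (
        [[0, 1, 0], [1, 1, 1], [0, 1, 0]] if connectivity == 1 else np.ones((3, 3))
    )
    return ndi.label(np.asarray(mask) == 0, structure=structure)[1]


def star_polygon(rng, n_vertices=None, radius_range=(15.0, 50.0), center=(0.0, 0.0)):
    """A random simple (star-shaped) polygon around ``center``."""
    n = int(n_vertices if n_vertices is not None else rng.integers(8, 30))
    angles = np.sort(rng.uniform(0, 2 * math.pi, n))
    radii = rng.uniform(*radius_range, n)
    cx, cy = center
    return np.column_stack([cx + radii * np.cos(angles), cy + radii * np.sin(angles)])
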