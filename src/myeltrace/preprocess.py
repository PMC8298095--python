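"""Micrograph preprocessing: grayscale conversion, edge-preserving smoothing,
binary thresholding and stroke-based mask editing.

Images are plain numpy arrays, the idiomatic raster container of the scientific
Python imaging stack: ``uint8`` of shape ``(H, W)`` for grayscale or
``(H, W, 3)`` for RGB. Binary masks are ``uint8`` arrays restricted to the two
values {0 (black, feature), 255 (white, background)}.

The processing order mirrors the quantification workflow: grayscale -> bilateral
smoothing -> threshold -> user strokes applied to the thresholded mask.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage as ndi
from skimage.draw import line as _draw_line
from skimage.morphology import disk as _disk

from .errors import (
    StrokeBoundsError,
    ThresholdRangeError,
    UnsupportedImageError,
)

__all__ = [
    "ThresholdConfig",
    "Stroke",
    "load_image",
    "to_grayscale",
    "smooth",
    "binarize",
    "apply_strokes",
    "load_strokes",
    "save_strokes",
]

# BT.601 luminance weights as integer per-mille factors; exact for uniform
# gray input and truncating like the common converters
_LUMA_MILLE = np.array([299, 587, 114], dtype=np.int64)


@dataclass(frozen=True)
class ThresholdConfig:
    """Parameters of the smoothing + thresholding stage.

    ``t`` is the 8-bit threshold: intensities <= t map to black (0), the rest
    to white (255). The bilateral-filter defaults (circular window of diameter
    9 px, range and spatial sigmas of 75) are the tool's standard smoothing
    settings for transmission-EM micrographs.
    """

    t: int = 128
    filter_diameter: int = 9
    sigma_color: float = 75.0
    sigma_space: float = 75.0

    def __post_init__(self):
        if not 0 <= self.t <= 255:
            raise ThresholdRangeError(f"threshold t={self.t} outside [0, 255]")
        if self.filter_diameter < 1 or self.filter_diameter % 2 == 0:
            raise ValueError("filter_diameter must be an odd integer >= 1")
        if self.sigma_color <= 0 or self.sigma_space <= 0:
            raise ValueError("bilateral sigmas must be positive")


@dataclass(frozen=True)
class Stroke:
    """A user-drawn polyline applied to the binary mask.

    mode="cut" paints white (background) — used to sever touching sheaths or to
    open a myelin fold onto the exterior; mode="draw" paints black (feature) —
    used to bridge locally discontinuous sheaths. ``target`` selects which
    threshold pass the stroke edits in the two-pass pipeline.
    """

    vertices: tuple = ()
    mode: str = "cut"
    width: int = 3
    target: str = "myelin"

    def __post_init__(self):
        if self.mode not in ("cut", "draw"):
            raise ValueError(f"stroke mode must be 'cut' or 'draw', got {self.mode!r}")
        if self.width < 1:
            raise ValueError("stroke width must be >= 1 px")
        if len(self.vertices) < 2:
            raise ValueError("a stroke needs at least 2 vertices")
        object.__setattr__(self, "vertices", tuple((float(x), float(y)) for x, y in self.vertices))

    @property
    def paint_value(self) -> int:
        return 255 if self.mode == "cut" else 0


def load_image(path) -> np.ndarray:
    """Read an 8-bit PNG/TIFF micrograph as a grayscale or RGB array.

    Rejects 16-bit data, multi-page stacks and channel layouts other than
    1 or 3 with :class:`UnsupportedImageError`.
    """
    arr = iio.imread(Path(path))
    if arr.dtype != np.uint8:
        raise UnsupportedImageError(
            f"{path}: expected 8-bit intensities, got dtype {arr.dtype}"
        )
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 3:
        return arr
    raise UnsupportedImageError(
        f"{path}: expected a single grayscale page or an RGB image, got shape {arr.shape}"
    )


def _check_gray(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 2:
        raise UnsupportedImageError(f"expected a single-channel image, got shape {img.shape}")
    return img


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB image to scalar intensity; grayscale passes through.

    RGB is mixed with the BT.601 luminance weights (0.299, 0.587, 0.114) and
    truncated to integer, so a uniform gray pixel (v, v, v) maps to v.
    """
    img = np.asarray(image)
    if img.ndim == 2:
        return img.copy()
    if img.ndim == 3 and img.shape[2] == 3:
        return ((img.astype(np.int64) @ _LUMA_MILLE) // 1000).astype(np.uint8)
    raise UnsupportedImageError(
        f"grayscale conversion needs 1 or 3 channels, got shape {img.shape}"
    )


def smooth(image: np.ndarray, cfg: ThresholdConfig = ThresholdConfig()) -> np.ndarray:
    """Edge-preserving bilateral filter.

    Each output pixel is a normalized weighted mean over the circular window of
    diameter ``cfg.filter_diameter``; weights are the product of a spatial
    Gaussian (``sigma_space``, in pixels) and a range Gaussian on the intensity
    difference (``sigma_color``, in gray levels). Large intensity steps get
    near-zero range weight, so edges stay sharp while flat regions are
    averaged. Borders use replicate padding. Deterministic; output intensities
    never leave the input range.
    """
    img = _check_gray(image).astype(np.float64)
    r = cfg.filter_diameter // 2
    if r == 0:
        return _check_gray(image).copy()
    padded = np.pad(img, r, mode="edge")
    h, w = img.shape
    num = np.zeros_like(img)
    den = np.zeros_like(img)
    inv2_sc = 1.0 / (2.0 * cfg.sigma_color**2)
    inv2_ss = 1.0 / (2.0 * cfg.sigma_space**2)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if dx * dx + dy * dy > r * r:
                continue
            w_spatial = np.exp(-(dx * dx + dy * dy) * inv2_ss)
            shifted = padded[r + dy : r + dy + h, r + dx : r + dx + w]
            wgt = w_spatial * np.exp(-((shifted - img) ** 2) * inv2_sc)
            num += wgt * shifted
            den += wgt
    out = num / den
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)


def binarize(image: np.ndarray, t: int) -> np.ndarray:
    """Threshold to a two-valued mask: intensity <= t -> 0, otherwise -> 255.

    The equal case goes to black so that t = 255 is the all-black extreme and
    the white region shrinks monotonically as t grows.
    """
    if not 0 <= int(t) <= 255:
        raise ThresholdRangeError(f"threshold t={t} outside [0, 255]")
    img = _check_gray(image)
    return np.where(img <= int(t), 0, 255).astype(np.uint8)


def apply_strokes(mask: np.ndarray, strokes) -> np.ndarray:
    """Rasterize user strokes onto a binary mask, in list order.

    Cut strokes paint white (background), severing 8-connected feature paths;
    draw strokes paint black (feature), bridging gaps. Only pixels within the
    stroke width of the polyline are touched. Vertices outside the image raise
    :class:`StrokeBoundsError` naming the offending stroke.
    """
    out = np.asarray(mask).copy()
    h, w = out.shape
    for i, stroke in enumerate(strokes):
        pts = np.rint(np.asarray(stroke.vertices, dtype=float)).astype(int)
        for x, y in pts:
            if not (0 <= x < w and 0 <= y < h):
                raise StrokeBoundsError(i, (x, y), out.shape)
        sel = np.zeros_like(out, dtype=bool)
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            rr, cc = _draw_line(y0, x0, y1, x1)
            sel[rr, cc] = True
        radius = stroke.width // 2
        if radius > 0:
            sel = ndi.binary_dilation(sel, structure=_disk(radius))
        out[sel] = stroke.paint_value
    return out


def load_strokes(path) -> list[Stroke]:
    """Read strokes from a JSON file: a list of {mode, width, vertices, [target]}."""
    with open(path) as fh:
        raw = json.load(fh)
    return [
        Stroke(
            vertices=tuple((v[0], v[1]) for v in item["vertices"]),
            mode=item["mode"],
            width=int(item.get("width", 3)),
            target=item.get("target", "myelin"),
        )
        for item in raw
    ]


def save_strokes(strokes, path) -> None:
    payload = [
        {
            "mode": s.mode,
            "width": s.width,
            "target": s.target,
            "vertices": [[x, y] for x, y in s.vertices],
        }
        for s in strokes
    ]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
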