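"""Result persistence: measurement CSV, numbered overlay image, session file.

The CSV is RFC-4180, UTF-8, one row per fiber in axon-selection order, with
units embedded in the column names (``_px``/``_px2`` or ``_um``/``_um2``).
Floats are written at full precision so a write -> read round trip is exact.
"""

from __future__ import annotations

import csv
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image, ImageDraw, ImageFont

from .errors import SessionError, SessionVersionError
from .geometry import polygon_centroid
from .metrics import FiberMeasurements

__all__ = [
    "OverlayStyle",
    "SessionState",
    "SESSION_SCHEMA_VERSION",
    "measurement_columns",
    "write_measurements_csv",
    "read_measurements_csv",
    "render_overlay",
    "save_session",
    "load_session",
]

SESSION_SCHEMA_VERSION = 1

_FIELDS = [
    "axon_area", "axon_perimeter", "axon_diameter",
    "inner_area", "inner_perimeter", "inner_diameter",
    "outer_area", "outer_perimeter", "outer_diameter",
]


def measurement_columns(unit: str = "px") -> list[str]:
    """Column names with units: selection_index, axon/inner/outer area,
    perimeter and diameter, then g_ratio."""
    area_u, lin_u = (f"{unit}2", unit)
    cols = ["selection_index"]
    for name in _FIELDS:
        suffix = area_u if name.endswith("area") else lin_u
        cols.append(f"{name}_{suffix}")
    cols.append("g_ratio")
    return cols


def write_measurements_csv(fibers, path) -> None:
    """Write per-fiber measurements; an empty list yields a header-only file.

    Rows follow the order of ``fibers`` (i.e. axon selection order). Axon
    fields of axonless fibers are left empty.
    """
    fibers = list(fibers)
    unit = fibers[0].unit if fibers else "px"
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(measurement_columns(unit))
        for m in fibers:
            row = [m.selection_index]
            for name in _FIELDS:
                value = getattr(m, name)
                row.append("" if value is None else repr(float(value)))
            row.append(repr(float(m.g_ratio)))
            w.writerow(row)


def read_measurements_csv(path) -> list[FiberMeasurements]:
    """Inverse of :func:`write_measurements_csv` (used for round-trip checks
    and downstream aggregation)."""
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        if not header or header[0] != "selection_index":
            raise SessionError(f"{path}: not a myeltrace measurement CSV")
        unit = "um" if header[-2].endswith("_um") else "px"
        out = []
        for row in reader:
            values = {
                name: (None if cell == "" else float(cell))
                for name, cell in zip(_FIELDS, row[1:-1])
            }
            out.append(
                FiberMeasurements(
                    selection_index=int(row[0]),
                    g_ratio=float(row[-1]),
                    unit=unit,
                    **values,
                )
            )
        return out


@dataclass(frozen=True)
class OverlayStyle:
    color: tuple = (0, 0, 255)  # blue, the tool's traditional overlay color
    width: int = 2
    font_size: int = 16
    label: bool = True


def render_overlay(image: np.ndarray, fibers, path, style: OverlayStyle = OverlayStyle()) -> None:
    """Draw fiber contours and selection numbers over the micrograph.

    Output is an RGB PNG of identical dimensions; with zero fibers the pixels
    are identical to the input. Each fiber is numbered at its axon centroid
    (inner-contour centroid when the axon is absent). Deterministic for a
    fixed style.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    img = Image.fromarray(arr.astype(np.uint8), mode="RGB")
    draw = ImageDraw.Draw(img)
    try:
        font = ImageFont.load_default(size=style.font_size)
    except TypeError:  # older Pillow without sized default font
        font = ImageFont.load_default()
    for group in fibers:
        for contour in (group.axon, group.inner, group.outer):
            if contour is None:
                continue
            pts = [tuple(p) for p in contour.vertices]
            draw.line(pts + [pts[0]], fill=tuple(style.color), width=style.width)
        if style.label:
            anchor_contour = group.axon if group.axon is not None else group.inner
            cx, cy = polygon_centroid(anchor_contour.vertices)
            draw.text(
                (cx, cy), str(group.selection_index),
                fill=tuple(style.color), font=font, anchor="mm",
            )
    img.save(Path(path), format="PNG")


@dataclass(frozen=True)
class SessionState:
    """Everything needed to re-run a quantification and reproduce its CSV."""

    image_path: str
    axon_threshold: int
    myelin_threshold: int
    strokes: tuple = ()  # JSON-ready dicts {mode, width, target, vertices}
    selections: Optional[dict] = None  # class -> contour ids; None = auto
    min_size: float = 0.0
    max_size: float = float("inf")
    min_vertices: int = 5
    microns_per_pixel: Optional[float] = None
    g_ratio_mode: str = "diameter"
    exclude_border: bool = True
    counts: Optional[dict] = None  # {"n_myelinated": ..., "n_unmyelinated": ...}
    schema_version: int = SESSION_SCHEMA_VERSION


def save_session(state: SessionState, path) -> None:
    payload = asdict(state)
    payload["strokes"] = list(state.strokes)
    if payload["max_size"] == float("inf"):
        payload["max_size"] = None
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)


def load_session(path) -> SessionState:
    """Load a session; truncated/invalid JSON or a foreign schema version
    raises without returning partial state."""
    try:
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as exc:
        raise SessionError(f"{path}: not valid session JSON ({exc})") from exc
    if not isinstance(payload, dict) or "schema_version" not in payload:
        raise SessionError(f"{path}: missing schema_version")
    if payload["schema_version"] != SESSION_SCHEMA_VERSION:
        raise SessionVersionError(
            f"{path}: schema_version {payload['schema_version']} unsupported "
            f"(this build reads version {SESSION_SCHEMA_VERSION})"
        )
    try:
        if payload.get("max_size") is None:
            payload["max_size"] = float("inf")
        payload["strokes"] = tuple(payload.get("strokes", ()))
        return SessionState(**payload)
    except TypeError as exc:
        raise SessionError(f"{path}: malformed session ({exc})") from exc
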