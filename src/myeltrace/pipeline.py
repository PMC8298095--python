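"""Headless orchestration of the full quantification workflow.

One run reproduces the recommended interactive workflow without a GUI:

1. grayscale + bilateral smoothing of the micrograph;
2. an **axon pass** — threshold at ``axon_threshold`` so only bright axoplasm
   stays white; the white holes of the black field are the axon contours;
3. a **myelin pass** — threshold at ``myelin_threshold`` so only compact
   myelin is black; root contours are outer boundaries, their direct holes are
   inner boundaries;
4. user strokes (cut/draw) applied to the thresholded masks;
5. contour filtering, feature selection (explicit ids or auto), nesting-based
   grouping, measurement, and CSV/overlay/session export.

Every stage logs counts in and out, so a batch run can be quality-controlled
post hoc from the log alone.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import yaml

from . import preprocess
from .contours import SizeConstraints, contour_depths, extract_contours, filter_contours
from .errors import ConfigError, MyelTraceError
from .grouping import assemble_fibers
from .metrics import PixelScale, measure_fiber
from .preprocess import Stroke, ThresholdConfig
from .reporting import (
    OverlayStyle,
    SessionState,
    render_overlay,
    save_session,
    write_measurements_csv,
)

__all__ = ["PipelineConfig", "PipelineResult", "BatchResult", "run_pipeline", "run_batch"]

log = logging.getLogger(__name__)

CONFIG_SCHEMA_VERSION = 1
IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


@dataclass(frozen=True)
class PipelineConfig:
    """All parameters of a headless quantification run.

    Thresholds are the two user-set values of the interactive workflow; the
    defaults match the synthetic phantom intensity classes and must be tuned
    per acquisition for real micrographs. ``selection_file=None`` enables
    auto-selection: every filtered, (optionally) non-border contour of the
    appropriate nesting parity is taken as a feature candidate.
    """

    axon_threshold: int = 175
    myelin_threshold: int = 100
    filter_diameter: int = 9
    sigma_color: float = 75.0
    sigma_space: float = 75.0
    min_size: float = 50.0
    max_size: float = float("inf")
    min_vertices: int = 5
    stroke_file: Optional[str] = None
    selection_file: Optional[str] = None
    g_ratio_mode: str = "diameter"
    microns_per_pixel: Optional[float] = None
    exclude_border: bool = True
    on_ambiguity: str = "first"
    overlay_color: tuple = (0, 0, 255)
    overlay_width: int = 2
    overlay_font_size: int = 16
    output_dir: str = "myeltrace_out"

    def __post_init__(self):
        for name in ("axon_threshold", "myelin_threshold"):
            t = getattr(self, name)
            if not 0 <= t <= 255:
                raise ConfigError(f"{name}={t} outside [0, 255]")
        if self.g_ratio_mode not in ("diameter", "area"):
            raise ConfigError(f"g_ratio_mode must be 'diameter' or 'area', got {self.g_ratio_mode!r}")
        if self.on_ambiguity not in ("error", "first"):
            raise ConfigError("on_ambiguity must be 'error' or 'first'")
        if self.microns_per_pixel is not None and not self.microns_per_pixel > 0:
            raise ConfigError("microns_per_pixel must be > 0")
        try:
            self.constraints
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    @property
    def constraints(self) -> SizeConstraints:
        return SizeConstraints(self.min_size, self.max_size, self.min_vertices)

    @property
    def scale(self) -> Optional[PixelScale]:
        return PixelScale(self.microns_per_pixel) if self.microns_per_pixel else None

    @property
    def overlay_style(self) -> OverlayStyle:
        return OverlayStyle(
            color=tuple(self.overlay_color),
            width=self.overlay_width,
            font_size=self.overlay_font_size,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        version = raw.pop("config_version", CONFIG_SCHEMA_VERSION)
        if version != CONFIG_SCHEMA_VERSION:
            raise ConfigError(
                f"{path}: config_version {version} unsupported (expected {CONFIG_SCHEMA_VERSION})"
            )
        if raw.get("max_size") is None:
            raw["max_size"] = float("inf")
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(f"{path}: {exc}") from exc


@dataclass(frozen=True)
class PipelineResult:
    image_path: str
    groups: tuple
    measurements: tuple
    unmatched: tuple
    csv_path: Path
    overlay_path: Path
    session_path: Path


@dataclass(frozen=True)
class BatchResult:
    results: dict
    failures: dict
    combined_csv: Optional[Path]


def _load_selections(path) -> dict:
    with open(path) as fh:
        raw = json.load(fh)
    if not isinstance(raw, dict) or not set(raw) <= {"axon", "inner", "outer"}:
        raise ConfigError(f"{path}: selection file must map axon/inner/outer to id lists")
    return {k: list(v) for k, v in raw.items()}


def _pick_by_ids(contours, ids, role):
    by_id = {c.id: c for c in contours}
    missing = [i for i in ids if i not in by_id]
    if missing:
        raise ConfigError(f"selection for {role!r} names unknown contour ids {missing}")
    return [by_id[i] for i in ids]


def _segment(image, threshold, cfg, strokes, pass_name):
    mask = preprocess.binarize(image, threshold)
    if strokes:
        mask = preprocess.apply_strokes(mask, strokes)
    contours = extract_contours(mask)
    depths = contour_depths(contours)
    kept = filter_contours(contours, cfg.constraints)
    if cfg.exclude_border:
        n_border = sum(c.touches_border for c in kept)
        if n_border:
            log.info("%s pass: excluding %d border-touching contour(s): %s",
                     pass_name, n_border, [c.id for c in kept if c.touches_border])
        kept = [c for c in kept if not c.touches_border]
    log.info("%s pass: threshold=%d, %d contours extracted, %d retained",
             pass_name, threshold, len(contours), len(kept))
    return kept, depths


def run_pipeline(image_path, cfg: PipelineConfig, output_dir=None) -> PipelineResult:
    """Quantify one micrograph; writes CSV, overlay, session next to the log.

    Deterministic: the outputs depend only on the image bytes, the config and
    the stroke/selection files. Unmatched contours and border-touching fibers
    are logged with their contour ids, never silently dropped.
    """
    image_path = Path(image_path)
    outdir = Path(output_dir if output_dir is not None else cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    image = preprocess.load_image(image_path)
    gray = preprocess.to_grayscale(image)
    smoothed = preprocess.smooth(
        gray,
        ThresholdConfig(
            t=cfg.myelin_threshold,
            filter_diameter=cfg.filter_diameter,
            sigma_color=cfg.sigma_color,
            sigma_space=cfg.sigma_space,
        ),
    )
    strokes = preprocess.load_strokes(cfg.stroke_file) if cfg.stroke_file else []
    axon_strokes = [s for s in strokes if s.target == "axon"]
    myelin_strokes = [s for s in strokes if s.target == "myelin"]

    axon_contours, axon_depths = _segment(smoothed, cfg.axon_threshold, cfg, axon_strokes, "axon")
    myelin_contours, myelin_depths = _segment(
        smoothed, cfg.myelin_threshold, cfg, myelin_strokes, "myelin"
    )

    if cfg.selection_file:
        sel = _load_selections(cfg.selection_file)
        axons = _pick_by_ids(axon_contours, sel.get("axon", []), "axon")
        inners = _pick_by_ids(myelin_contours, sel.get("inner", []), "inner")
        outers = _pick_by_ids(myelin_contours, sel.get("outer", []), "outer")
    else:
        # auto-selection by nesting parity: in the axon pass the axoplasm
        # disks are holes (odd depth) of the dark field; in the myelin pass
        # sheath outer boundaries are roots (even depth) and inner boundaries
        # are their holes (odd depth)
        axons = [c for c in axon_contours if axon_depths[c.id] % 2 == 1]
        outers = [c for c in myelin_contours if myelin_depths[c.id] % 2 == 0]
        inners = [c for c in myelin_contours if myelin_depths[c.id] % 2 == 1]
    log.info("selection: %d axon, %d inner, %d outer candidates",
             len(axons), len(inners), len(outers))

    groups, unmatched = assemble_fibers(
        axons, inners, outers, on_ambiguity=cfg.on_ambiguity
    )
    for u in unmatched:
        log.warning("unmatched %s contour %d: %s", u.role, u.contour.id, u.reason)
    measurements = [measure_fiber(g, cfg.scale, cfg.g_ratio_mode) for g in groups]
    log.info("grouping: %d fibers, %d unmatched contours", len(groups), len(unmatched))

    stem = image_path.stem
    csv_path = outdir / f"{stem}_measurements.csv"
    overlay_path = outdir / f"{stem}_overlay.png"
    session_path = outdir / f"{stem}_session.json"
    write_measurements_csv(measurements, csv_path)
    render_overlay(image, groups, overlay_path, cfg.overlay_style)
    save_session(_session_state(image_path, cfg), session_path)
    log.info("wrote %s, %s, %s", csv_path, overlay_path, session_path)
    return PipelineResult(
        image_path=str(image_path),
        groups=tuple(groups),
        measurements=tuple(measurements),
        unmatched=tuple(unmatched),
        csv_path=csv_path,
        overlay_path=overlay_path,
        session_path=session_path,
    )


def _session_state(image_path, cfg: PipelineConfig) -> SessionState:
    strokes = preprocess.load_strokes(cfg.stroke_file) if cfg.stroke_file else []
    selections = _load_selections(cfg.selection_file) if cfg.selection_file else None
    return SessionState(
        image_path=str(image_path),
        axon_threshold=cfg.axon_threshold,
        myelin_threshold=cfg.myelin_threshold,
        strokes=tuple(
            {"mode": s.mode, "width": s.width, "target": s.target,
             "vertices": [[x, y] for x, y in s.vertices]}
            for s in strokes
        ),
        selections=selections,
        min_size=cfg.min_size,
        max_size=cfg.max_size,
        min_vertices=cfg.min_vertices,
        microns_per_pixel=cfg.microns_per_pixel,
        g_ratio_mode=cfg.g_ratio_mode,
        exclude_border=cfg.exclude_border,
    )


def config_from_session(state: SessionState, workdir) -> PipelineConfig:
    """Rebuild a runnable config from a saved session (strokes/selections are
    re-materialized as files under ``workdir``)."""
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    stroke_file = None
    if state.strokes:
        stroke_file = workdir / "session_strokes.json"
        with open(stroke_file, "w") as fh:
            json.dump(list(state.strokes), fh)
    selection_file = None
    if state.selections is not None:
        selection_file = workdir / "session_selections.json"
        with open(selection_file, "w") as fh:
            json.dump(state.selections, fh)
    return PipelineConfig(
        axon_threshold=state.axon_threshold,
        myelin_threshold=state.myelin_threshold,
        min_size=state.min_size,
        max_size=state.max_size,
        min_vertices=state.min_vertices,
        stroke_file=str(stroke_file) if stroke_file else None,
        selection_file=str(selection_file) if selection_file else None,
        g_ratio_mode=state.g_ratio_mode,
        microns_per_pixel=state.microns_per_pixel,
        exclude_border=state.exclude_border,
        output_dir=str(workdir),
    )


def run_batch(directory, cfg: PipelineConfig, output_dir=None) -> BatchResult:
    """Quantify every supported image in a directory.

    Each image gets its own output subdirectory; a combined CSV prepends an
    ``image`` column. A failure on one image is logged and does not abort the
    rest. An empty directory is a warning, not an error.
    """
    directory = Path(directory)
    outdir = Path(output_dir if output_dir is not None else cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    images = sorted(p for p in directory.iterdir() if p.suffix.lower() in IMAGE_SUFFIXES)
    if not images:
        log.warning("no supported images (%s) in %s", "/".join(IMAGE_SUFFIXES), directory)
        return BatchResult(results={}, failures={}, combined_csv=None)

    results: dict[str, PipelineResult] = {}
    failures: dict[str, str] = {}
    for img in images:
        try:
            results[img.name] = run_pipeline(img, cfg, outdir / img.stem)
        except Exception as exc:  # one bad image must not sink the batch
            log.error("failed on %s: %s", img.name, exc)
            failures[img.name] = str(exc)

    combined = outdir / "combined_measurements.csv"
    header_written = False
    with open(combined, "w", newline="", encoding="utf-8") as out:
        import csv as _csv

        writer = _csv.writer(out)
        for name, res in results.items():
            with open(res.csv_path, newline="", encoding="utf-8") as fh:
                rows = list(_csv.reader(fh))
            if not header_written:
                writer.writerow(["image"] + rows[0])
                header_written = True
            for row in rows[1:]:
                writer.writerow([name] + row)
        if not header_written:
            from .reporting import measurement_columns

            writer.writerow(["image"] + measurement_columns("px"))
    log.info("batch: %d quantified, %d failed; combined CSV at %s",
             len(results), len(failures), combined)
    return BatchResult(results=results, failures=failures, combined_csv=combined)
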