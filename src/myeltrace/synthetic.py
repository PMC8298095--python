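"""Ground-truthed synthetic micrograph phantoms.

A phantom fiber is a set of concentric disks on a noisy background: a bright
axoplasm disk (radius ``r_axon``), a mid-gray periaxonal annulus out to
``r_inner`` (the adaxonal space that makes axon area smaller than inner-myelin
area), and a dark compact-myelin annulus out to ``r_outer``. Default
intensities (background 160, axoplasm 200, periaxonal 150, myelin 40) are
chosen so a single myelin threshold (midpoint 100) and a single axon threshold
(midpoint 175) each separate their classes, emulating the two-threshold
quantification workflow on real transmission-EM micrographs.

Two pathologies of real sections are modeled because they drive the manual
cut/draw editing steps:

* a **fold** (redundant myelin loop) is rendered as a background-intensity
  pocket enclosed inside the myelin annulus; at the myelin threshold it forms
  a second hole that must be cut open to the exterior before the true inner
  boundary can be measured;
* a **gap** (locally discontinuous sheath) removes a myelin arc, so the
  sheath no longer closes and must be bridged with a draw stroke.

All truth values (areas, diameters, g = r_inner/r_outer) are analytic in the
planted radii, never measured from the rendered image.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np

from .contours import SizeConstraints
from .errors import PhantomLayoutError
from .preprocess import Stroke, save_strokes

__all__ = [
    "FoldSpec",
    "GapSpec",
    "FiberPhantomSpec",
    "FiberTruth",
    "PhantomTruth",
    "Scenario",
    "generate_micrograph",
    "random_fiber_field",
    "scenario_suite",
    "write_scenario",
]

BACKGROUND = 160
AXOPLASM = 200
PERIAXONAL = 150
MYELIN = 40

#: class-midpoint thresholds matching the default intensities
MYELIN_THRESHOLD = 100
AXON_THRESHOLD = 175


@dataclass(frozen=True)
class FoldSpec:
    """A redundant-myelin pocket: a disk of background intensity of radius
    ``radius`` centered mid-annulus at polar angle ``angle_deg``."""

    angle_deg: float = 0.0
    radius: float = 6.0


@dataclass(frozen=True)
class GapSpec:
    """A missing myelin arc from ``start_deg`` spanning ``extent_deg``."""

    start_deg: float = -20.0
    extent_deg: float = 40.0


@dataclass(frozen=True)
class FiberPhantomSpec:
    """Geometry and intensities of one planted fiber; true g = r_inner/r_outer."""

    center: tuple
    r_axon: float
    r_inner: float
    r_outer: float
    axoplasm: int = AXOPLASM
    periaxonal: int = PERIAXONAL
    myelin: int = MYELIN
    fold: Optional[FoldSpec] = None
    gap: Optional[GapSpec] = None
    allow_contact: bool = False

    def __post_init__(self):
        if not 0 < self.r_axon < self.r_inner < self.r_outer:
            raise ValueError(
                f"need 0 < r_axon < r_inner < r_outer, got "
                f"({self.r_axon}, {self.r_inner}, {self.r_outer})"
            )
        if self.fold is not None:
            r_mid = (self.r_inner + self.r_outer) / 2.0
            if not (
                r_mid - self.fold.radius > self.r_inner + 1
                and r_mid + self.fold.radius < self.r_outer - 1
            ):
                raise ValueError("fold pocket does not fit inside the myelin annulus")

    @property
    def g_ratio(self) -> float:
        return self.r_inner / self.r_outer


@dataclass(frozen=True)
class FiberTruth:
    """Analytic ground truth for one planted fiber."""

    center: tuple
    r_axon: float
    r_inner: float
    r_outer: float
    axon_area: float
    inner_area: float
    outer_area: float
    axon_diameter: float
    inner_diameter: float
    outer_diameter: float
    g_ratio: float

    @classmethod
    def from_spec(cls, spec: FiberPhantomSpec) -> "FiberTruth":
        return cls(
            center=tuple(spec.center),
            r_axon=spec.r_axon,
            r_inner=spec.r_inner,
            r_outer=spec.r_outer,
            axon_area=math.pi * spec.r_axon**2,
            inner_area=math.pi * spec.r_inner**2,
            outer_area=math.pi * spec.r_outer**2,
            axon_diameter=2.0 * spec.r_axon,
            inner_diameter=2.0 * spec.r_inner,
            outer_diameter=2.0 * spec.r_outer,
            g_ratio=spec.g_ratio,
        )


@dataclass(frozen=True)
class PhantomTruth:
    """Per-fiber analytic truth for a rendered phantom image."""

    fibers: tuple

    def write_csv(self, path) -> None:
        cols = [
            "center_x", "center_y", "r_axon", "r_inner", "r_outer",
            "axon_area", "inner_area", "outer_area",
            "axon_diameter", "inner_diameter", "outer_diameter", "g_ratio",
        ]
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(cols)
            for f in self.fibers:
                w.writerow([
                    f.center[0], f.center[1], f.r_axon, f.r_inner, f.r_outer,
                    f.axon_area, f.inner_area, f.outer_area,
                    f.axon_diameter, f.inner_diameter, f.outer_diameter, f.g_ratio,
                ])


def _validate_layout(specs) -> None:
    for i in range(len(specs)):
        for j in range(i + 1, len(specs)):
            a, b = specs[i], specs[j]
            dist = math.hypot(a.center[0] - b.center[0], a.center[1] - b.center[1])
            if dist < a.r_outer + b.r_outer and not (a.allow_contact or b.allow_contact):
                raise PhantomLayoutError(
                    f"fibers {i} and {j} overlap (distance {dist:.1f} < "
                    f"{a.r_outer + b.r_outer:.1f}) without allow_contact"
                )


def generate_micrograph(
    specs,
    shape=(256, 256),
    noise_sd: float = 8.0,
    seed: int = 0,
    background: int = BACKGROUND,
):
    """Render a phantom micrograph and its analytic truth.

    Disks are rasterized by pixel-center membership (a pixel belongs to a
    structure when its center lies within the radius). Additive Gaussian noise
    of standard deviation ``noise_sd`` is applied to the whole canvas and
    clipped to [0, 255]; the returned truth is independent of the noise.
    Deterministic for a fixed ``seed``.

    Returns ``(image uint8, PhantomTruth)``.
    """
    _validate_layout(specs)
    h, w = shape
    canvas = np.full((h, w), float(background))
    yy, xx = np.mgrid[0:h, 0:w]
    for spec in specs:
        cx, cy = spec.center
        if not (spec.r_outer <= cx <= w - 1 - spec.r_outer and spec.r_outer <= cy <= h - 1 - spec.r_outer):
            raise PhantomLayoutError(
                f"fiber at {spec.center} with r_outer={spec.r_outer} exceeds the canvas"
            )
        dx, dy = xx - cx, yy - cy
        d2 = dx * dx + dy * dy
        canvas[d2 <= spec.r_outer**2] = spec.myelin
        canvas[d2 <= spec.r_inner**2] = spec.periaxonal
        canvas[d2 <= spec.r_axon**2] = spec.axoplasm
        if spec.gap is not None:
            ang = np.degrees(np.arctan2(dy, dx))
            rel = (ang - spec.gap.start_deg) % 360.0
            wedge = (rel <= spec.gap.extent_deg) & (d2 > spec.r_inner**2) & (d2 <= spec.r_outer**2)
            canvas[wedge] = background
        if spec.fold is not None:
            r_mid = (spec.r_inner + spec.r_outer) / 2.0
            th = math.radians(spec.fold.angle_deg)
            px, py = cx + r_mid * math.cos(th), cy + r_mid * math.sin(th)
            canvas[(xx - px) ** 2 + (yy - py) ** 2 <= spec.fold.radius**2] = background
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        canvas = canvas + rng.normal(0.0, noise_sd, canvas.shape)
    image = np.clip(np.rint(canvas), 0, 255).astype(np.uint8)
    truth = PhantomTruth(fibers=tuple(FiberTruth.from_spec(s) for s in specs))
    return image, truth


def random_fiber_field(
    n: int = 100,
    r_outer_range=(15.0, 60.0),
    g_range=(0.6, 0.9),
    seed: int = 0,
    axon_fraction: float = 0.8,
    margin: float = 6.0,
):
    """Specs for ``n`` isolated fibers on a grid, with randomized geometry.

    Outer radii are uniform in ``r_outer_range`` and true g-ratios uniform in
    ``g_range``; the axon radius is ``axon_fraction`` of the inner radius
    (periaxonal space). Fibers sit on a square grid with cells wide enough
    that no two sheaths touch. Returns ``(specs, shape)``.
    """
    rng = np.random.default_rng(seed)
    cols = int(math.ceil(math.sqrt(n)))
    rows = int(math.ceil(n / cols))
    cell = 2.0 * r_outer_range[1] + 2.0 * margin
    specs = []
    for k in range(n):
        r, c = divmod(k, cols)
        r_outer = float(rng.uniform(*r_outer_range))
        g = float(rng.uniform(*g_range))
        r_inner = g * r_outer
        specs.append(
            FiberPhantomSpec(
                center=(c * cell + cell / 2.0, r * cell + cell / 2.0),
                r_axon=axon_fraction * r_inner,
                r_inner=r_inner,
                r_outer=r_outer,
            )
        )
    shape = (int(rows * cell), int(cols * cell))
    return specs, shape


@dataclass(frozen=True)
class Scenario:
    """A named phantom with its truth, the mask-editing strokes it requires,
    and the thresholds/constraints a quantification run should use."""

    name: str
    image: np.ndarray
    truth: PhantomTruth
    strokes: tuple = ()
    axon_threshold: int = AXON_THRESHOLD
    myelin_threshold: int = MYELIN_THRESHOLD
    constraints: SizeConstraints = field(default_factory=lambda: SizeConstraints(min_size=50.0))


def _arc_points(center, radius, start_deg, end_deg, step_deg=5.0):
    cx, cy = center
    angles = np.arange(start_deg, end_deg + step_deg / 2, step_deg)
    return tuple(
        (cx + radius * math.cos(math.radians(a)), cy + radius * math.sin(math.radians(a)))
        for a in angles
    )


def scenario_suite(seed: int = 0, noise_sd: float = 8.0) -> dict:
    """The standard test scenarios, keyed by name.

    clean_isolated      three well-separated fibers, no editing needed
    touching_pair       two sheaths fused into one blob; one vertical cut
                        stroke through the bridge separates them
    folded_sheath       one fiber with a myelin-fold pocket; one radial cut
                        stroke joins the pocket to the exterior
    discontinuous_sheath one fiber with a missing myelin arc; one draw stroke
                        bridges the gap along the inner boundary
    dense_field         20 isolated fibers
    empty_field         background noise only
    """
    scenarios: dict[str, Scenario] = {}

    specs = [
        FiberPhantomSpec(center=(60, 64), r_axon=9, r_inner=13, r_outer=20),
        FiberPhantomSpec(center=(160, 70), r_axon=14, r_inner=20, r_outer=26),
        FiberPhantomSpec(center=(105, 170), r_axon=20, r_inner=27, r_outer=34),
    ]
    img, truth = generate_micrograph(specs, shape=(224, 224), noise_sd=noise_sd, seed=seed)
    scenarios["clean_isolated"] = Scenario("clean_isolated", img, truth)

    # two fibers, centers 40 px apart with r_outer 24: outer disks overlap so
    # the sheaths fuse, but the inner regions (r_inner 14) stay separate
    pair = [
        FiberPhantomSpec(center=(60, 64), r_axon=10, r_inner=14, r_outer=24, allow_contact=True),
        FiberPhantomSpec(center=(100, 64), r_axon=10, r_inner=14, r_outer=24, allow_contact=True),
    ]
    img, truth = generate_micrograph(pair, shape=(128, 160), noise_sd=noise_sd, seed=seed + 1)
    cut = Stroke(vertices=((80, 24), (80, 104)), mode="cut", width=3)
    scenarios["touching_pair"] = Scenario("touching_pair", img, truth, strokes=(cut,))

    fold_spec = FiberPhantomSpec(
        center=(64, 64), r_axon=12, r_inner=18, r_outer=40, fold=FoldSpec(angle_deg=0.0, radius=6.0)
    )
    img, truth = generate_micrograph([fold_spec], shape=(128, 128), noise_sd=noise_sd, seed=seed + 2)
    r_mid = (fold_spec.r_inner + fold_spec.r_outer) / 2.0
    cut = Stroke(vertices=((64 + r_mid, 64), (64 + fold_spec.r_outer + 5, 64)), mode="cut", width=3)
    scenarios["folded_sheath"] = Scenario("folded_sheath", img, truth, strokes=(cut,))

    gap_spec = FiberPhantomSpec(
        center=(64, 64), r_axon=10, r_inner=14, r_outer=22, gap=GapSpec(start_deg=-20, extent_deg=40)
    )
    img, truth = generate_micrograph([gap_spec], shape=(128, 128), noise_sd=noise_sd, seed=seed + 3)
    draw = Stroke(
        vertices=_arc_points((64, 64), gap_spec.r_inner + 2.0, -26, 26), mode="draw", width=4
    )
    scenarios["discontinuous_sheath"] = Scenario("discontinuous_sheath", img, truth, strokes=(draw,))

    specs, shape = random_fiber_field(
        n=20, r_outer_range=(12.0, 22.0), g_range=(0.65, 0.85), seed=seed + 4
    )
    img, truth = generate_micrograph(specs, shape=shape, noise_sd=noise_sd, seed=seed + 4)
    scenarios["dense_field"] = Scenario("dense_field", img, truth)

    img, truth = generate_micrograph([], shape=(128, 128), noise_sd=noise_sd, seed=seed + 5)
    scenarios["empty_field"] = Scenario("empty_field", img, truth)
    return scenarios


def write_scenario(scenario: Scenario, outdir) -> dict:
    """Persist a scenario as phantom.png + truth.csv + strokes.json.

    Returns the paths, ready to feed to the command-line pipeline.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    img_path = outdir / f"{scenario.name}.png"
    truth_path = outdir / f"{scenario.name}_truth.csv"
    strokes_path = outdir / f"{scenario.name}_strokes.json"
    iio.imwrite(img_path, scenario.image)
    scenario.truth.write_csv(truth_path)
    save_strokes(scenario.strokes, strokes_path)
    return {"image": img_path, "truth": truth_path, "strokes": strokes_path}
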