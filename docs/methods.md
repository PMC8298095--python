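# Methods

This note documents the models, conventions and numerical choices behind
`myeltrace`, and what the synthetic validation does and does not establish.

## Segmentation model

The tool assumes transverse-section EM contrast: compact myelin is the
darkest structure, axoplasm the brightest, with background and periaxonal
space in between. Segmentation is a per-class global threshold on the
smoothed grayscale image; there is no learned model. Consequences:

* a single threshold per feature class must separate that class across the
  field of view — uneven staining or illumination must be handled upstream;
* the same smoothed image is thresholded twice (an axon pass and a myelin
  pass), reproducing the interactive two-threshold workflow headlessly.

**Grayscale.** RGB input is collapsed with integer BT.601 weighting
`(299·R + 587·G + 114·B) // 1000`. Integer arithmetic makes uniform gray a
fixed point and matches common converters' truncation.

**Bilateral filter.** Circular window of diameter 9 px; spatial Gaussian
σ = 75 px and range Gaussian σ = 75 gray levels; replicate-edge padding;
output rounded to uint8. With both sigmas at 75, the range kernel weight
across a typical myelin/background step (~120 gray levels) is ≈ 0.28, so
edges blur mildly but symmetrically: when the threshold sits near the edge
midpoint the 50%-crossing does not move (verified against a direct
double-loop evaluation of the defining formula). Output is a convex
combination of inputs, so constants are fixed points and the range bound
holds exactly.

**Threshold convention.** `p ≤ t → 0` (black/feature), `p > t → 255`. The
equal case goes to black so `t = 255` is the all-black extreme and the white
region is monotonically non-increasing in `t`.

**Strokes.** Cut strokes rasterize their polyline white (background), draw
strokes black (feature); width w paints the Bresenham path dilated by a
disk of radius `w//2` (default width 3 px — enough to sever any connected
path). Strokes apply after thresholding, in list order; the smoothed image
is not recomputed, matching the stated order of operations.

## Contour extraction

Boundaries between black and white are traced at the 0.5 iso-level between
pixel centers (marching squares), so vertices sit on half-integer
coordinates and the polygon area of a filled region tracks its pixel count
to well under 1% for radii ≥ 10 px. The raw staircase chain is simplified
by Douglas–Peucker with a 0.45 px tolerance and then collinear-compressed.
The simplification budget was set below half a pixel so that simplified
boundaries stay within the digitization uncertainty of the originals; it
also removes the classic digitization bias that would otherwise inflate
perimeters of curved boundaries by 7–10%, and it lets simple shapes
compress to their natural vertex count (an axis-aligned rectangle → 4
vertices, a single-pixel speck → a 4-vertex diamond, which the default
5-vertex filter removes).

Connectivity: feature (black) regions are 4-connected, background
8-connected. The full nesting tree is built by assigning each contour the
smallest-area contour that contains one of its interior points; marching-
squares contours never cross, so a single interior point decides
containment. Contours clipped by the image edge are flagged
`touches_border`, not dropped — partial fibers are scientifically invalid
for g-ratio, so the pipeline excludes them by default, but exclusion is a
documented option rather than silent data loss. Boundary geometry is
invariant under black/white inversion except at saddle (2×2 checkerboard)
configurations, where the connectivity convention resolves ties differently
per side.

## Grouping

`nests_within(inner, outer)` tests one representative interior point of the
inner polygon against the outer polygon plus a strict area inequality —
sufficient for the non-crossing contours one mask can produce. A `strict`
mode adds full polygon containment for hand-supplied geometry. Matching is
"smallest containing parent": each inner boundary to the smallest outer it
nests in, each axon to the smallest matched inner. Two inners claiming one
outer (e.g. double myelination, or an unresolved myelin fold) is an
ambiguity: the library raises by default; the pipeline runs with an
explicit keep-first-selected policy so a batch degrades to a merged fiber
with logged warnings instead of aborting. Axonless inner/outer pairs are
valid fibers (the axon contour only adds the caliber axis); two axons in
one inner keeps the first and reports the rest unmatched.

## Measurement

Shoelace area and closed Euclidean perimeter on the boundary polygon;
equivalent diameter `2·sqrt(A/π)`. The g-ratio defaults to the diameter
convention `sqrt(A_inner/A_outer)`, which equals the inner/outer equivalent-
diameter ratio; the raw area ratio is available as `g_ratio_mode: area` for
exact replication of outputs that report the un-rooted quantity. Axon area
is always measured from the axon's own contour, never inferred from the
inner myelin boundary, because the periaxonal space makes the two differ.
Units are pixels unless an explicit `microns_per_pixel` calibration is
given (linear quantities scale by it, areas by its square; the g-ratio is
dimensionless).

## Synthetic phantoms

The generator renders what the thresholding model assumes: bright axoplasm
disks (intensity 200), a periaxonal annulus (150), a dark compact-myelin
annulus (40) on a 160 background, with additive Gaussian noise (default
sd 8) clipped to [0, 255]. The intensity defaults put the class midpoints at
100 (myelin) and 175 (axon), which the pipeline uses as default thresholds.
Disks are rasterized by pixel-center membership; all truth values are
analytic in the planted radii (true g = r_inner/r_outer) and independent of
the noise.

Two editing pathologies are modeled. A *fold* is a background-intensity
pocket enclosed in the myelin annulus: before editing it is a second hole
(an ambiguous inner candidate); the suggested radial cut joins it to the
exterior, after which the one remaining hole is the true inner boundary.
A *gap* removes a myelin arc so the sheath never closes; the suggested draw
stroke bridges it along the inner radius. The touching-pair scenario fuses
two sheaths (outer circles overlap, inner regions separate); one vertical
cut through the contact bridge restores two fibers.

What the phantoms do **not** emulate: EM texture (grain, knife marks,
staining gradients), irregular fiber cross-sections, mitochondria and inner-
tongue structure inside axons, and partial-volume edge profiles. Passing
the synthetic suite therefore demonstrates the correctness of the
segmentation-to-measurement chain under the tool's contrast assumptions,
not robustness to acquisition artifacts; thresholds on real data remain a
user decision per image set.

## Validation problem sizes and tolerances

The acceptance script and test suite use: 100 random fibers
(r_outer ∈ [15, 60] px, true g ∈ [0.6, 0.9], noise sd 8) for parameter
recovery, asserting mean |Δg| < 0.02 and |bias| < 0.01 — measured values are
an order of magnitude inside those bounds; 200 random star polygons vs a
10× supersampled rasterization oracle (2%); 10⁴ point/polygon pairs vs a
signed-angle winding oracle; 100 polygon pairs vs a rasterized containment
oracle; a 3% band on the fold-exclusion inner area (the cut notch costs
~1%). These sizes keep the full suite under a minute of numeric work while
estimating means to a precision far tighter than the asserted bounds.

## Known limitations

* Thresholds are global per image; no adaptive or per-fiber thresholding.
* The `< 5 vertices` filter operates on simplified chains; very small
  features (area ≲ 10 px²) may compress below the limit and vanish — use
  `min_size` rather than vertex count to control retention.
* Marching-squares tracing yields sub-pixel polygons, not the pixel-indexed
  chains of classical contour extractors; absolute areas can differ from
  such tools by up to ~1 px · perimeter in the worst case, though the
  g-ratio, a ratio of like-biased areas, is insensitive to this.
* Auto-selection trusts nesting parity; debris inside an axon bright enough
  to threshold dark would be offered as a (spurious) inner candidate and
  should be filtered by size or excluded via an explicit selection file.
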