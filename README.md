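# myeltrace

Headless quantification of myelinated-axon morphometry — in particular the
**g-ratio** — from transverse-section electron micrographs.

Myelin thickness relative to axon caliber is a key readout in studies of
developmental myelination, hypomyelinating disease models and remyelination
after injury. In an EM cross-section a myelinated fiber is three nested
closed curves: the axon membrane, the inner (adaxonal) myelin boundary and
the outer (abaxonal) myelin boundary, with the periaxonal space between axon
and inner myelin. `myeltrace` segments these boundaries by intensity
thresholding, assembles them into fibers by geometric nesting, and reports
per-fiber areas, perimeters, equivalent diameters and the g-ratio

    g = d / D = sqrt(A_inner / A_outer)

where `d` and `D` are the diameters of the circles with the measured inner-
and outer-myelin areas (`d = 2·sqrt(A/π)`). Healthy fibers sit around
g ≈ 0.6–0.8; higher values at a given axon diameter indicate thinner myelin.
A raw area-ratio mode (`g = A_inner/A_outer`) is available for replicating
outputs that report the un-rooted ratio.

The processing chain mirrors the established semi-automated workflow:

1. grayscale conversion (BT.601 weights) and edge-preserving bilateral
   smoothing (circular window d = 9 px, σ_color = σ_space = 75);
2. binary thresholding at a user-chosen level per feature class
   (intensity ≤ t → black/feature, > t → white/background);
3. optional user strokes applied to the mask: white **cut** polylines sever
   touching sheaths or open myelin folds to the exterior, black **draw**
   polylines bridge locally discontinuous sheaths;
4. sub-pixel boundary tracing between black and white with full nesting
   hierarchy, vertex-chain compression and a < 5-vertex speck filter plus
   user area constraints (Min/Max Size);
5. nesting-based grouping (each inner boundary to the smallest containing
   outer, each axon to the smallest containing inner);
6. export: an RFC-4180 CSV in axon-selection order, a numbered blue overlay
   PNG, and a JSON session file that replays to a bit-identical CSV.

Because clicking in a GUI is not available headlessly, selections are either
explicit (a JSON file of contour ids) or automatic (every filtered contour of
the right nesting parity). A synthetic phantom generator provides micrographs
with analytic ground truth — including touching sheaths, myelin folds and
discontinuous sheaths — so the whole pipeline is testable without EM data.

## Worked example

```bash
python examples/quantify_phantom.py
```

generates three phantom fibers of known geometry, quantifies them, and
prints:

```
fiber  axon d (px)  inner d (px)  outer d (px)       g  true g
    1        17.67         25.96         40.19   0.646   0.650
    2        27.90         40.15         51.99   0.772   0.769
    3        40.13         54.09         67.88   0.797   0.794
```

Each row is one fiber: the equivalent diameters of the axon, inner-myelin
and outer-myelin boundaries, the measured g-ratio, and the planted truth —
measured g agrees with truth to a few thousandths. The other examples show
cut-stroke editing of fused sheaths (`separate_touching_sheaths.py`) and
manual tracing plus myelinated-fraction counting
(`manual_trace_and_count.py`).

The same run from the shell:

```bash
myeltrace synth clean_isolated -o phantoms
myeltrace run phantoms/clean_isolated.png --myelin-threshold 100 \
    --axon-threshold 175 -o results
```

which writes `clean_isolated_measurements.csv` (columns: `selection_index`,
then area/perimeter/diameter for axon, inner and outer in pixel or micron
units, then `g_ratio`), a numbered overlay PNG, and a reloadable session
JSON. `myeltrace batch DIR` processes a directory and adds a combined CSV
with an `image` column; `myeltrace count` converts a manual
myelinated/unmyelinated tally into a percentage.

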