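"""Manual tracing and myelinated-axon counting.

Some features (collapsed sheaths, oblique cuts) defeat threshold-based
contouring; for those the library measures a hand-traced polygon with the
same area/perimeter/diameter contract as the automatic path. The counting
helper turns a manual myelinated/unmyelinated tally into a percentage.
"""

import math

from myeltrace import (
    MyelinationCount,
    PixelScale,
    measure_manual_polygon,
    percent_myelinated,
)

# a hand-traced 72-point outline of a roughly circular axon, radius ~11 px
points = [
    (50 + 11.2 * math.cos(a), 50 + 10.8 * math.sin(a))
    for a in [2 * math.pi * k / 72 for k in range(72)]
]

area_px, perim_px, diam_px = measure_manual_polygon(points)
print(f"traced axon (pixels):  area {area_px:7.1f} px^2, "
      f"perimeter {perim_px:6.1f} px, equivalent diameter {diam_px:5.2f} px")

scale = PixelScale(microns_per_pixel=0.012)
area_um, perim_um, diam_um = measure_manual_polygon(points, scale)
print(f"at 0.012 um/px:        area {area_um:7.4f} um^2, "
      f"perimeter {perim_um:6.3f} um, equivalent diameter {diam_um:5.3f} um")

count = MyelinationCount(n_myelinated=141, n_unmyelinated=33)
print(f"\nmyelinated fraction:   {percent_myelinated(count):.1f}% "
      f"({count.n_myelinated} of {count.n_myelinated + count.n_unmyelinated} axons)")
print("The equivalent diameter is the diameter of the circle with the traced")
print("area, the standard caliber measure for irregular cross-sections.")
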