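"""Quantify a synthetic micrograph end to end and print per-fiber g-ratios.

Generates three well-separated phantom fibers with known geometry, runs the
full threshold -> contour -> grouping -> measurement pipeline, and compares
the measured g-ratio of each fiber with the planted truth.
"""

import tempfile
from pathlib import Path

from myeltrace import PipelineConfig, run_pipeline, scenario_suite
from myeltrace.synthetic import write_scenario

scenario = scenario_suite(seed=0)["clean_isolated"]
workdir = Path(tempfile.mkdtemp())
paths = write_scenario(scenario, workdir)

result = run_pipeline(paths["image"], PipelineConfig(output_dir=workdir / "out"))

print(f"{'fiber':>5} {'axon d (px)':>12} {'inner d (px)':>13} "
      f"{'outer d (px)':>13} {'g':>7} {'true g':>7}")
truth = sorted(scenario.truth.fibers, key=lambda f: f.outer_area)
for m, t in zip(sorted(result.measurements, key=lambda m: m.outer_area), truth):
    print(f"{m.selection_index:>5} {m.axon_diameter:>12.2f} {m.inner_diameter:>13.2f} "
          f"{m.outer_diameter:>13.2f} {m.g_ratio:>7.3f} {t.g_ratio:>7.3f}")

print(f"\nCSV written to {result.csv_path}")
print(f"Numbered overlay written to {result.overlay_path}")
print("Each g is the equivalent inner-myelin diameter over the outer one;")
print("values near the planted truth confirm the segmentation is accurate.")
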