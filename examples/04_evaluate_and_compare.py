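"""Score mapping approaches with NAD and Dice, and watch the fused
mapping converge as the cohort grows.

Runs at reduced scale (coarser mesh, fewer seeds) so it finishes in
about a minute; the acceptance script runs the full study conditions.
"""

import numpy as np

from volsurf.experiments import convergence, method_ordering

res = method_ordering(seed=5, n_subjects=8)
print("mean NAD (lower is better) / mean Dice (higher is better):")
for name in ("rf", "affine", "single"):
    print(f"  {name:7s}  NAD {np.nanmean(res.nad_values[name]):.4f}   "
          f"Dice {np.nanmean(res.dice_values[name]):.4f}")
row = res.nad_tests[(res.nad_tests.a == "rf") & (res.nad_tests.b == "affine")].iloc[0]
print(f"fusion vs affine on NAD: t = {row.t:.2f}, p = {row.p:.2e}, "
      f"significant after BH-FDR: {bool(row.significant)}")

table, summary = convergence(
    base_seed=5, sizes=(4, 8, 16), n_seeds=3, subdivisions=2,
    grid_shape=(36,) * 3, r_in=10, r_out=14, n_parcels=8,
)
curve = summary["mean_vertex_error_mm"]["curve"]
print("\nmean vertex mapping error vs cohort size (3 seeds):")
for size, value in curve.items():
    print(f"  N = {size:2d}: {value:.4f} mm")
print("non-increasing:", summary["mean_vertex_error_mm"]["non_increasing"])
# averaging more subjects cancels more of the zero-mean per-subject
# registration jitter, so the curve falls roughly like 1/sqrt(N)
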