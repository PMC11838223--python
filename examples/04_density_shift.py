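"""Permutation test for a shift in nearest-leukemia distances between
timepoints, with the design's own positive control.

For each query cell the distance to its nearest leukemia cell is computed;
kernel densities of these distances at two timepoints are differenced and
compared against 100 cell-label permutations.  The positive control plants
the closest cell to every leukemia cell as the query type at timepoint B
(and the furthest at A), so the query type must crowd towards leukemia at B.
"""

import pandas as pd

from nicheshift import SyntheticTissueConfig, density_shift_test, generate_tissue, planted_shift_simulation

cfg = SyntheticTissueConfig(
    n_patients=1, timepoints=("A", "B"), fovs_per_sample=5, n_cells_per_fov=700,
    fov_width_um=560, fov_height_um=370, leukemia_focus_sigma_um=50.0, seed=8,
)
cells = generate_tissue(cfg).cells

null_res = density_shift_test(cells, "T CD8", j=100, seed=1)
print(f"null tissue: {null_res.flags.mean():.0%} of grid points flagged in this "
      "replicate (whole curves enter and leave the band together, so single "
      "replicates vary; the rate averages ~32% over replicates)")

a = planted_shift_simulation(cells[cells.timepoint == "A"], "furthest", query_type="qT", seed=1)
b = planted_shift_simulation(cells[cells.timepoint == "B"], "closest", query_type="qT", seed=2)
res = density_shift_test(pd.concat([a, b], ignore_index=True), "qT", j=100, seed=1)
near = res.grid < 5
print(f"positive control: {int((near & res.flags).sum())} flagged grid points "
      f"below 5 µm, shift sign there: {'negative' if res.shift[near].mean() < 0 else 'positive'}")
print("a negative shift near 0 µm means the query type sits closer to "
      "leukemia at timepoint B than at baseline — exactly what was planted.")
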