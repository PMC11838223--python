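"""Ring-neighbourhood composition around leukemia cells, tested with a
Poisson mixed model.

Counts of each cell type in annuli 0-5, 5-15, 15-25, 25-35 and 35-45 µm
around every leukemia cell are modelled with a response × timepoint × ring
interaction, a log ring-total offset, and a FOV random intercept.  Here the
counts are simulated directly from the model with a known rate ratio.
"""

from nicheshift import build_design, contrast_rr, fit_poisson_glmm
from nicheshift.glmm import average_over_rings, later_vs_baseline_in_responders
from nicheshift.synthetic import simulate_neighborhood_counts

planted_rr = 2.5
table = simulate_neighborhood_counts(
    n_fovs_per_group=5, index_cells_per_fov=200, rr_b_vs_a_responders=planted_rr, seed=4
)
frame = build_design(table, "query")
fit = fit_poisson_glmm(frame)
print(f"rows: {fit.n_rows}  fixed effects: {len(fit.params)}  "
      f"FOV intercept variance: {fit.re_var:.4f}")

for ring in (0, 2, 4):
    res = contrast_rr(fit, later_vs_baseline_in_responders(fit, ring if ring else None),
                      name=f"ring {ring}")
    print(f"responders, post vs baseline, ring {ring}: "
          f"RR = {res.rate_ratio:.2f} [{res.ci_low:.2f}, {res.ci_high:.2f}]  p = {res.p_raw:.2e}")

pooled = contrast_rr(fit, average_over_rings(later_vs_baseline_in_responders, fit))
print(f"averaged over rings: RR = {pooled.rate_ratio:.2f} (planted {planted_rr})")
print("RR > 1 means the cell type makes up a larger share of leukemia "
      "neighbourhoods after treatment in responders.")
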