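# nicheshift

Spatial niche analysis for single-cell spatial transcriptomics of bone
marrow (CosMx-style data): how the cellular neighbourhood of leukemia cells
changes with immunotherapy, which cell types move towards or away from
leukemia between timepoints, and which ligand–receptor pairs are active
specifically at the leukemia interface.

The package is for computational biologists analysing segmented,
polygon-resolved spatial transcriptomics — per-cell boundary polygons, sparse
gene counts (~100 transcripts/cell), and patient / timepoint / response
metadata — and ships a synthetic-tissue generator with planted ground truth
so the whole stack is testable without access to patient data.

## What it computes

**Edge-to-edge geometry.** Cells are polygons, not points: all distances are
minimum distances between cell boundaries (`min_edge_distance`,
`pairwise_min_distances`), so directly touching neighbours are at distance 0
and centroid distance is always an upper bound. Ring neighbourhoods
0–5, 5–15, 15–25, 25–35, 35–45 µm (half-open bands) around each leukemia
cell summarise neighbourhood composition per cell type.

**Neighbourhood mixed model.** For each cell type *t*, the count
$y_{ir}$ of type-*t* cells in ring *r* around leukemia cell *i* is modelled

$$y_{ir} \sim \mathrm{Poisson}\!\big(N_{ir}\,e^{\eta_{ir}}\big),\qquad
\eta_{ir} = x_{ir}^\top\beta + u_{f(i)},\quad u_f \sim \mathcal N(0,\sigma^2),$$

with $N_{ir}$ the ring's total cell count (log offset), $x_{ir}$ the full
response × timepoint × ring interaction, and a random intercept per field of
view (FOV). The model is fitted by a Laplace approximation (cross-checked
against lme4's `glmer` in the test suite); contrasts such as "responders,
post-treatment vs baseline within ring r" are reported as rate ratios
$\mathrm{RR}=e^{c^\top\beta}$ with t-based tests (containment df) and
Bonferroni adjustment across all models fitted.

**Density-shift permutation test.** Per patient and query type, the
distances $d_i$ from each query cell to its nearest leukemia cell (pooled
over a timepoint's FOVs) give kernel densities $\mathrm{pdf}_A$ and
$\mathrm{pdf}_B$; the shift curve $S = \mathrm{pdf}_A - \mathrm{pdf}_B$ is
compared against $J{=}100$ label permutations (per FOV, the same number of
pseudo-query cells drawn from the non-leukemia pool), and a grid point is
flagged where $|S - \bar S_{perm}| > \mathrm{SD}_{perm}$.

**Proximity-stratified ligand–receptor analysis.** Cells are split by
nearest-leukemia distance into close (≤ 5 µm) and far (≥ 30 µm) groups;
anchor genes highly expressed by leukemia (per-FOV median > mean + 2 SD of
the other types' medians) select pairs from a CellTalkDB-style table, and
the partner gene is tested close vs far per cell type with Mann–Whitney U
using per-FOV pseudo-bulk means as replicates (BH-adjusted).

**Segmentation utilities.** Merging nuclear and membrane instance masks
into one mask per cell (membrane footprints where stained, expanded nuclei
where not) and scoring any predicted segmentation with
$F_1 = TP / (TP + (FP+FN)/2)$ at an IOU threshold of 0.7.

**Reference-profile cell typing.** Two-round likelihood-based typing:
reference cells expressing markers of exactly one type define per-type mean
profiles; cells are assigned by a depth-scaled Poisson posterior with
additive negative-probe background; T/B cells are refined into subtypes in
a second round.

## Worked example

```bash
python examples/03_neighborhood_enrichment_glmm.py
```

simulates neighbourhood counts with a planted rate ratio of 2.5 for
responders after treatment and fits the mixed model:

```
rows: 20000  fixed effects: 20  FOV intercept variance: 0.0818
responders, post vs baseline, ring 0: RR = 2.64 [1.73, 4.02]  p = 7.21e-04
responders, post vs baseline, ring 2: RR = 2.68 [1.76, 4.09]  p = 6.50e-04
responders, post vs baseline, ring 4: RR = 2.75 [1.80, 4.19]  p = 5.59e-04
averaged over rings: RR = 2.68 (planted 2.5)
```

An RR of 2.68 means the query cell type makes up about 2.7× the share of
leukemia neighbourhoods after treatment (in responders) that it did at
baseline; the planted value 2.5 lies inside the confidence interval. The
other example scripts (`examples/01`–`06`) walk through tissue simulation,
mask merging and scoring, the density-shift test with its built-in positive
control, the ligand–receptor analysis with a planted TWEAK/TWEAKR signal,
and two-round cell typing.

A thin CLI mirrors the pipeline stages
(`nicheshift simulate | merge-masks | seg-eval | cell-type | niche-glmm |
density-shift | lr-analysis | run`); `nicheshift run --config run.yaml`
drives QC → typing → distances → all three analyses and writes a manifest.

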