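# Methods

This note documents the models and procedures the package implements, the
choices made where the design was open, and what the synthetic data does and
does not emulate.

## Geometry

All coordinates are µm, FOV-local. Raster inputs convert at 0.18 µm/pixel.
Cell–cell distance is the minimum Euclidean distance between boundary
polygons (shapely), 0 when boundaries touch or overlap; it never exceeds
the centroid distance, and in a confluent monolayer the number of
directly touching neighbours (distance ≤ a 1e-6 µm tolerance) is a
meaningful statistic, with a mode around 3–6 in packed tissue.

Distances are computed within a single FOV only; neighbourhoods of cells
near an FOV border are truncated. This is a property of the measurement, not
a bug: FOVs are the replicate unit, and analyses either condition on
neighbourhood size (the offset in the mixed model) or compare like with
like (permutations are drawn within FOV).

Ring neighbourhoods default to half-open bands [0,5), [5,15), [15,25),
[25,35), [35,45) µm around the index cell's membrane. Half-open intervals
make the bands a partition; a distance of exactly 5 µm falls in the second
band. The innermost band contains touching cells (distance 0); a caller who
wants "touching" as its own group can pass custom boundaries via `RingSpec`.

Quality control removes cells with fewer than 20 assigned transcripts, then
whole FOVs with fewer than 300 surviving cells; both stages are logged and
the boundary behaviour (19 vs 20, 299 vs 300) is exact.

## Neighbourhood mixed model

One Poisson model per cell type: the response is the count of that type in
each (index cell, ring); the fixed effects are the full three-way
interaction of patient response (reference: nonresponder), timepoint
(reference: earliest) and ring (reference: innermost) in treatment coding;
`log(ring total)` is an offset; each FOV has a Gaussian random intercept.
Analyses comparing two timepoints restrict the frame to that pair.

Fitting is by Laplace approximation: for a candidate variance σ², the fixed
effects and FOV intercepts are jointly maximised by Newton iterations on
the penalised Poisson log-likelihood (with step halving); σ² itself is
optimised by a bounded 1-D search (log scale, xatol 1e-4) on the Laplace
objective. Start values come from an unpenalised Poisson GLM. Fixed-effect
covariance is the β block of the inverse joint Hessian — the conditional
(Wald) covariance mixed-model software conventionally reports. The test
suite cross-checks coefficients and the variance component against
lme4::glmer on the same design (agreement to ~1e-3).

Contrasts are linear combinations of coefficients. Two builders cover the
reported comparisons: "later vs baseline timepoint within responders" and
"responder vs nonresponder at baseline", each per ring or averaged over
rings. p-values use a t reference with **containment degrees of freedom**:
the contrast is re-expressed as weights on (response × timepoint) cell
means, and df = (number of FOVs in the cells the contrast touches) − (number
of such cells). With few FOVs the normal reference is anti-conservative
(null z-scores have the dispersion of a t with a handful of df); the
containment rule restores family-wise error control under Bonferroni
without affecting large-FOV analyses, where it converges to the normal.
Bonferroni multiplicity defaults to the number of contrasts emitted across
all models fitted (configurable), with 0.05 two-sided significance.

Known limitation (inherited from the design): overlapping neighbourhoods of
nearby index cells are not modelled as dependent; rows are treated as
conditionally independent given the FOV intercept.

## Density-shift test

For one patient and query type, each query cell contributes the edge
distance to its nearest leukemia cell in its FOV; a patient-timepoint's
FOVs pool their values as sample replicates. Densities are Gaussian KDEs
with Silverman's rule-of-thumb bandwidth on a shared 512-point grid over
[0, 45] µm, truncated at 0 (no boundary reflection; a zero-spread sample
falls back to a narrow Gaussian bump). The shift curve is the difference of
the two timepoints' densities.

The null is built by J = 100 permutations: per FOV and timepoint, as many
pseudo-query cells as there are real ones are drawn without replacement
from the FOV's non-leukemia cells, and the shift is recomputed exactly as
observed. Both timepoints are permuted in each iteration. A grid point is
flagged when the observed shift leaves the ±1 SD band of the permuted
shifts. One SD is deliberately lenient — under the null ~32% of grid points
flag, and because KDE curves are smooth the flags of one replicate are
strongly correlated along the grid; single replicates therefore show flag
rates anywhere from 0% to ~60%, while the average over replicates is stable
in [0.15, 0.50]. Interpretation should rest on contiguous flagged regions
with a consistent sign, as in the positive control: planting the cell
closest to each leukemia cell as the query type at one timepoint (and the
furthest at the other) produces a correctly signed flagged region below
5 µm in ≥ 95% of replicates at 5 FOVs and ~100 planted query cells per FOV.
The figure-style normalisation of the shift by the per-distance median of
the permuted curves is available as a display transform only; the
significance rule never uses it.

## Ligand–receptor analysis

Non-leukemia cells are split by nearest-leukemia distance: close ≤ 5 µm,
far ≥ 30 µm, both thresholds inclusive; the band in between is excluded.
Expression is aggregated as per-FOV pseudo-bulk means of raw counts (no
normalisation; per-cell depth normalisation is available as an option).
Anchor genes — the ligand or receptor side carried by leukemia — must have
per-FOV leukemia median expression above the mean of the other cell types'
medians plus 2 of their sample standard deviations (SD over the per-type
medians, one-sided, ddof 1; at least 3 other types required) in at least
50% of the sample's FOVs (persistence; configurable). For each surviving
pair, the partner gene is compared close vs far per cell type with a
two-sided Mann–Whitney U over per-FOV means (exact for small tie-free
samples, normal approximation with tie correction otherwise; at least 2
FOVs per group). Adjustment is Benjamini–Hochberg within each sample and
direction (Bonferroni reserved for the neighbourhood models; the method is
a switch). Both raw and adjusted p-values are reported.

## Mask merging and scoring

Merging assigns each nucleus to the membrane label covering > 50% of its
pixels; each membrane footprint then becomes one cell (several nuclei in
one membrane are absorbed into it and logged). Nuclei without a majority
membrane are expanded by a Euclidean radius (default 3 µm ≈ lymphocyte
cytoplasm width; the true biological value is unknowable from the masks, so
it is a parameter) on unclaimed pixels only; colliding expansions split at
equidistance. Membranes without nuclei are retained. Output labels are
renumbered 1..n and no pixel belongs to two cells.

Scoring matches predicted to truth labels greedily by descending IOU (ties
by lower label id), one-to-one; pairs at IOU ≥ 0.7 are true positives, and
F1 = TP / (TP + (FP+FN)/2). Matching by counts is symmetric in
pred/truth, and F1 is non-increasing in the IOU threshold.

## Cell typing

Typing runs per sample (patient-timepoint) to insulate annotation from
between-sample variation. Reference cells express markers of **exactly one
type** — interpreted as "markers of only one type's set are nonzero", since
types carry multi-gene marker sets. Per-type profiles are the mean
expression of reference cells over the whole panel. Assignment maximises an
independent-Poisson posterior: the candidate profile is scaled so its total
matches the cell's total count, the dataset-mean negative-probe count is
added per gene as nonspecific background (an additive background is this
package's documented choice), and the prior is uniform (configurable).
Round 2 reruns the identical machinery on round-1 T/B cells with
lymphocyte subtype markers; non-lymphocytes are never relabelled. Leukemia
cells are exempt from transcript typing — in the data this package
emulates they are identified from morphology and CD34 protein, and the
synthetic generator carries their labels directly. Cells larger than
648 µm² (20,000 pixels at 0.18 µm/px) should be megakaryocytes; the
fraction so typed is a diagnostic.

## Synthetic data

The generator emulates: FOVs of 985 × 657 µm (defaults); confluent
polygonal cells (dart-thrown centres, reflected-Voronoi tessellation
trimmed to a per-cell maximum radius — neighbours genuinely share edges, so
touching statistics are exercised); 13 bone-marrow cell types at fixed
proportions with megakaryocytes placed as large cells; leukemia clustered
into Gaussian foci (blasts cluster in marrow; this also keeps both ≤ 5 µm
and ≥ 30 µm populations present in dense tissue); per-gene Poisson counts
from type profiles built from the marker panel (markers near-specific to
their type, housekeeping genes carrying most depth, ~100 total counts per
cell, matching the sparse imaging-based regime); 19 negative probes at
0.05 counts/probe/cell; and optional per-transcript points uniform inside
each cell. The default of 2,000 cells per FOV is the density at which the
packing and touching statistics are exercised; real bone-marrow FOVs of
this size run denser (~4,000 cells) with smaller cells, and examples and
tests scale FOV size and cell count down together to keep densities
comparable.

Planted structure is exact by construction: proximity enrichment relabels
types with inclusion probabilities proportional to a distance-band
multiplier (systematic sampling), keeping per-FOV type proportions fixed —
so a multiplier m is recovered as the in-band vs out-of-band rate ratio,
isolating the spatial effect from abundance; ligand–receptor signals
multiply one gene's Poisson mean in close cells of one type; mask fixtures
plant splits, merges, misses and spurious cells whose TP/FP/FN ledger at
IOU 0.7 follows by arithmetic (whole-cell jitter ≤ 1 px keeps unaffected
cells above threshold, enforced by a radius precondition).

What the generator does **not** emulate: segmentation errors in the cell
polygons (polygons are exact), spatial expression gradients within a type
beyond the planted signals, doublets, optical artefacts, RBC contamination,
or patient-level biological heterogeneity beyond the FOV random intercept.
Passing tests therefore demonstrate the correctness and calibration of the
algorithms under their stated models, not robustness to segmentation or
staining artefacts in real images.

## Numerical choices

Polygon coordinates are snapped to a 1e-9 µm grid (far below any reported
precision) to keep polygon overlay operations exact. Distance queries use
an STR tree with a 45 µm `dwithin` predicate; pairs are exact to 1e-6 µm.
KDE bandwidth is Silverman's rule; the 512-point grid is shared between
timepoints. The GLMM clips the linear predictor at ±30 to avoid overflow,
regularises Newton systems with 1e-10 on the diagonal, and bounds log σ² in
[−10, 3]. Mann–Whitney switches from exact to corrected-normal p-values
per scipy's standard small-sample rule. Transcript points on a cell
boundary are assigned to the covering polygon with the lowest cell id
(arbitrary but deterministic).

## Problem sizes used in validation

The validation suite and `scripts/acceptance.py` use: 200 random polygon
pairs against a 10⁴-point boundary-sampling oracle; mask fixtures of 22–30
cells; rate-ratio recovery at 20 FOVs × 200 index cells × 5 rings (medians
over 20 replicates, planted RR ∈ {1, 1.5, 2.5}); family-wise error over
14 cell types × 2 contrasts × 60–100 null replicates at 12 FOVs; density
shift at 5 FOVs × 700 cells with J = 100 (8–12 replicates); ligand–receptor
power at 12 FOVs × 900 cells with ≥ 30 close cells of the planted type per
FOV; typing on ~2,000 cells at ~100 counts/cell. These sizes were chosen so
each check is statistically decisive at desk scale.
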