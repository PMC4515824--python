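# Methods

`leukopan` simulates a leukocyte-capture antibody microarray end to end and
implements the measurement chain such an assay needs.  This note documents
the models, the parameters that matter, the numerical choices, and what the
synthetic data can and cannot establish.

## Capture model

**Saturation law.** The bound-cell density on a spot is
`y(x) = a · (1 − exp(−x/x₀))` in the analysed-suspension concentration `x`
(10⁶ cells/ml), with one characteristic concentration `x₀` shared across
spots and per-spot asymptotes `a = d_sat · f`, where `f` is the fraction of
suspension cells expressing the spot's target.  Defaults: `x₀ = 2.4` and
`d_sat = 6400 cells/mm²` (the saturated pan-leukocyte density; values of
7000–8000 are admissible and config-overridable).  The shared `x₀` is the
load-bearing assumption: it makes the ratio of any two spot densities
independent of `x`, so the CD45-normalised density estimates the
percent-positive fraction at any concentration in the working range.
`fit_saturation` recovers `(x₀, aᵢ)` by global least squares
(`scipy.optimize.least_squares`) with standard errors from the Gauss–Newton
covariance; a panel of series that is flat in `x` is rejected as
unidentifiable.

**Packing bound.** Spot capacity uses a square-lattice bound, one cell per
`d × d` site, i.e. `ceil(1/d²)` cells/mm² with `d` in mm.  This choice (not
hexagonal packing) reproduces the printed 6945 and 8265 cells/mm² endpoints
at 12 and 11 µm exactly.  Simulated counts are Poisson at the expected
density, capped at `packing_limit(min diameter) × packing_efficiency`
(default 0.95).

**Specificity.** Each spot has a matched-capture purity — the expected
fraction of captured cells truly expressing the target: 0.97 (CD3), 0.97
(CD4), 0.98 (CD8), 0.93 (CD19) on the validated spots and 0.995 elsewhere;
anti-CD45 is treated as 1.0 since every PBMC expresses it.  The residual
cross-binding is drawn from **small-lymphocyte-morphotype cells not
expressing the target**.  That composition matters: the stained-control
experiments see only CD4⁺/CD19⁺ small lymphocytes among cross-bound cells,
and no granular or lobed-nucleus lymphocytes ever appear on anti-CD19 or
anti-CD4 — a population-proportional residual would contradict both.  On
spots whose target no cell expresses, the density falls to a nonspecific
floor, `cross_binding = 1.5%` of the saturated density, jittered
log-normally between runs (`cross_binding_cv = 0.35`).  Without that
run-to-run spread the reference intervals of unexpressed targets (CD103,
CD25, CD10 in healthy blood) collapse to the counting noise and any patient
sample flags them spuriously.

**Temperature.** Monocytes adhere nonspecifically to antibody-coated spots
above the ~18 °C phagocytosis threshold; the model is a step function —
0 below threshold, `monocyte_nonspecific_density = 140 cells/mm²` above.
The sub-threshold value is set to zero rather than a small constant because
the captured-composition table shows exact zeros for monocytes on the
B-/T-cell spots at cold incubation; the reported bound (≤15 cells/mm² at
4 °C) is an upper limit, which zero satisfies.

## Synthetic cohorts

Five healthy cell classes (CD4 T, CD8 T, NK, B, monocyte) carry Bernoulli
marker-expression probabilities and exclusive morphotype mixtures over
{small, large, lobed, granular, granular-lobed, monocyte, binuclear}.
Because capture is class-independent at defaults, the captured composition
on a spot depends only on the within-class mixtures; these are
back-calculated from the published captured-composition table with the
spot purity folded in (e.g. the CD8 T class carries 22.3% granular +
1.4% granular-lobed so that the anti-CD8 spot shows 23% granular after 98%
purity and small-lymphocyte cross-binding).  Class *fractions* are
therefore free parameters and are set to flow-cytometry reference values
(CD4 T 0.47, CD8 T 0.23, NK 0.05, B 0.12, monocyte 0.13 of PBMC).  The
published table is not perfectly consistent with any single decomposition
(its CD3 row implies a lower granular share than its CD8 row plus a
physiologic CD4:CD8 ratio allows); the anchor rows (CD45, CD8, CD14, CD16,
CD19, CD56) are honoured and the CD3-row granular entry is reproduced only
approximately.

Donor-to-donor variation is an independent truncated normal per class
fraction, renormalised to the simplex.  Renormalisation damps the realised
spread, so the component SDs (0.125, 0.075, 0.025, 0.050, 0.045) are chosen
to make the *realised* inter-donor spread match reference intervals:
CD3 ≈ 7, CD4 ≈ 7, CD8 ≈ 7, CD19 ≈ 5 percentage points.

Leukemic profiles add one clone class at a given PBMC fraction: CLL
(CD19⁺CD5⁺CD23⁺, CD20/CD22 expressed but with capture strength 0.25,
modelling the reduced antigen density that weakens capture), HCL
(CD19⁺CD20⁺CD22⁺CD25⁺CD11c⁺CD103⁺, TRAP⁺, hairy morphology), SMZL, MCL,
FL.  Flow cytometry is simulated as a binomial draw of each marker
frequency out of `n_events` CD45-gated events — unbiased by construction,
which is exactly the property the concordance analysis tests.

## Image synthesis

Rendered cells are flattened discs (cytoplasm channel 0.55) containing
analytic nucleus contours (nucleus channel 0.9) and optional granules
(1 µm discs at 1.0), plus additive Gaussian noise (σ = 0.02).  Contour
families: ellipses (non-lobed), `r(θ) = r₀(1 − amp·Σ gaussian notches)`
with k ≥ 2 for radially segmented nuclei, and a single wide notch for
kidney-shaped monocyte nuclei.  Area and perimeter come from a 2048-gon
discretisation (relative error ≪ 10⁻⁴), so every rendered nucleus has an
exact NCI and exact cleft depths as ground truth.

**Cleft-depth convention.** A cleft is a local minimum of the radial
function about the centroid, its depth measured from the **convex hull**
radius at that angle, normalised by √(A/π).  The hull is the right local
baseline: it is identically zero for any convex contour, so an eccentric
ellipse (whose radial function has two deep minima against its maxima)
scores no clefts, while true notches score their full indentation.  The
generator solves notch amplitudes so the *hull-based* ground-truth depth
hits its target; detector and generator therefore share one definition and
agree within ±0.05.  A corollary: very wide shallow indentations leave the
contour convex, so kidney nuclei need indent widths ≲0.35 rad to register
their 0.25–0.38 depths.

**Placement.** Random sequential adsorption (grid-accelerated, per-cell
radii) below 30% area coverage; above it a rigid jittered hexagonal lattice
(random placement jams near 40% coverage, while saturated spots reach
~70%).  Overlap invariant: centre distance ≥ 0.95 × summed radii.  The
donut mode biases RSA acceptance toward the rim (weight ∝ 0.45 + 1.55 r̂²),
emulating the drying artifact.  RSA itself mildly enriches spot edges at
moderate coverage (less competition near the boundary) — a real property
of the placement model, visible as uniformity ratios up to ~1.3 on single
renders; the uniformity tests therefore average over replicate renders.

**Scales.** Default 0.25 µm/px for morphometry fields, 0.1 µm/px for
dedicated NCI rasters, 0.35 µm/px for counting fields; a render refuses to
run if the smallest nuclear radius falls below 10 px.  Granule size/count
and monocyte geometry are package defaults (granule Ø 1 µm, 4–8 per
granular cell, ≥3 = "granular"; monocyte Ø 15.5–19 µm, nuclear fraction
0.48–0.55), not validated against published morphometry — the source
material does not quantify them.

## Measurement

**Segmentation** is nucleus-seeded: fixed thresholds relative to the known
render levels, connected components with a 12 µm² minimum, then a
watershed from nucleus markers over the cytoplasm foreground.  Nuclei
never touch under the packing geometry, which makes counting robust to
confluent cytoplasm.  Granules are bright blobs (≥3 px) assigned to the
cell under their centroid.  Cells touching the image border are excluded
from morphometry (their areas and cleft geometry are clipped).

**Morphometry.**  Nuclear perimeter and area come from a marching-squares
sub-pixel contour smoothed circularly with σ = 1 px; raw pixel-edge
counting overestimates perimeters by ~10% and would shift every NCI by the
same amount.  Accuracy contracts, verified in tests: perimeter ≤2% error at
contour radius ≥10 px; disk NCI within 1% of 2√π; rasterised pixel area
within 1% of analytic.  The NC ratio is nuclear : (cell − nuclear) area,
the smear-morphology convention (3:1 ↔ nuclear fraction 0.75).

**Classification order**: binuclear → lobed (≥2 clefts ≥0.5) → granular
(≥3 granules) → monocyte (>15 µm, NC < 2:1, kidney indentation in
[0.1, 0.5)) → reactive (15–20 µm, NC 1–2) → small/large by size with the
12–13 µm gap resolved by NC ratio (>3:1 → small).  Plasma and hairy cells
are generator labels only; the classifier maps them to reactive/other, as
no published measurable criteria distinguish them in this geometry.
End-to-end accuracy on rendered fields is ≥95% (typically ≥98.5%), with
residual errors from cells merged at placement boundaries.

**Quantification.**  `normalize` divides by the anti-CD45 density (×100);
values >100% are flagged, not clipped.  Counting noise on tables-only
profiles follows the replicate-field protocol: three multiplicative 5%-SD
field factors averaged, i.e. ≈2.9% SE per spot density.  `mann_whitney`
uses exact permutation enumeration (ties included) for n₁+n₂ ≤ 12 and the
tie-corrected normal approximation with continuity correction beyond;
`scipy.stats.mannwhitneyu` serves as an independent cross-check in tests
only.  Reference intervals are 2.5–97.5 percentiles of a healthy cohort
(warning below 20 donors, error below 3).  Disease signatures score
matched/applicable directional expectations; "variable" entries (CD20/CD22
in CLL) never score; "normal" competes as a candidate scored by the
fraction of unflagged CDs, so a stray flag on a 35-spot panel does not
force a disease call.  Single-patient flagging uses the percentile
intervals; cohort-vs-cohort comparisons use the rank test, mirroring how
the two kinds of claims are made.

## Problem sizes

Acceptance and analysis runs use the study's own scales: 10 replicates of
≥2000 captured cells for specificity, 14 donors × 10⁴ flow events for
concordance, ≥5 donors × ≥500 rendered cells per spot for the cross-tab,
three ~1000-cell fields for counting precision, and 50 lobed / 150
non-lobed nuclei for the NCI medians.  The counting study renders one
contiguous strip and partitions detections into three windows, emulating
three pictures of one spot region (sub-Poisson field-to-field variation,
as placement anti-clusters).

## What the synthetic data does not show

The generator realises the statistical structure the analysis assumes:
Bernoulli marker expression (no antigen-density continuum beyond the CLL
capture-strength scalar), no activation/apoptosis states, stain-free
two-channel imaging with no point-spread function, uneven illumination or
debris, and geometric morphotypes with hard thresholds.  Passing tests
establish that the pipeline recovers known ground truth under these
conditions — they do not establish robustness to real staining variability,
touching nuclei, smeared cytoplasm or atypical morphologies.  Patient-cohort
effect sizes (the magnitudes of disease-wise density shifts) are likewise
not reproducible from first principles; disease recognition is validated at
the level of flag directions and ranking, not magnitudes.
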