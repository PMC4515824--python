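# leukopan

Simulation and analysis pipeline for **leukocyte panning on anti-CD antibody
microarrays** — a "cell-sorted smear" in which peripheral blood mononuclear
cells (PBMC) are captured on printed spots of antibodies against
cluster-of-differentiation (CD) surface antigens, so that cells positive for
CD3, CD19, CD14, … sit in predefined areas where their morphology can be
examined at smear quality.

The package is for quantitative method developers and computational
hematologists: it implements the full measurement chain of such an assay —
capture physics, image-based cell counting, morphometry, immunophenotype
quantification and disease-signature matching — together with a synthetic
blood generator, so every stage is testable against analytic ground truth at
desk scale.

## The quantitative machinery

* **Capture density.** The bound-cell density on a spot saturates in the
  analysed-suspension concentration *x* (10⁶ cells/ml) as
  *y(x) = a·(1 − e^(−x/x₀))* with a single characteristic concentration *x₀*
  shared by all spots and a per-spot asymptote *a = d_sat·f* proportional to
  the fraction *f* of cells expressing the target.  A geometric packing
  limit, one cell per *d*×*d* lattice site (⌈1/d²⌉ ≈ 6945–8265 cells/mm² for
  11–12 µm cells), bounds every spot.
* **Percent-positive estimator.** Because *x₀* is shared, the density
  normalised to the anti-CD45 (pan-leukocyte) control spot,
  100·y_CD/y_CD45, estimates the percent of cells positive for that CD,
  independently of *x* — validated here against simulated flow cytometry
  (binomial sampling of the same cell population).
* **Morphometry.** Cells are segmented nucleus-first; nuclear area *A* and
  perimeter *P* come from a sub-pixel smoothed contour, giving the nuclear
  contour index NCI = *P*/√*A* (2√π ≈ 3.54 for a disk; 4.2–5.0 for radially
  segmented "clover-leaf" nuclei).  Cleft depths are measured against the
  convex hull of the contour, normalised by √(*A*/π).
* **Morphotype rules.** binuclear → lobed (≥2 clefts ≥ 0.5 radius) →
  granular (≥3 granules) → monocyte (>15 µm, NC < 2:1, kidney nucleus) →
  reactive → small/large by diameter and nuclear:cytoplasmic ratio.
* **Diagnosis.** Per-CD reference intervals (2.5–97.5 percentiles of a
  healthy cohort) flag a patient profile; disease signatures (CLL, HCL,
  SMZL, MCL, FL) are ranked by the fraction of matched expectations.

## Worked example

```python
import leukopan as lp

truth = lp.build_disease_profile("HCL", clone_fraction=0.3, seed=7)
cap = lp.simulate_capture(truth, lp.default_panel(), seed=8)
profile = lp.profile_from_capture(cap, seed=9)
print(round(profile.normalized["CD103"], 1), round(profile.normalized["CD3"], 1))
```

prints `32.0 52.8` — the hairy-cell clone (CD103⁺) occupies ~32% of the
normalized profile while the T-cell compartment is diluted to ~53%, the
binding pattern the diagnosis stage recognises as HCL:

```python
ranked = lp.suggest_diagnosis(profile, ranges)   # ranges from a healthy cohort
# ranked[0].disease == "HCL"
```

The numbered scripts under `analysis/` run the full set of studies
(`python analysis/03_flow_concordance.py --seed 1` prints per-CD Pearson
R of 0.90–0.98 and a pooled through-origin slope k = 0.984 for a 14-donor
cohort) and write their tables under `results/`.

## Layout

```
src/leukopan/     library: cohort, capture, geometry, render, segment,
                  morphometry, quantify, signatures, panel, pipeline, cli
analysis/         numbered narrative drivers writing results/
tests/            pytest suite (unit, property and recovery tests)
scripts/          acceptance.py
docs/methods.md   model assumptions, parameters, limitations
```

A `leukopan` console script exposes the pipeline verbs
(`simulate`, `render`, `analyze`, `quantify`, `diagnose`, `all`).
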