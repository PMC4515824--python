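"""Reproducible study designs: the simulated counterparts of the assay's
validation experiments, shared by the analysis scripts and the acceptance
harness.

Each function builds its own inputs from the generator, runs the relevant
pipeline stages, and returns measured summaries.  Problem sizes follow the
study conditions (14-donor concordance cohort, >=2000-cell specificity
replicates, >=500-cell rendered spots, 3 counting fields of ~1000 cells,
50/150-nucleus contour populations).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geometry as G
from .capture import CaptureParams, SaturationParams, simulate_capture
from .cohort import (
    CohortParams,
    DonorTruth,
    _realize_roster,
    build_disease_profile,
    build_healthy_profile,
    simulate_flow,
)
from .morphometry import measure, measure_all
from .panel import default_panel
from .quantify import (
    ConcordanceResult,
    MorphotypeByAntibody,
    crosstab,
    fc_concordance,
    fit_saturation,
    profile_from_capture,
    reference_ranges,
    suggest_diagnosis,
)
from .render import RenderParams, render_field
from .segment import estimate_density, segment_cells

_MOD = 2**31 - 1


def _child(seed: int, k: int) -> int:
    return (seed * 1000 + k) % _MOD


def build_profile_from_fractions(
    fractions: dict[str, float],
    seed: int,
    params: CohortParams | None = None,
) -> DonorTruth:
    """A donor with prescribed (already-normalised) class fractions."""
    params = params if params is not None else CohortParams()
    rng = np.random.default_rng(seed)
    cells = _realize_roster(fractions, params.classes, params.n_cells, rng)
    return DonorTruth(fractions, dict(params.classes), cells,
                      params.suspension_concentration)


# ---------------------------------------------------------------------------
# specificity (stained-positive fraction on matched spots)


def specificity_study(
    seed: int,
    n_replicates: int = 10,
    cds: tuple[str, ...] = ("CD3", "CD4", "CD8", "CD19"),
    min_cells: int = 2000,
) -> pd.DataFrame:
    """Stained-positive percentage on each matched spot over replicates.

    Rosters and spot sizes are scaled so every studied spot captures at
    least ``min_cells`` cells per replicate.
    """
    params = CohortParams(n_cells=45_000)
    panel = default_panel(spot_diameter_mm=2.4)
    rows = []
    for r in range(n_replicates):
        truth = build_healthy_profile(params, seed=_child(seed, r))
        cap = simulate_capture(truth, panel, seed=_child(seed, 100 + r))
        for cd in cds:
            roster = cap.spots[cd].cells
            if len(roster) < min_cells:
                warnings.warn(f"{cd}: only {len(roster)} captured cells", stacklevel=2)
            rows.append(
                {
                    "replicate": r,
                    "cd": cd,
                    "n_captured": len(roster),
                    "stained_positive_pct": 100.0 * roster[cd].mean(),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# flow-cytometry concordance (14-donor cohort)


def concordance_cohort_fractions(rng: np.random.Generator) -> dict[str, float]:
    """One donor's class fractions for the concordance study.

    CD3-positive fraction ~ truncated Normal(60, 8) bounded to [30, 85]%,
    split 2:1 between CD4 and CD8 T cells; B, NK and monocyte fractions
    drawn around reference values and scaled to fill the remainder.
    """
    cd3 = np.clip(rng.normal(60.0, 8.0), 30.0, 85.0) / 100.0
    rest = {
        "B": max(rng.normal(0.12, 0.04), 0.02),
        "NK": max(rng.normal(0.05, 0.015), 0.01),
        "monocyte": max(rng.normal(0.13, 0.04), 0.03),
    }
    scale = (1.0 - cd3) / sum(rest.values())
    out = {"CD4_T": cd3 * 2 / 3, "CD8_T": cd3 / 3}
    out.update({k: v * scale for k, v in rest.items()})
    return out


def flow_concordance_study(
    seed: int,
    n_donors: int = 14,
    n_events: int = 10_000,
    cds: tuple[str, ...] = ("CD3", "CD4", "CD8", "CD19"),
) -> tuple[pd.DataFrame, ConcordanceResult]:
    """Microarray normalized density vs simulated flow for each donor x CD."""
    rng = np.random.default_rng(seed)
    panel = default_panel()
    rows = []
    for i in range(n_donors):
        fr = concordance_cohort_fractions(rng)
        truth = build_profile_from_fractions(fr, seed=_child(seed, i))
        cap = simulate_capture(truth, panel, seed=_child(seed, 200 + i))
        prof = profile_from_capture(cap, seed=_child(seed, 400 + i))
        flow = simulate_flow(truth, n_events, seed=_child(seed, 600 + i), cds=list(cds))
        for cd in cds:
            rows.append(
                {
                    "donor": i,
                    "cd": cd,
                    "microarray_pct": prof.normalized[cd],
                    "flow_pct": flow.percent_positive[cd],
                }
            )
    paired = pd.DataFrame(rows)
    return paired, fc_concordance(paired)


# ---------------------------------------------------------------------------
# replicate-field counting precision


def counting_precision_study(
    seed: int,
    field_area_mm2: float = 0.25,
    n_fields: int = 3,
    cells_per_field: int = 1000,
    pixel_scale_um: float = 0.35,
):
    """Three x200-like fields of one spot region, counted by segmentation.

    A contiguous strip covering the fields is rendered once at the target
    density; detections are partitioned into the field windows, emulating
    three pictures of the same spot.
    """
    side_mm = float(np.sqrt(field_area_mm2))
    strip_w = side_mm * n_fields
    density = cells_per_field / field_area_mm2
    n_total = int(round(density * strip_w * side_mm))
    roster = pd.DataFrame(
        {"morphotype": ["small_lymphocyte"] * n_total, "diameter_um": np.nan}
    )
    img = render_field(roster, strip_w, side_mm,
                       RenderParams(pixel_scale_um=pixel_scale_um), seed=seed)
    seg = segment_cells(img)
    centers = seg.centers_um
    counts = []
    for k in range(n_fields):
        lo, hi = k * side_mm * 1000.0, (k + 1) * side_mm * 1000.0
        counts.append(int(((centers[:, 0] >= lo) & (centers[:, 0] < hi)).sum()))
    return estimate_density(counts, field_area_mm2), counts


# ---------------------------------------------------------------------------
# nuclear contour index recovery


def _measure_rasterized(shape: G.NucleusShape, scale_um: float = 0.1,
                        equivalent_radius_um: float = 4.0) -> float:
    from skimage.draw import polygon as draw_polygon

    s = shape.scaled(np.pi * equivalent_radius_um**2)
    ext = np.abs(s.vertices).max() * 1.2
    n = int(2 * ext / scale_um) + 4
    mask = np.zeros((n, n), dtype=bool)
    rr, cc = draw_polygon((s.vertices[:, 1] + ext) / scale_um,
                          (s.vertices[:, 0] + ext) / scale_um, shape=mask.shape)
    mask[rr, cc] = True
    return measure(mask, [mask], scale_um).nci


def nci_study(
    seed: int,
    n_lobed: int = 50,
    n_nonlobed: int = 150,
    pixel_scale_um: float = 0.1,
) -> dict[str, float]:
    """Measured NCI medians for lobed and non-lobed synthetic populations.

    Analytic target NCIs are drawn from the two-piece uniform families
    (median 4.4 on [4.2, 5.0]; median 3.75 above the disk bound), each
    contour is rasterised and measured with the sub-pixel estimator.
    """
    rng = np.random.default_rng(seed)
    lobed_targets = G.sample_lobed_nci(rng, n_lobed)
    lobed = []
    for t in lobed_targets:
        amp = G.lobed_amp_for_nci(t, k=2, sigma=0.12)
        sh = G.lobed_shape(2, amp, 0.12, phase=rng.uniform(0, 2 * np.pi))
        lobed.append(_measure_rasterized(sh, pixel_scale_um))
    nonlobed_targets = G.sample_nonlobed_nci(rng, n_nonlobed)
    nonlobed = []
    for t in nonlobed_targets:
        q = G.ellipse_ratio_for_nci(t)
        sh = G.ellipse_shape(q, phase=rng.uniform(0, 2 * np.pi))
        nonlobed.append(_measure_rasterized(sh, pixel_scale_um))
    return {
        "lobed_median_nci": float(np.median(lobed)),
        "nonlobed_median_nci": float(np.median(nonlobed)),
        "lobed_analytic_median": float(np.median(lobed_targets)),
        "nonlobed_analytic_median": float(np.median(nonlobed_targets)),
        "lobed_min": float(np.min(lobed)),
        "lobed_max": float(np.max(lobed)),
    }


# ---------------------------------------------------------------------------
# end-to-end cross-tabulation (capture -> render -> segment -> classify)


def crosstab_study(
    seed: int,
    n_donors: int = 5,
    spots: tuple[str, ...] = ("CD14", "CD8", "CD19"),
    min_cells: int = 500,
    pixel_scale_um: float = 0.3,
) -> MorphotypeByAntibody:
    """Morphotype x antibody cross-tab measured through the full image path."""
    params = CohortParams(n_cells=20_000)
    panel = default_panel(spot_diameter_mm=1.2)
    per_donor = []
    for i in range(n_donors):
        truth = build_healthy_profile(params, seed=_child(seed, i))
        cap = simulate_capture(truth, panel, seed=_child(seed, 50 + i))
        frames = []
        for j, spot in enumerate(spots):
            roster = cap.spots[spot].cells
            density = cap.spots[spot].density
            n = min(len(roster), max(min_cells, 0))
            side_mm = float(np.sqrt(n / density))
            sub = roster.sample(n=n, random_state=_child(seed, 500 + 10 * i + j))
            img = render_field(sub, side_mm, side_mm,
                               RenderParams(pixel_scale_um=pixel_scale_um),
                               seed=_child(seed, 700 + 10 * i + j))
            seg = segment_cells(img)
            cells = measure_all(seg)
            cells["antibody"] = spot
            frames.append(cells[["antibody", "morphotype"]])
        per_donor.append(pd.concat(frames, ignore_index=True))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return crosstab(per_donor, min_cells=200)


# ---------------------------------------------------------------------------
# titration replicates


def titration_study(
    seed: int,
    n_replicates: int = 20,
    noise: float = 0.05,
    x0: float = 2.4,
    asymptotes: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Global-fit recovery under multiplicative counting noise."""
    asym = asymptotes if asymptotes is not None else {
        "CD45": 6400.0, "CD3": 3580.0, "CD19": 330.0,
    }
    xs = np.array([0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 10.0])
    rng = np.random.default_rng(seed)
    out = []
    for r in range(n_replicates):
        rows = []
        for spot, a in asym.items():
            y = a * (1 - np.exp(-xs / x0)) * (1 + noise * rng.standard_normal(len(xs)))
            rows.extend({"x": x, "spot": spot, "density": yi} for x, yi in zip(xs, y))
        params, se = fit_saturation(pd.DataFrame(rows))
        out.append({"replicate": r, "x0": params.x0, "se_x0": se["x0"],
                    **{f"a_{s}": v for s, v in params.a.items()}})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# disease recognition and rare-cell sensitivity


@dataclass
class DiseaseRankingResult:
    top: dict[str, str]
    scores: dict[str, float]


def disease_ranking_study(
    seed: int,
    diseases: tuple[tuple[str, float], ...] = (("HCL", 0.3), ("CLL", 0.5), ("SMZL", 0.4)),
    n_reference: int = 30,
) -> DiseaseRankingResult:
    """Are simulated patients top-ranked by their own signatures?"""
    panel = default_panel()
    params = CohortParams(n_cells=12_000)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        profiles = []
        for i in range(n_reference):
            t = build_healthy_profile(params, seed=_child(seed, i))
            c = simulate_capture(t, panel, seed=_child(seed, 300 + i))
            profiles.append(profile_from_capture(c, seed=_child(seed, 600 + i)))
        ranges = reference_ranges(profiles)
    top, scores = {}, {}
    for k, (dz, frac) in enumerate(diseases):
        t = build_disease_profile(dz, frac, seed=_child(seed, 900 + k), params=params)
        c = simulate_capture(t, panel, seed=_child(seed, 950 + k))
        prof = profile_from_capture(c, seed=_child(seed, 980 + k))
        sugg = suggest_diagnosis(prof, ranges)
        top[dz] = sugg[0].disease
        scores[dz] = sugg[0].score
    return DiseaseRankingResult(top, scores)


def rare_cell_study(
    seed: int,
    n_seeds: int = 20,
    hairy_per_ul: float = 50.0,
    total_per_ul: float = 1500.0,
    min_hairy: int = 10,
) -> float:
    """Fraction of seeds where the anti-CD103 spot holds >= ``min_hairy``
    hairy cells, for a leukopenic HCL sample (50 hairy cells/ul blood)."""
    clone_fraction = hairy_per_ul / total_per_ul
    panel = default_panel()
    params = CohortParams(n_cells=8000)
    hits = 0
    for r in range(n_seeds):
        t = build_disease_profile("HCL", clone_fraction, seed=_child(seed, r),
                                  params=params)
        cap = simulate_capture(t, panel, seed=_child(seed, 400 + r))
        roster = cap.spots["CD103"].cells
        n_hairy = int((roster["cell_class"] == "clone_HCL").sum())
        hits += n_hairy >= min_hairy
    return hits / n_seeds
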