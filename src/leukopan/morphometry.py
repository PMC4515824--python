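"""Per-cell morphometry and rule-based morphotype classification.

Measurements reproduce what a hematologist reads off a stained smear:

* cell area and equivalent diameter,
* nuclear area A and perimeter P from a sub-pixel, Gaussian-smoothed
  marching-squares contour (raw pixel-edge counting overestimates P by
  ~10% and would distort the contour index),
* NC ratio = nuclear area : cytoplasmic (cell minus nuclear) area,
* nuclear contour index NCI = P / sqrt(A) (2*sqrt(pi) for a disk),
* cleft depths of the nuclear outline, measured against the convex hull
  and normalised by sqrt(A/pi) (see :mod:`leukopan.geometry`).

Classification applies the smear-morphology rules in a fixed order:
binuclear -> lobed nucleus (>= 2 clefts at least half a radius deep) ->
granular -> monocyte (large, low NC, kidney nucleus) -> reactive ->
small/large by diameter and NC ratio.  Cells between the small (<= 12 um)
and large (13-15 um) bins are assigned by NC ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from skimage.measure import find_contours
from shapely.geometry import Polygon as ShapelyPolygon

from .geometry import contour_cleft_depths, polygon_area, polygon_perimeter
from .segment import SegmentationResult

#: classification thresholds (um / NC-ratio units)
SMALL_MAX_DIAMETER = 12.0
LARGE_MIN_DIAMETER = 13.0
LARGE_MAX_DIAMETER = 15.0
MONOCYTE_MIN_DIAMETER = 15.0
REACTIVE_RANGE = (15.0, 20.0)
SMALL_NC_MIN = 3.0
CLEFT_LOBED_DEPTH = 0.5
KIDNEY_DEPTH_RANGE = (0.1, 0.5)
GRANULAR_MIN_GRANULES = 3


@dataclass
class MorphometryRecord:
    cell_area_um2: float
    equivalent_diameter_um: float
    nuclear_area_um2: float
    nuclear_perimeter_um: float
    nc_ratio: float  # nuclear : cytoplasmic area
    granule_count: int
    cleft_depths: list[float]
    nuclei_count: int
    nci: float


@dataclass
class MorphotypeCall:
    label: str
    rule_trace: list[str] = field(default_factory=list)


def smoothed_contour(mask: np.ndarray, sigma_px: float = 1.0) -> np.ndarray:
    """Sub-pixel closed contour of a binary mask, Gaussian-smoothed.

    Returns (n, 2) vertices in (x, y) pixel coordinates.  The smoothing is
    circular along the vertex sequence so closure is preserved.
    """
    padded = np.pad(mask, 1).astype(float)
    contours = find_contours(padded, 0.5)
    if not contours:
        raise ValueError("empty mask")
    c = max(contours, key=len)
    c = c[:-1] if np.allclose(c[0], c[-1]) else c
    ys = gaussian_filter1d(c[:, 0], sigma_px, mode="wrap")
    xs = gaussian_filter1d(c[:, 1], sigma_px, mode="wrap")
    return np.c_[xs - 1.0, ys - 1.0]  # undo padding offset


def measure(
    cell_mask: np.ndarray,
    nucleus_masks: list[np.ndarray] | np.ndarray,
    pixel_scale_um: float,
    granule_count: int = 0,
) -> MorphometryRecord:
    """Morphometry of one cell from its binary masks.

    Areas come from pixel sums; the nuclear perimeter from the sub-pixel
    smoothed contour (<= 2% error at contour radii >= 10 px).  Raises if
    the nuclei do not fit inside the cell.
    """
    if isinstance(nucleus_masks, np.ndarray) and nucleus_masks.ndim == 2:
        nucleus_masks = [nucleus_masks]
    if not nucleus_masks or not any(m.any() for m in nucleus_masks):
        raise ValueError("empty nucleus mask")
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    s2 = pixel_scale_um**2
    cell_area = float(cell_mask.sum() * s2)
    nuc_area_px = sum(int(m.sum()) for m in nucleus_masks)
    nuclear_area = float(nuc_area_px * s2)
    if nuclear_area > cell_area * 1.02:
        raise ValueError("nucleus mask larger than cell mask")
    cyto = max(cell_area - nuclear_area, 1e-9)

    main = max(nucleus_masks, key=lambda m: m.sum())
    contour_px = smoothed_contour(main)
    contour_um = contour_px * pixel_scale_um
    per = polygon_perimeter(contour_um)
    area_poly = polygon_area(contour_um)
    depths = detect_clefts(contour_um)
    # NCI from the same sub-pixel contour for internal consistency
    nci = per / np.sqrt(area_poly)
    return MorphometryRecord(
        cell_area_um2=cell_area,
        equivalent_diameter_um=float(2.0 * np.sqrt(cell_area / np.pi)),
        nuclear_area_um2=float(area_poly if len(nucleus_masks) == 1 else nuclear_area),
        nuclear_perimeter_um=float(per),
        nc_ratio=float(nuclear_area / cyto),
        granule_count=int(granule_count),
        cleft_depths=depths,
        nuclei_count=len([m for m in nucleus_masks if m.any()]),
        nci=float(nci),
    )


def detect_clefts(contour_um: np.ndarray, min_depth: float = 0.08) -> list[float]:
    """Cleft depths of a closed nuclear contour (um coordinates).

    Local minima of the smoothed radial function about the centroid,
    scored against the convex-hull radius and normalised by sqrt(A/pi);
    minima closer than 15 degrees merge into one cleft.  Raises on
    self-intersecting contours.
    """
    if len(contour_um) < 8:
        raise ValueError("contour too short")
    if not ShapelyPolygon(contour_um).is_valid:
        raise ValueError("self-intersecting contour")
    return contour_cleft_depths(
        contour_um, min_depth=min_depth, min_separation_deg=15.0, smooth_sigma_bins=2.0
    )


def classify(record: MorphometryRecord) -> MorphotypeCall:
    """Assign one morphotype by the fixed decision cascade."""
    trace: list[str] = []
    d = record.equivalent_diameter_um
    nc = record.nc_ratio
    deep = [c for c in record.cleft_depths if c >= CLEFT_LOBED_DEPTH]
    shallow = [
        c for c in record.cleft_depths if KIDNEY_DEPTH_RANGE[0] <= c < KIDNEY_DEPTH_RANGE[1]
    ]
    granular = record.granule_count >= GRANULAR_MIN_GRANULES

    if record.nuclei_count >= 2:
        trace.append("nuclei>=2")
        return MorphotypeCall("binuclear_lymphocyte", trace)
    if len(deep) >= 2:
        trace.append(f"clefts>=2@{CLEFT_LOBED_DEPTH}")
        if granular:
            trace.append("granules>=3")
            return MorphotypeCall("granular_lobed_lymphocyte", trace)
        return MorphotypeCall("lobed_lymphocyte", trace)
    if granular:
        trace.append("granules>=3")
        return MorphotypeCall("granular_lymphocyte", trace)
    if d > MONOCYTE_MIN_DIAMETER and nc < 2.0 and len(shallow) >= 1 and not deep:
        trace.append("large+lowNC+kidney")
        return MorphotypeCall("monocyte", trace)
    if REACTIVE_RANGE[0] <= d <= REACTIVE_RANGE[1] and 1.0 <= nc <= 2.0:
        trace.append("reactive-size+NC")
        return MorphotypeCall("reactive_lymphocyte", trace)
    if d <= SMALL_MAX_DIAMETER:
        trace.append("d<=12")
        return MorphotypeCall("small_lymphocyte", trace)
    if d < LARGE_MIN_DIAMETER:
        # the 12-13 um gap: assign by NC ratio
        trace.append("gap-by-NC")
        return MorphotypeCall(
            "small_lymphocyte" if nc > SMALL_NC_MIN else "large_lymphocyte", trace
        )
    if d <= LARGE_MAX_DIAMETER + 0.5:
        trace.append("13-15um")
        return MorphotypeCall("large_lymphocyte", trace)
    trace.append("fallback")
    return MorphotypeCall("other", trace)


def measure_all(seg: SegmentationResult, exclude_border: bool = True) -> pd.DataFrame:
    """Measure and classify every segmented cell; one row per cell.

    Cells whose mask touches the image border are clipped and excluded by
    default (their area, NC ratio and cleft geometry are unreliable).
    """
    h, w = seg.cell_labels.shape
    border = np.zeros(int(seg.cell_labels.max()) + 1, dtype=bool)
    if exclude_border and seg.cells:
        for edge in (seg.cell_labels[0], seg.cell_labels[-1],
                     seg.cell_labels[:, 0], seg.cell_labels[:, -1]):
            border[np.unique(edge)] = True
    rows = []
    for rec in seg.cells:
        if exclude_border and border[rec.label]:
            continue
        cell, nucs, _ = seg.masks_for(rec)
        try:
            m = measure(cell, nucs, seg.pixel_scale_um, granule_count=rec.granule_count)
        except ValueError:
            continue
        call = classify(m)
        rows.append(
            {
                "label": rec.label,
                "x_um": rec.center_um[0],
                "y_um": rec.center_um[1],
                "cell_area_um2": m.cell_area_um2,
                "equivalent_diameter_um": m.equivalent_diameter_um,
                "nuclear_area_um2": m.nuclear_area_um2,
                "nuclear_perimeter_um": m.nuclear_perimeter_um,
                "nc_ratio": m.nc_ratio,
                "granule_count": m.granule_count,
                "n_clefts_deep": sum(1 for c in m.cleft_depths if c >= CLEFT_LOBED_DEPTH),
                "max_cleft_depth": max(m.cleft_depths, default=0.0),
                "nuclei_count": m.nuclei_count,
                "nci": m.nci,
                "morphotype": call.label,
                "rule_trace": ";".join(call.rule_trace),
            }
        )
    return pd.DataFrame(rows)
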