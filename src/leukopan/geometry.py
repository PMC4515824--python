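"""Analytic cell and nucleus geometry.

Nuclei are star-shaped contours given by a radial function about the
origin.  Three families cover the morphotypes seen on the array:

* ellipses (non-lobed lymphocyte nuclei),
* lobed contours ``r(theta) = r0 * (1 - amp * g(theta))`` where ``g`` is a
  sum of ``k >= 2`` wrapped Gaussian notches ("clover-leaf" radially
  segmented nuclei),
* kidney contours (a single wide, shallow indentation; monocytes).

Every shape carries its area, perimeter and nuclear contour index
NCI = P / sqrt(A) computed from a dense polygonal discretisation
(relative accuracy well below 1e-4), plus ground-truth cleft depths.

Cleft depth convention: a cleft is a local minimum of the radial function
about the centroid; its depth is measured from the *convex hull* radius at
the same angle, normalised by the equivalent radius sqrt(A/pi).  The hull
is the local baseline: it is identically the contour for any convex shape,
so an eccentric ellipse has depth zero while a true notch scores its full
indentation.  The same definition is used by the measurement side
(:func:`leukopan.morphometry.detect_clefts`), so generator ground truth and
measured depths are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import brentq
from scipy.spatial import ConvexHull
from scipy.special import ellipe

DISK_NCI = 2.0 * np.sqrt(np.pi)  # 3.5449..., the minimum over all shapes

_N_THETA = 2048
_THETA = np.linspace(0.0, 2.0 * np.pi, _N_THETA, endpoint=False)


# ---------------------------------------------------------------------------
# polygon primitives


def polygon_area(vertices: np.ndarray) -> float:
    """Shoelace area of a closed polygon given as an (n, 2) vertex array."""
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_perimeter(vertices: np.ndarray) -> float:
    d = np.diff(np.vstack([vertices, vertices[:1]]), axis=0)
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def polygon_centroid(vertices: np.ndarray) -> np.ndarray:
    x, y = vertices[:, 0], vertices[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = cross.sum() / 2.0
    cx = ((x + xn) * cross).sum() / (6.0 * a)
    cy = ((y + yn) * cross).sum() / (6.0 * a)
    return np.array([cx, cy])


def _hull_radius(hull_pts: np.ndarray, angles: np.ndarray) -> np.ndarray:
    """Radial function of a convex polygon (vertices about the origin)."""
    p = hull_pts
    e = np.roll(p, -1, axis=0) - p
    out = np.empty(len(angles))
    for j, th in enumerate(angles):
        dx, dy = np.cos(th), np.sin(th)
        det = -dx * e[:, 1] + e[:, 0] * dy
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (-p[:, 0] * e[:, 1] + e[:, 0] * p[:, 1]) / det
            s = (dx * p[:, 1] - dy * p[:, 0]) / det
        ok = (np.abs(det) > 1e-14) & (t > 0) & (s >= -1e-9) & (s <= 1 + 1e-9)
        out[j] = t[ok].max(initial=0.0)
    return out


def contour_cleft_depths(
    vertices: np.ndarray,
    min_depth: float = 0.08,
    min_separation_deg: float = 15.0,
    n_bins: int = 720,
    smooth_sigma_bins: float = 0.0,
) -> list[float]:
    """Cleft depths of a star-shaped closed contour.

    Recentres on the polygon centroid, resamples the radial function on a
    uniform angular grid, optionally smooths it circularly, finds local
    minima and scores each against the convex-hull radius at the same
    angle, normalised by sqrt(A/pi).  Minima closer than
    ``min_separation_deg`` are merged keeping the deepest.
    """
    c = polygon_centroid(vertices)
    p = vertices - c
    theta = np.arctan2(p[:, 1], p[:, 0])
    r = np.hypot(p[:, 0], p[:, 1])
    order = np.argsort(theta)
    theta, r = theta[order], r[order]
    grid = np.linspace(-np.pi, np.pi, n_bins, endpoint=False)
    # wrap-around interpolation of r(theta)
    theta_ext = np.concatenate([theta - 2 * np.pi, theta, theta + 2 * np.pi])
    r_ext = np.concatenate([r, r, r])
    rg = np.interp(grid, theta_ext, r_ext)
    if smooth_sigma_bins > 0:
        m = int(np.ceil(4 * smooth_sigma_bins))
        kx = np.arange(-m, m + 1)
        kern = np.exp(-0.5 * (kx / smooth_sigma_bins) ** 2)
        kern /= kern.sum()
        rg = np.convolve(np.concatenate([rg[-m:], rg, rg[:m]]), kern, mode="same")[m:-m]

    area = polygon_area(vertices)
    r_eff = np.sqrt(area / np.pi)
    hull = ConvexHull(p)
    hull_pts = p[hull.vertices]

    prev = np.roll(rg, 1)
    nxt = np.roll(rg, -1)
    is_min = (rg <= prev) & (rg < nxt)
    idx = np.where(is_min)[0]
    if len(idx) == 0:
        return []
    rh = _hull_radius(hull_pts, grid[idx])
    depths = (rh - rg[idx]) / r_eff
    keep = depths >= min_depth
    idx, depths = idx[keep], depths[keep]
    if len(idx) == 0:
        return []
    # merge minima closer than the angular separation threshold (circular)
    sep = np.deg2rad(min_separation_deg)
    order = np.argsort(-depths)
    chosen: list[int] = []
    for i in order:
        ang = grid[idx[i]]
        ok = True
        for j in chosen:
            d = abs(np.angle(np.exp(1j * (ang - grid[idx[j]]))))
            if d < sep:
                ok = False
                break
        if ok:
            chosen.append(i)
    return sorted((float(depths[i]) for i in chosen), reverse=True)


# ---------------------------------------------------------------------------
# shape families


@dataclass(frozen=True)
class NucleusShape:
    """A closed nuclear contour with analytic morphometry.

    ``vertices`` are (n, 2) coordinates in micrometres about the shape
    centroid.  ``cleft_depths`` are the hull-based relative depths (ground
    truth for :func:`leukopan.morphometry.detect_clefts`).
    """

    vertices: np.ndarray
    area: float
    perimeter: float
    nci: float
    cleft_depths: tuple[float, ...] = ()
    family: str = "ellipse"

    def scaled(self, target_area: float) -> "NucleusShape":
        s = np.sqrt(target_area / self.area)
        return NucleusShape(
            vertices=self.vertices * s,
            area=self.area * s * s,
            perimeter=self.perimeter * s,
            nci=self.nci,
            cleft_depths=self.cleft_depths,
            family=self.family,
        )


def _shape_from_radial(r: np.ndarray, family: str, find_clefts: bool) -> NucleusShape:
    v = np.c_[r * np.cos(_THETA), r * np.sin(_THETA)]
    v = v - polygon_centroid(v)
    area = polygon_area(v)
    per = polygon_perimeter(v)
    depths = tuple(contour_cleft_depths(v)) if find_clefts else ()
    return NucleusShape(v, area, per, per / np.sqrt(area), depths, family)


def ellipse_shape(axis_ratio: float, phase: float = 0.0, area: float = np.pi) -> NucleusShape:
    """Ellipse with major:minor axis ratio ``axis_ratio`` >= 1."""
    if axis_ratio < 1.0:
        raise ValueError("axis_ratio must be >= 1")
    q = np.sqrt(axis_ratio)
    a, b = q, 1.0 / q
    r = a * b / np.sqrt((b * np.cos(_THETA - phase)) ** 2 + (a * np.sin(_THETA - phase)) ** 2)
    return _shape_from_radial(r, "ellipse", find_clefts=False).scaled(area)


def ellipse_nci(axis_ratio: float) -> float:
    """Closed-form NCI of an ellipse (series-accurate perimeter)."""
    m = 1.0 - 1.0 / axis_ratio**2
    return float(4.0 * np.sqrt(axis_ratio) * ellipe(m) / np.sqrt(np.pi))


def ellipse_ratio_for_nci(target: float) -> float:
    if target < DISK_NCI - 1e-9:
        raise ValueError(f"NCI below the disk minimum {DISK_NCI:.4f}")
    if target <= DISK_NCI + 1e-9:
        return 1.0
    return float(brentq(lambda q: ellipse_nci(q) - target, 1.0 + 1e-9, 12.0, xtol=1e-10))


def _notch_profile(theta: np.ndarray, k: int, amp: float, sigma: float, phase: float) -> np.ndarray:
    g = np.zeros_like(theta)
    for c in phase + np.arange(k) * 2.0 * np.pi / k:
        d = np.angle(np.exp(1j * (theta - c)))
        g += np.exp(-0.5 * (d / sigma) ** 2)
    return 1.0 - amp * g


def lobed_shape(
    k: int,
    amp: float,
    sigma: float = 0.12,
    phase: float = 0.0,
    area: float = np.pi,
    axis_ratio: float = 1.0,
) -> NucleusShape:
    """Radially segmented ("clover-leaf") nucleus with ``k`` notches.

    ``amp`` is the notch amplitude relative to the base radius (must be
    < 1); the reported ground-truth cleft depths use the hull-based
    convention and are generally larger than ``amp`` because lobing
    shrinks the equivalent radius.
    """
    if k < 2:
        raise ValueError("lobed nuclei need k >= 2 notches")
    if not 0.0 < amp < 1.0:
        raise ValueError("notch amplitude must be in (0, 1)")
    r = _notch_profile(_THETA, k, amp, sigma, phase)
    if axis_ratio != 1.0:
        q = np.sqrt(axis_ratio)
        r = r * (q * (1.0 / q)) / np.sqrt(
            ((1.0 / q) * np.cos(_THETA - phase)) ** 2 + (q * np.sin(_THETA - phase)) ** 2
        )
    return _shape_from_radial(r, "lobed", find_clefts=True).scaled(area)


def kidney_shape(
    indent_depth: float = 0.3,
    width: float = 0.6,
    phase: float = 0.0,
    area: float = np.pi,
) -> NucleusShape:
    """Kidney/bean contour: one wide indentation, shallower than a cleft."""
    if not 0.0 < indent_depth < 1.0:
        raise ValueError("indent_depth must be in (0, 1)")
    r = _notch_profile(_THETA, 1, indent_depth, width, phase)
    return _shape_from_radial(r, "kidney", find_clefts=True).scaled(area)


def lobed_nci(k: int, amp: float, sigma: float = 0.12) -> float:
    r = _notch_profile(_THETA, k, amp, sigma, 0.0)
    v = np.c_[r * np.cos(_THETA), r * np.sin(_THETA)]
    return polygon_perimeter(v) / np.sqrt(polygon_area(v))


def lobed_amp_for_nci(target: float, k: int = 2, sigma: float = 0.12) -> float:
    """Notch amplitude giving a target NCI (monotone in amp; bisection)."""
    lo, hi = 1e-3, 0.95
    if not lobed_nci(k, lo, sigma) <= target <= lobed_nci(k, hi, sigma):
        raise ValueError(f"target NCI {target} out of range for k={k}, sigma={sigma}")
    return float(brentq(lambda a: lobed_nci(k, a, sigma) - target, lo, hi, xtol=1e-8))


@lru_cache(maxsize=256)
def _kidney_depth_table(width: float) -> tuple[tuple[float, ...], tuple[float, ...]]:
    amps = np.linspace(0.25, 0.9, 14)
    depths = []
    for a in amps:
        s = kidney_shape(a, width)
        depths.append(s.cleft_depths[0] if s.cleft_depths else 0.0)
    return tuple(amps), tuple(depths)


def kidney_amp_for_depth(target_depth: float, width: float = 0.3) -> float:
    """Indent amplitude whose hull-based depth hits target (kidney nuclei).

    Wide shallow notches can leave the contour convex (hull depth 0), so
    the usable range starts around amplitude ~0.3 for width ~0.3.
    Interpolated from a cached amp->depth table (depth is monotone in amp).
    """
    amps, depths = _kidney_depth_table(round(width, 2))
    if not depths[0] <= target_depth <= depths[-1]:
        raise ValueError(f"target depth {target_depth} out of range for width={width}")
    return float(np.interp(target_depth, depths, amps))


@lru_cache(maxsize=256)
def _lobed_depth_table(k: int, sigma: float) -> tuple[tuple[float, ...], tuple[float, ...]]:
    amps = np.linspace(0.1, 0.95, 18)
    depths = []
    for a in amps:
        s = lobed_shape(k, a, sigma)
        depths.append(s.cleft_depths[0] if s.cleft_depths else 0.0)
    return tuple(amps), tuple(depths)


def lobed_amp_for_depth(target_depth: float, k: int = 2, sigma: float = 0.12) -> float:
    """Notch amplitude whose hull-based ground-truth cleft depth hits target."""
    amps, depths = _lobed_depth_table(k, round(sigma, 3))
    if not depths[0] <= target_depth <= depths[-1]:
        raise ValueError(f"target depth {target_depth} out of range for k={k}, sigma={sigma}")
    return float(np.interp(target_depth, depths, amps))


# ---------------------------------------------------------------------------
# NCI population samplers (Fig-5Q-like study populations)


def sample_lobed_nci(rng: np.random.Generator, n: int) -> np.ndarray:
    """Lobed-nucleus NCI values on [4.2, 5.0] with median 4.4.

    Two-piece uniform mixture: half the mass on [4.2, 4.4], half on
    [4.4, 5.0], so the median is exactly 4.4 and the support matches the
    observed lobed-nucleus range.
    """
    lower = rng.random(n) < 0.5
    out = np.where(lower, rng.uniform(4.2, 4.4, n), rng.uniform(4.4, 5.0, n))
    return out


def sample_nonlobed_nci(rng: np.random.Generator, n: int) -> np.ndarray:
    """Non-lobed (elliptical) NCI values with median 3.75, support [3.56, 4.1]."""
    lower = rng.random(n) < 0.5
    return np.where(lower, rng.uniform(3.56, 3.75, n), rng.uniform(3.75, 4.1, n))


# ---------------------------------------------------------------------------
# morphotype geometry library


@dataclass(frozen=True)
class MorphotypeGeometry:
    """Generative geometry for one morphotype.

    ``diameter_um`` and ``nuclear_fraction`` (nuclear area / cell area) are
    uniform ranges; the nuclear fraction encodes the NC ratio convention
    NC = A_nuc : (A_cell - A_nuc), e.g. NC 3:1 <-> fraction 0.75.
    """

    name: str
    diameter_um: tuple[float, float]
    nuclear_fraction: tuple[float, float]
    granules: tuple[int, int] = (0, 0)
    nucleus_kind: str = "ellipse"  # ellipse | lobed | kidney
    ellipse_ratio: tuple[float, float] = (1.0, 1.3)
    lobe_k: tuple[int, ...] = (2,)
    cleft_depth: tuple[float, float] = (0.55, 0.75)  # hull-based target, lobed only
    kidney_depth: tuple[float, float] = (0.25, 0.38)
    nuclei_count: int = 1

    def __post_init__(self) -> None:
        if self.diameter_um[0] <= 0:
            raise ValueError("cell diameter must be positive")
        if self.nucleus_kind == "lobed":
            if min(self.lobe_k) < 2:
                raise ValueError("lobed nuclei need k >= 2")
            if self.cleft_depth[1] >= 1.0:
                raise ValueError("cleft depth must be < 1")


# Diameters and NC ranges follow the smear-morphology class definitions the
# classifier uses; granule counts and monocyte geometry are package defaults
# (not constrained by published morphometry) and are configurable.
MORPHOTYPE_GEOMETRY: dict[str, MorphotypeGeometry] = {
    "small_lymphocyte": MorphotypeGeometry(
        "small_lymphocyte", (9.0, 11.5), (0.78, 0.82), ellipse_ratio=(1.0, 1.3)
    ),
    "large_lymphocyte": MorphotypeGeometry(
        "large_lymphocyte", (13.0, 15.0), (0.70, 0.737), ellipse_ratio=(1.0, 1.4)
    ),
    "granular_lymphocyte": MorphotypeGeometry(
        "granular_lymphocyte", (13.0, 16.0), (0.70, 0.737), granules=(4, 8),
        ellipse_ratio=(1.0, 1.4),
    ),
    "lobed_lymphocyte": MorphotypeGeometry(
        "lobed_lymphocyte", (13.0, 15.0), (0.70, 0.737), nucleus_kind="lobed",
        lobe_k=(2, 3), cleft_depth=(0.55, 0.72),
    ),
    "granular_lobed_lymphocyte": MorphotypeGeometry(
        "granular_lobed_lymphocyte", (13.0, 15.0), (0.70, 0.737), granules=(4, 8),
        nucleus_kind="lobed", lobe_k=(2, 3), cleft_depth=(0.55, 0.72),
    ),
    "monocyte": MorphotypeGeometry(
        "monocyte", (15.5, 19.0), (0.48, 0.55), nucleus_kind="kidney",
        kidney_depth=(0.25, 0.38),
    ),
    "reactive_lymphocyte": MorphotypeGeometry(
        "reactive_lymphocyte", (15.5, 19.5), (0.52, 0.62), ellipse_ratio=(1.1, 1.5)
    ),
    "binuclear_lymphocyte": MorphotypeGeometry(
        "binuclear_lymphocyte", (12.0, 15.0), (0.55, 0.68), ellipse_ratio=(1.1, 1.4),
        nuclei_count=2,
    ),
    "plasma_cell": MorphotypeGeometry(
        "plasma_cell", (14.0, 18.0), (0.50, 0.60), ellipse_ratio=(1.1, 1.4)
    ),
    "hairy_cell": MorphotypeGeometry(
        "hairy_cell", (15.0, 19.0), (0.50, 0.60), ellipse_ratio=(1.1, 1.4)
    ),
    "other": MorphotypeGeometry("other", (12.0, 16.0), (0.6, 0.7)),
}


@dataclass
class CellGeometry:
    """Sampled geometry of one rendered cell (analytic ground truth)."""

    morphotype: str
    diameter_um: float
    cell_area_um2: float
    nuclear_fraction: float
    nuclei: list[NucleusShape] = field(default_factory=list)
    granule_count: int = 0

    @property
    def nuclear_area_um2(self) -> float:
        return sum(n.area for n in self.nuclei)


def synthesize_nucleus(geom: MorphotypeGeometry, rng: np.random.Generator) -> NucleusShape:
    """Draw one nucleus contour (unit area; callers rescale) for a morphotype."""
    phase = rng.uniform(0, 2 * np.pi)
    if geom.nucleus_kind == "lobed":
        k = int(rng.choice(geom.lobe_k))
        sigma = 0.12 if k == 2 else 0.20
        depth = rng.uniform(*geom.cleft_depth)
        amp = lobed_amp_for_depth(depth, k=k, sigma=sigma)
        return lobed_shape(k, amp, sigma, phase)
    if geom.nucleus_kind == "kidney":
        width = rng.uniform(0.28, 0.35)
        amp = kidney_amp_for_depth(rng.uniform(*geom.kidney_depth), width)
        return kidney_shape(amp, width, phase)
    return ellipse_shape(rng.uniform(*geom.ellipse_ratio), phase)


def sample_cell_geometry(
    morphotype: str,
    rng: np.random.Generator,
    library: dict[str, MorphotypeGeometry] | None = None,
) -> CellGeometry:
    """Sample a full cell: diameter, nuclear fraction, nuclei, granules."""
    lib = library if library is not None else MORPHOTYPE_GEOMETRY
    geom = lib.get(morphotype, lib["other"])
    d = rng.uniform(*geom.diameter_um)
    cell_area = np.pi * (d / 2.0) ** 2
    nf = rng.uniform(*geom.nuclear_fraction)
    n_area = nf * cell_area
    nuclei = [
        synthesize_nucleus(geom, rng).scaled(n_area / geom.nuclei_count)
        for _ in range(geom.nuclei_count)
    ]
    g_lo, g_hi = geom.granules
    granules = int(rng.integers(g_lo, g_hi + 1)) if g_hi > 0 else 0
    return CellGeometry(morphotype, d, cell_area, nf, nuclei, granules)
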