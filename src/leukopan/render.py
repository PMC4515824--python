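"""Synthetic microscopy of captured cells with analytic ground truth.

Each rendered cell is a flattened disc (cytoplasm channel) containing one
or two nuclei (nucleus channel) drawn from the analytic contour families in
:mod:`leukopan.geometry`, plus optional high-contrast cytoplasmic granules.
The two-channel raster emulates what the measurement pipeline needs from a
stained brightfield image (cell body + granules, nuclear outline) without
simulating stain colour.

Placement is overlap-free: random sequential adsorption below ~30% area
coverage, a jittered hexagonal lattice above it (random placement jams well
below the densities seen on saturated spots).  A "donut" mode biases the
radial placement density toward the spot edge, emulating the non-uniform
antibody distribution artifact of dried protein spots.

Ground truth records, per cell: centre, class, morphotype, diameter, and
the analytic nuclear area/perimeter/NCI/cleft depths actually rasterised.
Rendering is bit-reproducible for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import polygon as draw_polygon

from .geometry import (
    MORPHOTYPE_GEOMETRY,
    CellGeometry,
    MorphotypeGeometry,
    sample_cell_geometry,
)

CYTO_LEVEL = 0.55
NUCLEUS_LEVEL = 0.9
GRANULE_LEVEL = 1.0
GRANULE_RADIUS_UM = 0.5


@dataclass
class RenderParams:
    pixel_scale_um: float = 0.25  # um per pixel
    noise_sigma: float = 0.02
    mode: str = "uniform"  # uniform | donut
    min_nuclear_radius_px: float = 10.0

    def __post_init__(self) -> None:
        if self.pixel_scale_um <= 0:
            raise ValueError("pixel scale must be positive")
        if self.mode not in ("uniform", "donut"):
            raise ValueError("mode must be 'uniform' or 'donut'")


@dataclass
class SpotImage:
    """Two-channel raster plus per-cell analytic ground truth.

    ``image`` has shape (2, H, W): channel 0 cytoplasm + granules,
    channel 1 nuclei.  ``spot_center_um``/``spot_diameter_um`` are set for
    circular spot renders and ``None`` for rectangular fields.
    """

    image: np.ndarray
    pixel_scale_um: float
    ground_truth: pd.DataFrame
    geometries: list[CellGeometry] = field(default_factory=list)
    spot_center_um: tuple[float, float] | None = None
    spot_diameter_um: float | None = None

    @property
    def field_area_mm2(self) -> float:
        h, w = self.image.shape[1:]
        return h * w * (self.pixel_scale_um / 1000.0) ** 2

    @property
    def placed_density(self) -> float:
        """Ground-truth density over the placement region, cells/mm^2."""
        if self.spot_diameter_um is not None:
            area = np.pi * (self.spot_diameter_um / 2000.0) ** 2  # mm^2
            return len(self.ground_truth) / area
        return len(self.ground_truth) / self.field_area_mm2


# ---------------------------------------------------------------------------
# placement


class _Grid:
    """Uniform spatial hash for overlap queries."""

    def __init__(self, cell: float) -> None:
        self.cell = cell
        self.data: dict[tuple[int, int], list[tuple[float, float, float]]] = {}

    def key(self, x: float, y: float) -> tuple[int, int]:
        return (int(x // self.cell), int(y // self.cell))

    def ok(self, x: float, y: float, r: float, factor: float = 0.95) -> bool:
        kx, ky = self.key(x, y)
        for dx in (-1, 0, 1):
            for dy in (-1, 0, 1):
                for (px, py, pr) in self.data.get((kx + dx, ky + dy), ()):
                    if (x - px) ** 2 + (y - py) ** 2 < (factor * (r + pr)) ** 2:
                        return False
        return True

    def add(self, x: float, y: float, r: float) -> None:
        self.data.setdefault(self.key(x, y), []).append((x, y, r))


def _place_rsa(radii, sampler, accept, rng, max_tries: int = 300):
    """Random sequential adsorption honouring per-cell radii."""
    order = np.argsort(-np.asarray(radii))
    grid = _Grid(2.0 * float(np.max(radii)) + 1e-6)
    pos = np.full((len(radii), 2), np.nan)
    for i in order:
        r = radii[i]
        for _ in range(max_tries):
            x, y = sampler()
            if accept is not None and not accept(x, y):
                continue
            if grid.ok(x, y, r):
                grid.add(x, y, r)
                pos[i] = (x, y)
                break
        else:
            raise ValueError(
                "could not place all cells: requested density too high for random placement"
            )
    return pos


def _place_hex(radii, width: float, height: float, rng):
    """Jittered hexagonal lattice for near-saturated densities."""
    n = len(radii)
    area = width * height
    # 0.96: edge truncation eats lattice sites, so overshoot the site count
    s = 0.96 * np.sqrt(2.0 * area / (np.sqrt(3.0) * n))
    r_max = float(np.max(radii))
    if s < 1.9 * r_max:
        raise ValueError("requested density above packing capacity at given diameters")
    jitter = 0.45 * max(0.0, s - 1.9 * r_max)
    dy = s * np.sqrt(3.0) / 2.0
    # rigid lattice with a single global random shift; per-row shifts would
    # break the guaranteed nearest-neighbour spacing
    gx = rng.uniform(0, s / 4)
    gy = rng.uniform(0, dy / 4)
    xs, ys = [], []
    row = 0
    y = (height - np.floor(height / dy) * dy) / 2.0 + gy
    while y < height:
        x = (s / 2.0 if row % 2 else 0.0) + gx
        while x < width:
            xs.append(x)
            ys.append(y)
            x += s
        y += dy
        row += 1
    sites = np.c_[xs, ys]
    if len(sites) < n:
        raise ValueError("requested density above packing capacity at given diameters")
    pick = rng.choice(len(sites), size=n, replace=False)
    pos = sites[pick]
    pos += rng.uniform(-jitter, jitter, size=pos.shape)
    return pos


def place_cells(
    radii_um: np.ndarray,
    width_um: float,
    height_um: float,
    rng: np.random.Generator,
    circular: bool = False,
    mode: str = "uniform",
) -> np.ndarray:
    """Overlap-free cell centres in a rectangle or inscribed disk (um)."""
    radii = np.asarray(radii_um, dtype=float)
    if circular:
        R = min(width_um, height_um) / 2.0
        cx, cy = width_um / 2.0, height_um / 2.0
        region_area = np.pi * R * R
    else:
        region_area = width_um * height_um
    coverage = float(np.sum(np.pi * radii**2) / region_area)

    if circular:
        def sampler():
            r = R * np.sqrt(rng.random())
            th = rng.uniform(0, 2 * np.pi)
            return cx + r * np.cos(th), cy + r * np.sin(th)

        accept = None
        if mode == "donut":
            def accept(x, y):
                rhat2 = ((x - cx) ** 2 + (y - cy) ** 2) / (R * R)
                return rng.random() < (0.45 + 1.55 * rhat2) / 2.0

        return _place_rsa(radii, sampler, accept, rng)

    if mode == "donut":
        raise ValueError("donut mode applies to circular spots")
    if coverage <= 0.30:
        return _place_rsa(radii, lambda: (rng.uniform(0, width_um), rng.uniform(0, height_um)),
                          None, rng)
    return _place_hex(radii, width_um, height_um, rng)


# ---------------------------------------------------------------------------
# rasterisation


def _disc(img: np.ndarray, cx: float, cy: float, r: float, value: float, scale: float) -> None:
    h, w = img.shape
    x0, x1 = int((cx - r) / scale) - 1, int((cx + r) / scale) + 2
    y0, y1 = int((cy - r) / scale) - 1, int((cy + r) / scale) + 2
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    m = ((xx + 0.5) * scale - cx) ** 2 + ((yy + 0.5) * scale - cy) ** 2 <= r * r
    sub = img[y0:y1, x0:x1]
    sub[m] = np.maximum(sub[m], value)


def _poly(img: np.ndarray, verts_um: np.ndarray, value: float, scale: float) -> None:
    # decimate to ~1.5 vertices per rasterised pixel of contour length
    n = len(verts_um)
    span = verts_um[:, 0].max() - verts_um[:, 0].min()
    target = max(64, int(1.5 * np.pi * span / scale))
    step = max(1, n // target)
    v = verts_um[::step]
    rr, cc = draw_polygon(v[:, 1] / scale - 0.5, v[:, 0] / scale - 0.5, shape=img.shape)
    img[rr, cc] = np.maximum(img[rr, cc], value)


def _nucleus_radial_lookup(verts: np.ndarray):
    th = np.arctan2(verts[:, 1], verts[:, 0])
    r = np.hypot(verts[:, 0], verts[:, 1])
    o = np.argsort(th)
    th, r = th[o], r[o]
    return np.concatenate([th - 2 * np.pi, th, th + 2 * np.pi]), np.concatenate([r, r, r])


def _render_cells(
    geoms: list[CellGeometry],
    pos_um: np.ndarray,
    shape_px: tuple[int, int],
    scale: float,
    rng: np.random.Generator,
    noise_sigma: float,
) -> np.ndarray:
    img = np.zeros((2,) + shape_px, dtype=np.float32)
    for geom, (x, y) in zip(geoms, pos_um):
        r_cell = geom.diameter_um / 2.0
        _disc(img[0], x, y, r_cell, CYTO_LEVEL, scale)
        n = len(geom.nuclei)
        if n == 1:
            offsets = [np.zeros(2)]
        else:
            # two nuclei side by side along a random axis
            ax = rng.uniform(0, 2 * np.pi)
            u = np.array([np.cos(ax), np.sin(ax)])
            rn = np.sqrt(geom.nuclei[0].area / np.pi)
            d = min(1.12 * rn, 0.92 * r_cell - rn)
            d = max(d, 1.02 * rn)
            offsets = [d * u, -d * u]
        for nuc, off in zip(geom.nuclei, offsets):
            _poly(img[1], nuc.vertices + np.array([x, y]) + off, NUCLEUS_LEVEL, scale)
        if geom.granule_count > 0:
            th_l, r_l = _nucleus_radial_lookup(geom.nuclei[0].vertices)
            placed = 0
            centers: list[tuple[float, float]] = []
            for _ in range(80 * geom.granule_count):
                if placed >= geom.granule_count:
                    break
                th = rng.uniform(-np.pi, np.pi)
                rn_th = np.interp(th, th_l, r_l)
                # granules may half-overlap the nuclear outline; they live in
                # the cytoplasm channel and stay countable either way
                lo = rn_th
                hi = r_cell - GRANULE_RADIUS_UM * 1.2
                if hi <= lo:
                    continue
                rad = rng.uniform(lo, hi)
                gx, gy = rad * np.cos(th), rad * np.sin(th)
                # keep granules separated so blobs are not merged at detection
                # (3.2 radii leaves a >=1 px gap at 0.3 um/px)
                if any((gx - px) ** 2 + (gy - py) ** 2 < (3.2 * GRANULE_RADIUS_UM) ** 2
                       for px, py in centers):
                    continue
                centers.append((gx, gy))
                _disc(img[0], x + gx, y + gy, GRANULE_RADIUS_UM, GRANULE_LEVEL, scale)
                placed += 1
            geom.granule_count = placed  # ground truth = granules actually drawn
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, img.shape).astype(np.float32)
        np.clip(img, 0.0, None, out=img)
    return img


def _ground_truth_frame(geoms, pos_um, extra: dict | None = None) -> pd.DataFrame:
    rows = []
    for i, (g, (x, y)) in enumerate(zip(geoms, pos_um)):
        nuc = g.nuclei[0]
        rows.append(
            {
                "cell_id": i,
                "x_um": x,
                "y_um": y,
                "morphotype": g.morphotype,
                "diameter_um": g.diameter_um,
                "cell_area_um2": g.cell_area_um2,
                "nuclear_fraction": g.nuclear_fraction,
                "nuclear_area_um2": g.nuclear_area_um2,
                "nuclear_perimeter_um": nuc.perimeter * np.sqrt(1.0),
                "nci": nuc.nci,
                "cleft_depths": nuc.cleft_depths,
                "granule_count": g.granule_count,
                "nuclei_count": len(g.nuclei),
            }
        )
    df = pd.DataFrame(rows)
    if extra:
        for k, v in extra.items():
            df[k] = v
    return df


def _check_scale(geoms: list[CellGeometry], params: RenderParams) -> None:
    min_rn = min(np.sqrt(n.area / np.pi) for g in geoms for n in g.nuclei)
    if min_rn / params.pixel_scale_um < params.min_nuclear_radius_px:
        raise ValueError(
            f"pixel scale {params.pixel_scale_um} um/px too coarse: min nuclear radius "
            f"{min_rn / params.pixel_scale_um:.1f} px < {params.min_nuclear_radius_px}"
        )


def _sample_geometries(roster: pd.DataFrame, rng, library) -> list[CellGeometry]:
    geoms = []
    for _, row in roster.iterrows():
        g = sample_cell_geometry(row["morphotype"], rng, library)
        if "diameter_um" in row and np.isfinite(row["diameter_um"]):
            # honour the roster's diameter; rescale areas accordingly
            d = float(row["diameter_um"])
            cell_area = np.pi * (d / 2.0) ** 2
            factor = cell_area * g.nuclear_fraction / g.nuclear_area_um2
            g = CellGeometry(
                g.morphotype, d, cell_area, g.nuclear_fraction,
                [n.scaled(n.area * factor) for n in g.nuclei], g.granule_count,
            )
        geoms.append(g)
    return geoms


def render_spot(
    roster: pd.DataFrame,
    spot_diameter_mm: float,
    render: RenderParams | None = None,
    seed: int = 0,
    library: dict[str, MorphotypeGeometry] | None = None,
    pad_um: float = 40.0,
) -> SpotImage:
    """Render a full circular antibody spot from a captured-cell roster.

    The roster needs ``morphotype`` and (optionally) ``diameter_um``
    columns.  Cells are placed inside the spot disk; ``donut`` mode biases
    placement toward the rim.  Raises if the roster cannot be placed at
    the implied density.
    """
    params = render if render is not None else RenderParams()
    rng = np.random.default_rng(seed)
    D = spot_diameter_mm * 1000.0
    side = D + 2 * pad_um
    geoms = _sample_geometries(roster, rng, library)
    if not geoms:
        npx = int(np.ceil(side / params.pixel_scale_um))
        return SpotImage(
            np.zeros((2, npx, npx), dtype=np.float32), params.pixel_scale_um,
            _ground_truth_frame([], np.zeros((0, 2))), [],
            (side / 2, side / 2), D,
        )
    _check_scale(geoms, params)
    radii = np.array([g.diameter_um / 2.0 for g in geoms])
    inner = np.full(2, side / 2.0)
    pos = place_cells(radii, D, D, rng, circular=True, mode=params.mode)
    pos = pos + (inner - D / 2.0)  # shift into padded frame
    npx = int(np.ceil(side / params.pixel_scale_um))
    img = _render_cells(geoms, pos, (npx, npx), params.pixel_scale_um, rng,
                        params.noise_sigma)
    gt = _ground_truth_frame(geoms, pos)
    return SpotImage(img, params.pixel_scale_um, gt, geoms, (side / 2, side / 2), D)


def render_field(
    roster: pd.DataFrame,
    width_mm: float,
    height_mm: float,
    render: RenderParams | None = None,
    seed: int = 0,
    library: dict[str, MorphotypeGeometry] | None = None,
) -> SpotImage:
    """Render a rectangular microscope field (e.g. one x200 counting field)."""
    params = render if render is not None else RenderParams()
    rng = np.random.default_rng(seed)
    W, H = width_mm * 1000.0, height_mm * 1000.0
    geoms = _sample_geometries(roster, rng, library)
    npx = (int(np.ceil(H / params.pixel_scale_um)), int(np.ceil(W / params.pixel_scale_um)))
    if not geoms:
        return SpotImage(np.zeros((2,) + npx, dtype=np.float32), params.pixel_scale_um,
                         _ground_truth_frame([], np.zeros((0, 2))), [])
    _check_scale(geoms, params)
    radii = np.array([g.diameter_um / 2.0 for g in geoms])
    pos = place_cells(radii, W, H, rng, circular=False, mode=params.mode)
    img = _render_cells(geoms, pos, npx, params.pixel_scale_um, rng, params.noise_sigma)
    return SpotImage(img, params.pixel_scale_um, _ground_truth_frame(geoms, pos), geoms)


def roster_for_density(
    density_per_mm2: float,
    area_mm2: float,
    morphotype: str = "small_lymphocyte",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Convenience: a single-morphotype roster realising a target density."""
    n = int(round(density_per_mm2 * area_mm2))
    return pd.DataFrame({"morphotype": [morphotype] * n, "diameter_um": [np.nan] * n})


def save_tiff(spot: SpotImage, path) -> None:
    import tifffile

    tifffile.imwrite(path, spot.image)


def save_png_preview(spot: SpotImage, path) -> None:
    from imageio import v3 as iio

    rgb = np.zeros(spot.image.shape[1:] + (3,), dtype=np.uint8)
    rgb[..., 0] = np.clip(spot.image[0] * 255, 0, 255)
    rgb[..., 2] = np.clip(spot.image[1] * 255, 0, 255)
    iio.imwrite(path, rgb)
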