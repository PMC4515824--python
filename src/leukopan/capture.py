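"""Cell binding to antibody spots: saturation, specificity, capacity.

The bound-cell density on a spot follows a saturation law in the analysed
suspension concentration x (1e6 cells/ml):

    y(x) = a * (1 - exp(-x / x0))

with one characteristic concentration x0 shared by all spots and a per-spot
asymptote ``a = d_sat * f`` proportional to the fraction ``f`` of suspension
cells expressing the spot's target.  Because x0 is shared, the ratio of any
two spot densities is independent of x, which is what makes the
CD45-normalised density an estimator of the percent-positive fraction.

Spot capacity is bounded by a geometric packing limit: one cell per d x d
square-lattice site for cell diameter d, i.e. ceil(1/d^2) cells per mm^2
(6945/mm^2 at 12 um, 8265/mm^2 at 11 um).

Specificity: a per-spot matched-capture purity gives the expected fraction
of captured cells that truly express the target (0.93-0.98 by default);
the residual cross-binding is drawn from small-lymphocyte-morphotype cells
that do not express the target, matching the observed composition of the
cross-bound population (helper/B small lymphocytes, no granular or
lobed-nucleus cells).  Monocytes additionally bind Fc-coated surfaces
above the ~18 degC phagocytosis threshold; below it this term is absent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import DonorTruth
from .panel import DEFAULT_PURITY, PanelConfig


@dataclass
class SaturationParams:
    """Shared characteristic concentration and per-spot asymptotes."""

    x0: float = 2.4  # 1e6 cells/ml
    a: dict[str, float] = field(default_factory=dict)  # spot -> cells/mm^2

    def __post_init__(self) -> None:
        if self.x0 <= 0:
            raise ValueError("x0 must be positive")
        if any(v < 0 for v in self.a.values()):
            raise ValueError("asymptotic densities must be >= 0")


@dataclass
class CaptureParams:
    """Specificity, background and temperature parameters of one run."""

    matched_capture_purity: dict[str, float] = field(default_factory=dict)
    default_purity: float = 0.995
    cross_binding: float = 0.015  # residual density fraction on target-free spots
    cross_binding_cv: float = 0.35  # run-to-run lognormal spread of that floor
    background_density: float = 12.0  # cells/mm^2 off-spot
    monocyte_nonspecific_density: float = 140.0  # cells/mm^2 on-spot at >= 18 degC
    temperature: float = 4.0  # degC
    phagocytosis_threshold: float = 18.0
    packing_efficiency: float = 0.95
    d_sat: float = 6400.0  # saturated anti-CD45 density, cells/mm^2

    def purity(self, target: str) -> float:
        if target == "CD45":
            return 1.0  # every PBMC expresses CD45; no cross-binding to model
        merged = {**DEFAULT_PURITY, **self.matched_capture_purity}
        return merged.get(target, self.default_purity)

    def __post_init__(self) -> None:
        if self.background_density < 0:
            raise ValueError("background density must be >= 0")
        for t, p in self.matched_capture_purity.items():
            if not 0.0 < p <= 1.0:
                raise ValueError(f"purity for {t} outside (0, 1]")


@dataclass
class SpotCapture:
    target: str
    density: float  # cells/mm^2
    n_captured: int
    cells: pd.DataFrame  # captured roster rows with true labels


@dataclass
class CaptureResult:
    spots: dict[str, SpotCapture]
    off_spot_density: float
    spot_area_mm2: float

    def density_table(self) -> pd.Series:
        return pd.Series({t: s.density for t, s in self.spots.items()}, name="density")


# ---------------------------------------------------------------------------


def packing_limit(diameter_um: float) -> int:
    """Geometric bound on bound-cell density: one cell per d x d lattice site.

    ``ceil(1/d^2)`` with d in mm; 6945 cells/mm^2 for 12 um cells and
    8265 cells/mm^2 for 11 um cells.
    """
    if diameter_um <= 0:
        raise ValueError("diameter must be positive")
    d_mm = diameter_um / 1000.0
    return math.ceil(1.0 / (d_mm * d_mm))


def expected_density(
    fraction_positive: float,
    x: float,
    sat: SaturationParams | None = None,
    d_sat: float = 6400.0,
) -> float:
    """Expected bound density: d_sat * f * (1 - exp(-x/x0)), cells/mm^2."""
    if not 0.0 <= fraction_positive <= 1.0:
        raise ValueError("fraction_positive must be in [0, 1]")
    if x < 0:
        raise ValueError("suspension concentration must be >= 0")
    x0 = (sat.x0 if sat is not None else 2.4)
    return d_sat * fraction_positive * (1.0 - np.exp(-x / x0))


def titration_curve(x: np.ndarray, x0: float, a: float) -> np.ndarray:
    """The saturation-binding model y = a * (1 - exp(-x/x0))."""
    return a * (1.0 - np.exp(-np.asarray(x, dtype=float) / x0))


def _sample_weighted(rng, indices: np.ndarray, weights: np.ndarray, k: int) -> np.ndarray:
    if k >= len(indices):
        return indices
    w = weights / weights.sum()
    return rng.choice(indices, size=k, replace=False, p=w)


def simulate_capture(
    truth: DonorTruth,
    panel: PanelConfig,
    params: CaptureParams | None = None,
    sat: SaturationParams | None = None,
    seed: int = 0,
) -> CaptureResult:
    """Simulate one microarray incubation.

    Per spot the captured count is Poisson(expected density x spot area),
    capped at the packing capacity; roster membership is drawn without
    replacement so the expected fraction of captured cells expressing the
    target equals the spot's matched-capture purity.
    """
    params = params if params is not None else CaptureParams()
    sat = sat if sat is not None else SaturationParams()
    if panel.positive_control not in panel.targets:
        raise ValueError("panel lacks the anti-CD45 positive-control spot")
    if len(truth.cells) == 0:
        raise ValueError("empty roster")
    rng = np.random.default_rng(seed)
    cells = truth.cells
    x = truth.suspension_concentration
    satfrac = 1.0 - np.exp(-x / sat.x0)
    area = panel.spot_area_mm2
    min_diam = float(cells["diameter_um"].min())
    capacity = packing_limit(min_diam) * params.packing_efficiency * area

    is_small = (cells["morphotype"] == "small_lymphocyte").to_numpy()
    all_idx = np.arange(len(cells))

    spots: dict[str, SpotCapture] = {}
    for spot in panel.spots:
        t = spot.target
        if spot.is_negative_control:
            n = rng.poisson(params.background_density * area)
            picked = rng.choice(all_idx, size=min(n, len(all_idx)), replace=False)
            spots[t] = SpotCapture(t, len(picked) / area, len(picked), cells.iloc[picked])
            continue
        f_eff = truth.effective_marker_fraction(t)
        purity = params.purity(t)
        if f_eff > 0:
            mean_density = params.d_sat * satfrac * f_eff / purity
        else:
            # nonspecific floor varies between runs/spots (antibody lot,
            # washing); without this spread, reference intervals for
            # unexpressed targets collapse to the counting noise alone
            cv = params.cross_binding_cv
            jitter = rng.lognormal(-0.5 * np.log1p(cv**2), np.sqrt(np.log1p(cv**2)))
            mean_density = params.d_sat * satfrac * params.cross_binding * jitter
        n = int(min(rng.poisson(mean_density * area), capacity))

        if t == "CD45":
            expressing = all_idx
            weights = np.ones(len(all_idx))
        elif t in cells.columns:
            mask = cells[t].to_numpy()
            expressing = all_idx[mask]
            w = np.ones(len(cells))
            for name, spec in truth.class_specs.items():
                s = spec.expression_strength.get(t, 1.0)
                if s != 1.0:
                    w[(cells["cell_class"] == name).to_numpy()] = s
            weights = w[mask]
        else:
            expressing = np.array([], dtype=int)
            weights = np.array([])

        if len(expressing) > 0:
            n_matched = rng.binomial(n, purity)
            if n_matched > len(expressing):
                warnings.warn(
                    f"{t}: roster has only {len(expressing)} expressing cells for "
                    f"{n_matched} captures; spot purity will be diluted "
                    "(enlarge the roster or shrink the spot)",
                    stacklevel=2,
                )
                n_matched = len(expressing)
        else:
            n_matched = 0
        n_cross = n - n_matched
        matched = _sample_weighted(rng, expressing, weights, n_matched)
        # residual cross-binding comes from small-lymphocyte non-expressors
        non_expr = np.setdiff1d(all_idx, expressing, assume_unique=False)
        pool = non_expr[is_small[non_expr]]
        if len(pool) < n_cross:
            pool = non_expr
        cross = rng.choice(pool, size=min(n_cross, len(pool)), replace=False)

        picked = np.concatenate([matched, cross])
        roster = cells.iloc[picked].copy()
        # temperature-dependent nonspecific monocyte adhesion (step at 18 degC)
        if params.temperature >= params.phagocytosis_threshold:
            n_mono = rng.poisson(params.monocyte_nonspecific_density * area)
            mono_idx = all_idx[(cells["morphotype"] == "monocyte").to_numpy()]
            extra = rng.choice(mono_idx, size=min(n_mono, len(mono_idx)), replace=False)
            roster = pd.concat([roster, cells.iloc[extra]], ignore_index=False)
        spots[t] = SpotCapture(t, len(roster) / area, len(roster), roster)

    off_spot = rng.poisson(params.background_density * area) / area
    return CaptureResult(spots, off_spot, area)
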