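"""Synthetic donor and patient PBMC populations.

The generator produces per-donor cell rosters with the latent structure the
downstream analysis assumes: a small number of cell classes (CD4 T, CD8 T,
NK, B, monocyte, plus optional leukemic clones), each with

* Bernoulli surface-marker expression probabilities per CD antigen,
* a morphotype mixture (small/large/granular/lobed lymphocytes, monocytes,
  rare binuclear cells), and
* an optional per-marker "expression strength" in (0, 1] that scales the
  capture probability (used to model weak CD20/CD22 on CLL cells).

Class fractions vary donor-to-donor as independent truncated normals that
are renormalised to the simplex.  Flow cytometry is simulated as binomial
sampling of the roster's true marker frequencies and serves as the
gold-standard comparator for the normalized-density estimator.

Default class fractions follow standard flow-cytometry reference values
for adult peripheral blood (CD3 ~70%, B ~12%, NK ~5%, monocytes ~13% of
PBMC); the morphotype mixtures within each class are back-calculated from
the captured-cell composition table so that capture under the default
model reproduces that table in expectation (capture is class-independent
at defaults, so captured composition per spot depends only on the
within-class mixtures).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
import yaml

#: morphotype labels used throughout the package
MORPHOTYPES = (
    "small_lymphocyte",
    "large_lymphocyte",
    "lobed_lymphocyte",
    "granular_lymphocyte",
    "granular_lobed_lymphocyte",
    "monocyte",
    "reactive_lymphocyte",
    "binuclear_lymphocyte",
    "plasma_cell",
    "hairy_cell",
    "other",
)

_SIMPLEX_TOL = 1e-9


@dataclass
class CellClassSpec:
    """One latent cell class: marker probabilities and morphotype mixture."""

    name: str
    marker_expression: dict[str, float]
    morphotype_mixture: dict[str, float]
    size_params: tuple[float, float] | None = None  # mean, SD of diameter (um)
    expression_strength: dict[str, float] = dc_field(default_factory=dict)
    trap_prob: float = 0.0

    def __post_init__(self) -> None:
        s = sum(self.morphotype_mixture.values())
        if abs(s - 1.0) > 1e-6:
            raise ValueError(f"{self.name}: morphotype mixture sums to {s}, not 1")
        # exact renormalisation to the simplex tolerance
        self.morphotype_mixture = {k: v / s for k, v in self.morphotype_mixture.items()}
        for cd, p in self.marker_expression.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.name}: expression P({cd}) = {p} outside [0,1]")
        for m in self.morphotype_mixture:
            if m not in MORPHOTYPES:
                raise ValueError(f"{self.name}: unknown morphotype {m!r}")
        if self.size_params is not None and self.size_params[0] <= 0:
            raise ValueError("size mean must be positive")


@dataclass
class DonorTruth:
    """Latent composition of one subject plus a realised cell roster.

    ``cells`` has one row per cell: ``cell_class``, ``morphotype``,
    ``diameter_um``, ``trap_pos`` and one boolean column per CD marker.
    ``suspension_concentration`` is in 1e6 cells/ml.
    """

    class_fractions: dict[str, float]
    class_specs: dict[str, CellClassSpec]
    cells: pd.DataFrame
    suspension_concentration: float = 8.0

    def __post_init__(self) -> None:
        if abs(sum(self.class_fractions.values()) - 1.0) > _SIMPLEX_TOL:
            raise ValueError("class fractions must sum to 1")
        if self.suspension_concentration <= 0:
            raise ValueError("suspension concentration must be positive")

    @property
    def marker_columns(self) -> list[str]:
        skip = {"cell_class", "morphotype", "diameter_um", "trap_pos"}
        return [c for c in self.cells.columns if c not in skip]

    def marker_fraction(self, cd: str) -> float:
        """True fraction of roster cells expressing a CD."""
        if cd == "CD45":
            return 1.0
        if cd not in self.cells.columns:
            return 0.0
        return float(self.cells[cd].mean())

    def effective_marker_fraction(self, cd: str) -> float:
        """Marker fraction weighted by per-class capture strength."""
        if cd == "CD45":
            return 1.0
        if cd not in self.cells.columns:
            return 0.0
        w = np.zeros(len(self.cells))
        expr = self.cells[cd].to_numpy()
        for name, spec in self.class_specs.items():
            mask = (self.cells["cell_class"] == name).to_numpy()
            w[mask] = spec.expression_strength.get(cd, 1.0)
        return float((expr * w).mean())

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


@dataclass
class FlowResult:
    """Simulated flow-cytometry readout: % positive of CD45+ events."""

    percent_positive: dict[str, float]
    n_events: int

    def __post_init__(self) -> None:
        for cd, v in self.percent_positive.items():
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{cd}: percentage {v} outside [0, 100]")


# ---------------------------------------------------------------------------
# default healthy parameterisation


def _healthy_classes() -> dict[str, CellClassSpec]:
    return {
        "CD4_T": CellClassSpec(
            "CD4_T",
            {"CD45": 1, "CD2": 1, "CD3": 1, "CD4": 1, "CD5": 1, "CD7": 1, "CD38": 0.3},
            {
                "small_lymphocyte": 0.978,
                "large_lymphocyte": 0.018,
                "lobed_lymphocyte": 0.002,
                "granular_lymphocyte": 0.001,
                "granular_lobed_lymphocyte": 0.001,
            },
        ),
        "CD8_T": CellClassSpec(
            "CD8_T",
            {"CD45": 1, "CD2": 1, "CD3": 1, "CD5": 1, "CD7": 1, "CD8": 1, "CD38": 0.3},
            {
                # captured composition on the matched spot at 98% purity:
                # small 74.7, large 0.5, lobed 1.5, granular 22.3, gran-lobed 1.4 (%)
                "small_lymphocyte": 0.74232,
                "large_lymphocyte": 0.00516,
                "lobed_lymphocyte": 0.01546,
                "granular_lymphocyte": 0.22263,
                "granular_lobed_lymphocyte": 0.01443,
            },
        ),
        "NK": CellClassSpec(
            "NK",
            {"CD45": 1, "CD2": 0.8, "CD7": 0.9, "CD16": 1, "CD56": 1, "CD38": 0.5},
            {
                "small_lymphocyte": 0.3235,
                "large_lymphocyte": 0.0049,
                "lobed_lymphocyte": 0.0343,
                "granular_lymphocyte": 0.5912,
                "granular_lobed_lymphocyte": 0.0461,
            },
        ),
        "B": CellClassSpec(
            "B",
            {
                "CD45": 1, "CD19": 1, "CD20": 1, "CD21": 0.9, "CD22": 1,
                "CD23": 0.1, "HLA-DR": 1, "IgM": 0.6,
            },
            {
                # B cells carry no granular or radially segmented morphotypes
                "small_lymphocyte": 0.9490,
                "large_lymphocyte": 0.0505,
                "binuclear_lymphocyte": 0.0005,
            },
        ),
        "monocyte": CellClassSpec(
            "monocyte",
            {
                "CD45": 1, "CD4": 0.30, "CD14": 1, "CD16": 0.09, "CD33": 1,
                "CD11c": 1, "CD64": 1, "CD15": 0.3, "HLA-DR": 1, "CD38": 0.5,
            },
            {"monocyte": 0.999, "small_lymphocyte": 0.001},
        ),
    }


#: disease clone profiles: CD-marker sets per chronic B-cell neoplasm
DISEASE_CLONES: dict[str, CellClassSpec] = {
    "CLL": CellClassSpec(
        "clone_CLL",
        {"CD45": 1, "CD19": 1, "CD20": 1, "CD22": 1, "CD5": 1, "CD23": 1, "CD43": 0.8,
         "HLA-DR": 1},
        {"small_lymphocyte": 1.0},
        expression_strength={"CD20": 0.25, "CD22": 0.25},
    ),
    "HCL": CellClassSpec(
        "clone_HCL",
        {"CD45": 1, "CD19": 1, "CD20": 1, "CD22": 1, "CD25": 1, "CD11c": 1, "CD103": 1,
         "HLA-DR": 1},
        {"hairy_cell": 1.0},
        trap_prob=1.0,
    ),
    "SMZL": CellClassSpec(
        "clone_SMZL",
        {"CD45": 1, "CD19": 1, "CD20": 1, "CD22": 1, "CD25": 1, "HLA-DR": 1, "IgM": 1},
        {"small_lymphocyte": 0.7, "large_lymphocyte": 0.3},
    ),
    "MCL": CellClassSpec(
        "clone_MCL",
        {"CD45": 1, "CD19": 1, "CD20": 1, "CD22": 1, "CD5": 1, "HLA-DR": 1},
        {"small_lymphocyte": 1.0},
    ),
    "FL": CellClassSpec(
        "clone_FL",
        {"CD45": 1, "CD19": 1, "CD20": 1, "CD22": 1, "CD10": 1, "HLA-DR": 1},
        {"small_lymphocyte": 1.0},
    ),
}

DISEASES = tuple(DISEASE_CLONES) + ("normal",)


@dataclass
class CohortParams:
    """Parameter set for the healthy-donor generator."""

    classes: dict[str, CellClassSpec] = dc_field(default_factory=_healthy_classes)
    fraction_mean: dict[str, float] = dc_field(
        default_factory=lambda: {
            "CD4_T": 0.47, "CD8_T": 0.23, "NK": 0.05, "B": 0.12, "monocyte": 0.13,
        }
    )
    # component SDs chosen so the realised (post-renormalisation) donor
    # spread matches flow reference intervals: CD3 ~7, CD4 ~7, CD8 ~7,
    # CD19 ~5 percentage points
    fraction_sd: dict[str, float] = dc_field(
        default_factory=lambda: {
            "CD4_T": 0.125, "CD8_T": 0.075, "NK": 0.025, "B": 0.050, "monocyte": 0.045,
        }
    )
    n_cells: int = 20000
    suspension_concentration: float = 8.0

    def to_dict(self) -> dict:
        return {
            "classes": {
                k: {
                    "marker_expression": dict(v.marker_expression),
                    "morphotype_mixture": dict(v.morphotype_mixture),
                    "size_params": list(v.size_params) if v.size_params else None,
                    "expression_strength": dict(v.expression_strength),
                    "trap_prob": v.trap_prob,
                }
                for k, v in self.classes.items()
            },
            "fraction_mean": dict(self.fraction_mean),
            "fraction_sd": dict(self.fraction_sd),
            "n_cells": self.n_cells,
            "suspension_concentration": self.suspension_concentration,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortParams":
        classes = {
            k: CellClassSpec(
                k,
                v["marker_expression"],
                v["morphotype_mixture"],
                tuple(v["size_params"]) if v.get("size_params") else None,
                v.get("expression_strength", {}),
                v.get("trap_prob", 0.0),
            )
            for k, v in d["classes"].items()
        }
        return cls(
            classes=classes,
            fraction_mean=d["fraction_mean"],
            fraction_sd=d["fraction_sd"],
            n_cells=d.get("n_cells", 20000),
            suspension_concentration=d.get("suspension_concentration", 8.0),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "CohortParams":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# operations

_MAX_RETRIES = 100


def _draw_fractions(params: CohortParams, rng: np.random.Generator) -> dict[str, float]:
    names = list(params.fraction_mean)
    for _ in range(_MAX_RETRIES):
        draws = np.array(
            [rng.normal(params.fraction_mean[n], params.fraction_sd.get(n, 0.0)) for n in names]
        )
        if (draws > 0).all():
            draws /= draws.sum()
            return dict(zip(names, draws))
    raise RuntimeError("could not draw a valid (positive) class-fraction vector")


def _realize_roster(
    fractions: dict[str, float],
    classes: dict[str, CellClassSpec],
    n_cells: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    from .geometry import MORPHOTYPE_GEOMETRY

    names = list(fractions)
    p = np.array([fractions[n] for n in names])
    counts = rng.multinomial(n_cells, p)
    markers = sorted({cd for s in classes.values() for cd in s.marker_expression})
    blocks = []
    for name, count in zip(names, counts):
        if count == 0:
            continue
        spec = classes[name]
        mts = list(spec.morphotype_mixture)
        mt_idx = rng.choice(len(mts), size=count, p=list(spec.morphotype_mixture.values()))
        morphs = np.array(mts, dtype=object)[mt_idx]
        if spec.size_params is not None:
            mu, sd = spec.size_params
            diam = np.clip(rng.normal(mu, sd, count), 0.5 * mu, 1.5 * mu)
        else:
            lo = np.array([MORPHOTYPE_GEOMETRY[m].diameter_um[0] for m in morphs])
            hi = np.array([MORPHOTYPE_GEOMETRY[m].diameter_um[1] for m in morphs])
            diam = rng.uniform(lo, hi)
        block = {
            "cell_class": np.full(count, name, dtype=object),
            "morphotype": morphs,
            "diameter_um": diam,
            "trap_pos": rng.random(count) < spec.trap_prob,
        }
        for cd in markers:
            pr = spec.marker_expression.get(cd, 0.0)
            block[cd] = rng.random(count) < pr if pr > 0 else np.zeros(count, dtype=bool)
        blocks.append(pd.DataFrame(block))
    return pd.concat(blocks, ignore_index=True)


def build_healthy_profile(params: CohortParams | None = None, seed: int = 0) -> DonorTruth:
    """Generate one healthy donor: class fractions, then a realised roster."""
    params = params if params is not None else CohortParams()
    rng = np.random.default_rng(seed)
    fractions = _draw_fractions(params, rng)
    cells = _realize_roster(fractions, params.classes, params.n_cells, rng)
    return DonorTruth(fractions, dict(params.classes), cells, params.suspension_concentration)


def build_disease_profile(
    disease: str,
    clone_fraction: float,
    seed: int = 0,
    params: CohortParams | None = None,
) -> DonorTruth:
    """Healthy background plus a leukemic clone at the given PBMC fraction."""
    if disease not in DISEASES:
        raise ValueError(f"unknown disease {disease!r}; allowed: {', '.join(DISEASES)}")
    if not 0.0 <= clone_fraction <= 1.0:
        raise ValueError("clone_fraction must be in [0, 1]")
    params = params if params is not None else CohortParams()
    if disease == "normal" or clone_fraction == 0.0:
        return build_healthy_profile(params, seed)
    clone = copy.deepcopy(DISEASE_CLONES[disease])
    rng = np.random.default_rng(seed)
    fractions = _draw_fractions(params, rng)
    fractions = {k: v * (1.0 - clone_fraction) for k, v in fractions.items()}
    fractions[clone.name] = clone_fraction
    classes = dict(params.classes)
    classes[clone.name] = clone
    cells = _realize_roster(fractions, classes, params.n_cells, rng)
    return DonorTruth(fractions, classes, cells, params.suspension_concentration)


def simulate_flow(
    truth: DonorTruth,
    n_events: int = 10_000,
    seed: int = 0,
    cds: list[str] | None = None,
) -> FlowResult:
    """Flow cytometry as binomial sampling of true marker frequencies.

    Events are gated on CD45 (every PBMC in the roster is CD45+), so the
    percentage positive for each CD is a binomial draw at the roster's
    marker frequency out of ``n_events`` events.
    """
    if len(truth.cells) == 0:
        raise ValueError("empty roster")
    if n_events < 100:
        raise ValueError("n_events must be >= 100")
    rng = np.random.default_rng(seed)
    cds = cds if cds is not None else truth.marker_columns
    out = {}
    for cd in cds:
        p = truth.marker_fraction(cd)
        out[cd] = 100.0 * rng.binomial(n_events, p) / n_events
    return FlowResult(out, n_events)


def cohort(
    n_donors: int,
    seed: int,
    params: CohortParams | None = None,
    disease: str = "normal",
    clone_fraction: float = 0.0,
) -> list[DonorTruth]:
    """A cohort of donors with per-donor child seeds derived from one seed."""
    return [
        build_disease_profile(disease, clone_fraction, seed=(seed * 1000 + i) % (2**31 - 1),
                              params=params)
        for i in range(n_donors)
    ]
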