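"""Microarray panel map: spot grid, CD target per spot, controls.

The default panel mirrors the full antibody list of the assay (34 anti-CD /
anti-Ig spots plus a mouse-IgG isotype negative control) on a 5 x 7 grid.
Anti-CD45 is the positive control: it binds every leukocyte and anchors the
density normalisation; the mouse-IgG spot feeds the background-binding
check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

DEFAULT_TARGETS = [
    "CD1a", "CD2", "CD3", "CD4", "CD5", "CD7", "CD8",
    "CD10", "CD11c", "CD14", "CD15", "CD16", "CD19", "CD20",
    "CD21", "CD22", "CD23", "CD25", "CD33", "CD38", "CD41a",
    "CD43", "CD45", "CD45RA", "CD45RO", "CD56", "CD61", "CD64",
    "CD103", "HLA-DR", "IgG-kappa", "IgG-lambda", "IgM", "CD117", "mIgG",
]

#: default matched-capture purities (fraction of captured cells that express
#: the spot's target).  The four measured spots carry their reported values;
#: every other spot uses the panel-wide default 0.96.
DEFAULT_PURITY = {"CD3": 0.97, "CD4": 0.97, "CD8": 0.98, "CD19": 0.93}


@dataclass(frozen=True)
class Spot:
    row: int
    col: int
    target: str  # CD name, or "mIgG" for the isotype control

    @property
    def is_negative_control(self) -> bool:
        return self.target == "mIgG"


@dataclass
class PanelConfig:
    """Spot grid with per-spot CD targets and control designations."""

    rows: int
    cols: int
    spots: list[Spot]
    spot_diameter_mm: float = 1.5
    positive_control: str = "CD45"

    def __post_init__(self) -> None:
        seen_pos = set()
        for s in self.spots:
            if not (0 <= s.row < self.rows and 0 <= s.col < self.cols):
                raise ValueError(f"spot {s.target} at ({s.row},{s.col}) outside grid")
            if (s.row, s.col) in seen_pos:
                raise ValueError(f"duplicate grid position ({s.row},{s.col})")
            seen_pos.add((s.row, s.col))
        n_pos = sum(1 for s in self.spots if s.target == self.positive_control)
        if n_pos != 1:
            raise ValueError(
                f"panel needs exactly one {self.positive_control} positive-control spot"
            )
        if self.spot_diameter_mm <= 0:
            raise ValueError("spot diameter must be positive")

    @property
    def spot_area_mm2(self) -> float:
        return float(np.pi * (self.spot_diameter_mm / 2.0) ** 2)

    @property
    def targets(self) -> list[str]:
        return [s.target for s in self.spots]

    def to_dict(self) -> dict:
        return {
            "rows": self.rows,
            "cols": self.cols,
            "spot_diameter_mm": self.spot_diameter_mm,
            "positive_control": self.positive_control,
            "spots": [{"row": s.row, "col": s.col, "target": s.target} for s in self.spots],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_panel(spot_diameter_mm: float = 1.5) -> PanelConfig:
    """The shipped 35-spot panel (5 x 7 grid, anti-CD45 positive control)."""
    spots = [
        Spot(i // 7, i % 7, t) for i, t in enumerate(DEFAULT_TARGETS)
    ]
    return PanelConfig(5, 7, spots, spot_diameter_mm=spot_diameter_mm)


def load_panel(path) -> PanelConfig:
    """Load and validate a panel map from YAML/JSON."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    spots = [Spot(s["row"], s["col"], s["target"]) for s in d["spots"]]
    return PanelConfig(
        rows=d["rows"],
        cols=d["cols"],
        spots=spots,
        spot_diameter_mm=d.get("spot_diameter_mm", 1.5),
        positive_control=d.get("positive_control", "CD45"),
    )
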