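"""Disease binding-pattern signatures for chronic B-cell neoplasms.

Each signature states the expected direction of the CD45-normalised
binding density per CD relative to the healthy reference interval:
``up`` / ``down`` (flagged outside the interval in that direction),
``normal`` (inside), or ``variable`` (observed but too erratic to score —
e.g. CD20/CD22 in CLL, where reduced antigen density weakens capture).
Scoring counts matched non-variable expectations over applicable ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

EXPECTATIONS = ("up", "down", "variable", "normal")

_T_DOWN = {"CD2": "down", "CD3": "down", "CD4": "down", "CD7": "down", "CD8": "down"}


@dataclass
class DiseaseSignature:
    disease: str
    expectations: dict[str, str] = field(default_factory=dict)
    morphotype_evidence: str | None = None  # morphotype expected among captured cells

    def __post_init__(self) -> None:
        for cd, e in self.expectations.items():
            if e not in EXPECTATIONS:
                raise ValueError(f"{self.disease}: unknown expectation {e!r} for {cd}")
        if self.disease != "normal" and all(
            e == "normal" for e in self.expectations.values()
        ):
            raise ValueError(f"{self.disease}: signature has no non-normal expectation")


DEFAULT_SIGNATURES: list[DiseaseSignature] = [
    DiseaseSignature(
        "CLL",
        {**_T_DOWN, "CD19": "up", "CD23": "up", "CD5": "variable",
         "CD20": "variable", "CD22": "variable"},
    ),
    DiseaseSignature(
        "HCL",
        {**_T_DOWN, "CD19": "up", "CD20": "up", "CD22": "up", "CD25": "up",
         "CD11c": "up", "CD103": "up", "CD5": "down", "CD23": "normal"},
        morphotype_evidence="hairy_cell",
    ),
    DiseaseSignature(
        "SMZL",
        {**_T_DOWN, "CD19": "up", "CD20": "up", "CD22": "up", "CD25": "up",
         "CD5": "down", "CD23": "normal", "CD11c": "normal", "CD103": "normal"},
    ),
    DiseaseSignature(
        "MCL",
        {**_T_DOWN, "CD19": "up", "CD20": "up", "CD22": "up", "CD5": "up",
         "CD23": "normal"},
    ),
    DiseaseSignature(
        "FL",
        {**_T_DOWN, "CD19": "up", "CD20": "up", "CD22": "up", "CD10": "up",
         "CD5": "down"},
    ),
]


def save_signatures(signatures: list[DiseaseSignature], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            [
                {
                    "disease": s.disease,
                    "expectations": dict(s.expectations),
                    "morphotype_evidence": s.morphotype_evidence,
                }
                for s in signatures
            ],
            fh,
            sort_keys=False,
        )


def load_signatures(path) -> list[DiseaseSignature]:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [
        DiseaseSignature(d["disease"], d["expectations"], d.get("morphotype_evidence"))
        for d in raw
    ]
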