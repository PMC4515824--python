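"""Pipeline orchestration: simulate -> capture -> image -> quantify -> diagnose.

Each stage writes plain tabular artifacts (CSV/JSON, TIFF for images) into
the run directory, and a manifest records the seed, configuration hash and
every produced file, so re-running a manifest reproduces all tabular
outputs byte for byte.

The imaging stage is optional ("tables-only" runs quantify directly from
simulated densities); when enabled it renders the configured spots as
fields, segments them, and derives the profile from detection counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .capture import CaptureParams, SaturationParams, simulate_capture
from .cohort import CohortParams, build_disease_profile
from .morphometry import measure_all
from .panel import PanelConfig, default_panel
from .quantify import (
    profile_from_capture,
    reference_ranges,
    suggest_diagnosis,
)
from .render import RenderParams, render_field, save_tiff
from .segment import segment_cells

log = logging.getLogger("leukopan")

STAGES = ("simulate", "capture", "image", "quantify", "diagnose")


@dataclass
class RunConfig:
    seed: int
    outdir: str | Path = "leukopan_run"
    disease: str = "normal"
    clone_fraction: float = 0.0
    stages: tuple[str, ...] = STAGES
    imaging: bool = False
    image_spots: tuple[str, ...] = ("CD45", "CD14")
    cohort: CohortParams = field(default_factory=CohortParams)
    capture: CaptureParams = field(default_factory=CaptureParams)
    saturation: SaturationParams = field(default_factory=SaturationParams)
    render: RenderParams = field(default_factory=RenderParams)
    panel: PanelConfig = field(default_factory=default_panel)
    n_reference_donors: int = 30
    image_field_mm: float = 0.6

    def __post_init__(self) -> None:
        idx = [STAGES.index(s) for s in self.stages if s in STAGES]
        if len(idx) != len(self.stages) or idx != sorted(idx):
            raise ValueError(f"stages must be an ordered subset of {STAGES}")

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed,
            "disease": self.disease,
            "clone_fraction": self.clone_fraction,
            "stages": list(self.stages),
            "imaging": self.imaging,
            "cohort": self.cohort.to_dict(),
            "panel": self.panel.to_dict(),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stage prefix; returns the manifest dict."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": list(config.stages),
        "files": [],
    }

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest["files"].append(name)
        return path

    truth = capture = profile = None
    try:
        for stage in config.stages:
            log.info("stage %s (seed %d)", stage, config.seed)
            if stage == "simulate":
                truth = build_disease_profile(
                    config.disease, config.clone_fraction, seed=config.seed,
                    params=config.cohort,
                )
                emit("roster.csv", truth.to_csv)
            elif stage == "capture":
                assert truth is not None, "simulate stage required first"
                capture = simulate_capture(
                    truth, config.panel, config.capture, config.saturation,
                    seed=config.seed + 1,
                )
                emit("densities.csv",
                     lambda p: capture.density_table().to_csv(p, header=True))
            elif stage == "image" and config.imaging:
                assert capture is not None
                frames = []
                for i, spot in enumerate(config.image_spots):
                    roster = capture.spots[spot].cells
                    dens = capture.spots[spot].density
                    side = config.image_field_mm
                    n = int(round(dens * side * side))
                    sub = roster.sample(n=min(n, len(roster)),
                                        random_state=config.seed + 7 + i)
                    img = render_field(sub, side, side, config.render,
                                       seed=config.seed + 13 + i)
                    emit(f"spot_{spot}.tiff", lambda p, im=img: save_tiff(im, p))
                    emit(f"spot_{spot}_truth.csv",
                         lambda p, im=img: im.ground_truth.assign(
                             cleft_depths=im.ground_truth.cleft_depths.map(list)
                         ).to_csv(p, index=False))
                    seg = segment_cells(img)
                    cells = measure_all(seg)
                    cells["antibody"] = spot
                    frames.append(cells)
                if frames:
                    allcells = pd.concat(frames, ignore_index=True)
                    emit("cells.csv", lambda p: allcells.to_csv(p, index=False))
            elif stage == "quantify":
                assert capture is not None
                profile = profile_from_capture(capture, seed=config.seed + 2)
                emit("profile.csv", lambda p: pd.DataFrame(
                    {"density": profile.raw, "normalized_pct": profile.normalized}
                ).to_csv(p))
            elif stage == "diagnose":
                assert profile is not None
                ref_profiles = []
                for i in range(config.n_reference_donors):
                    child = (config.seed * 977 + 31 * i + 1) % (2**31 - 1)
                    t = build_disease_profile("normal", 0.0, seed=child,
                                              params=config.cohort)
                    c = simulate_capture(t, config.panel, config.capture,
                                         config.saturation, seed=child + 1)
                    ref_profiles.append(profile_from_capture(c, seed=child + 2))
                ranges = reference_ranges(ref_profiles)
                emit("reference_ranges.csv", lambda p: ranges.to_csv(p))
                sugg = suggest_diagnosis(profile, ranges)
                report = {
                    "seed": config.seed,
                    "disease_simulated": config.disease,
                    "suggestions": [
                        {
                            "disease": s.disease,
                            "score": round(s.score, 4),
                            "matched": s.matched,
                            "mismatched": s.mismatched,
                        }
                        for s in sugg
                    ],
                }
                emit("report.json",
                     lambda p: p.write_text(json.dumps(report, indent=2)))
    except Exception as exc:  # annotate the failing stage, keep partial output
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
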