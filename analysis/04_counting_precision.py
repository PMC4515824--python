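#!/usr/bin/env python
"""Replicate-field counting precision and spot uniformity.

Renders a spot region at ~4000 cells/mm^2, counts three x200-like fields
of ~1000 cells by segmentation, and reports the relative SD of the density
estimate.  Also demonstrates the edge-to-edge radial profile: a uniform
spot vs one rendered with the "donut" drying artifact.

Writes results/counting_precision.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from leukopan.render import RenderParams, render_spot
from leukopan.segment import radial_profile, segment_cells
from leukopan.study import counting_precision_study

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()
args.results.mkdir(exist_ok=True)

est, counts = counting_precision_study(seed=args.seed)
pd.DataFrame({"field": range(1, 4), "count": counts}).to_csv(
    args.results / "counting_precision.csv", index=False
)
print(f"field counts: {counts}")
print(f"density {est.density:.0f} cells/mm^2, relative SD {est.relative_sd_percent:.1f}%")

roster = pd.DataFrame({"morphotype": ["small_lymphocyte"] * 450, "diameter_um": np.nan})
for mode in ("uniform", "donut"):
    img = render_spot(roster, 0.4, RenderParams(pixel_scale_um=0.3, mode=mode),
                      seed=args.seed)
    prof = radial_profile(segment_cells(img), img.spot_center_um, img.spot_diameter_um)
    print(f"{mode} spot: edge/centre density ratio {prof.uniformity_ratio:.2f}"
          f"{' (donut flagged)' if prof.is_donut else ''}")
print("-> detection-based counting reproduces the few-percent replicate "
      "precision of manual field counting and spots the drying artifact.")
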