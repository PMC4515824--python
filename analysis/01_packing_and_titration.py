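#!/usr/bin/env python
"""Packing bound and shared-x0 saturation fit.

Checks the geometric bound on bound-cell density (one cell per d x d
lattice site) at the diameters relevant for lymphocytes, then fits the
saturation model y = a * (1 - exp(-x/x0)) globally (shared x0) to noisy
synthetic titrations of the anti-CD45/CD3/CD19 spots.

Writes results/titration_fit.csv and prints the recovered parameters.
"""

import argparse
from pathlib import Path

import pandas as pd

from leukopan.capture import packing_limit
from leukopan.study import titration_study

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()
args.results.mkdir(exist_ok=True)

print("geometric packing bound:")
for d in (11.0, 12.0, 15.0):
    print(f"  {d:.0f} um cells -> {packing_limit(d)} cells/mm^2")

df = titration_study(seed=args.seed, n_replicates=20, noise=0.05)
df.to_csv(args.results / "titration_fit.csv", index=False)
print(
    f"\nglobal fit over {len(df)} noisy replicates (true x0=2.4):\n"
    f"  x0   = {df.x0.mean():.2f} +- {df.x0.std(ddof=1):.2f}\n"
    f"  a_CD45 = {df.a_CD45.mean():.0f} +- {df.a_CD45.std(ddof=1):.0f}\n"
    f"  a_CD3  = {df.a_CD3.mean():.0f},  a_CD19 = {df.a_CD19.mean():.0f}"
)
print("-> the shared characteristic concentration is identifiable from "
      "three spot series; density ratios are concentration-invariant.")
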