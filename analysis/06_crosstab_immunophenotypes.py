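#!/usr/bin/env python
"""Morphotype x antibody cross-tab and immunophenotype calls, end to end.

Simulates healthy donors, captures them on the array, renders the
anti-CD14/CD8/CD19 spots, segments and classifies every cell, and
cross-tabulates morphotypes by capturing antibody.  Then infers the
immunophenotype of granular lymphocytes from which antibodies captured
them.

Writes results/crosstab_mean.csv / results/crosstab_sem.csv.
"""

import argparse
from pathlib import Path

from leukopan.quantify import call_immunophenotype
from leukopan.study import crosstab_study

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--donors", type=int, default=4)
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()
args.results.mkdir(exist_ok=True)

xt = crosstab_study(seed=args.seed, n_donors=args.donors,
                    spots=("CD14", "CD8", "CD19"), min_cells=450)
xt.mean_percent.round(2).to_csv(args.results / "crosstab_mean.csv")
xt.sem_percent.round(2).to_csv(args.results / "crosstab_sem.csv")
print("mean % of each morphotype among captured cells:")
print(xt.mean_percent.round(1).to_string())

call = call_immunophenotype(xt, "granular_lymphocyte")
print("\ngranular-lymphocyte immunophenotype calls:")
for ab, verdict in call.calls.items():
    print(f"  {ab}: {verdict} ({call.fractions[ab]:.1f}%)")
print("-> granular lymphocytes are captured by anti-CD8 but never by "
      "anti-CD19: a cytotoxic/NK, not B, phenotype.")
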