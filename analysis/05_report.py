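#!/usr/bin/env python
"""Summary report: published-table means vs this run's synthetic study.

The published per-drug heritability tables ship with the package; their
column means are the abstract-level summaries (PK parent/metabolite
0.15/0.18 for FBZ and 0.31/0.40 for FLU; across-time 0.27/0.60 and
0.14/0.44; pooled PK 0.23/0.27 and across-time parent 0.20 /
metabolite 0.51). This script recomputes them and sets the current
synthetic-study estimates beside them.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from pkherit import mean_heritability
from pkherit.published import PK_TABLE, TIME_TABLE

ap = argparse.ArgumentParser()
ap.add_argument("--results", type=Path, default=Path("results"))
args = ap.parse_args()

summary = {"published": {}, "synthetic_study": {}}
for table, tag in ((PK_TABLE, "pk"), (TIME_TABLE, "time")):
    for drug in ("FBZ", "FLU"):
        for compound in ("parent", "metabolite"):
            summary["published"][f"{tag}_{drug}_{compound}"] = mean_heritability(
                table, {"drug": drug, "compound": compound})
    for compound in ("parent", "metabolite"):
        summary["published"][f"{tag}_pooled_{compound}"] = mean_heritability(
            table, {"compound": compound})

for name, tag in (("heritability_pk.csv", "pk"), ("heritability_time.csv", "time")):
    rep = pd.read_csv(args.results / name)
    for drug in ("FBZ", "FLU"):
        for compound in ("parent", "metabolite"):
            try:
                summary["synthetic_study"][f"{tag}_{drug}_{compound}"] = \
                    mean_heritability(rep, {"drug": drug, "compound": compound})
            except ValueError:
                pass

with open(args.results / "summary.json", "w") as fh:
    json.dump(summary, fh, indent=2)
print(json.dumps(summary, indent=2))
print("wrote summary.json")
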