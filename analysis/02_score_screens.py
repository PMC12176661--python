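#!/usr/bin/env python
"""Score the simulated screens: filters, lfc, anchor scaling, selective z, hits.

Reads the tables written by 01_simulate_screens.py and writes the per-gene
score table, rank-plot table, control-vs-treated scatter table and a JSON run
summary under ``results/02_scores/<preset>/``.
"""

import json
from pathlib import Path

from crisprsel import RunConfig, run_pipeline

IN = Path("results/01_screens")
OUT = Path("results/02_scores")

for name in ("lowdose", "highdose"):
    cfg = RunConfig(
        counts=str(IN / name / "counts.tsv"),
        annotation=str(IN / name / "annotation.tsv"),
        design={"initial": "initial", "control": ["dmso"], "treated": ["drug"]},
        seed=7,
        outdir=str(OUT / name),
    )
    out = run_pipeline(cfg)
    s = out["summary"]
    print(f"{name}: scored {s['n_genes_scored']} genes")
    print(f"  anchors: {json.dumps(s['anchors'])}")
    print(f"  categories: {s['categories']}")
    print(f"  top depleted: {', '.join(s['top_hits']['top_depleted'][:5])} ...")
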