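#!/usr/bin/env python
"""Null calibration of the selective-essentiality z-score.

Simulates 20 screens with no planted drug-selective effects (only the shared
core-essential depletion and biological arm noise) and measures how often
|z| >= 2, which for a well-calibrated score should match the two-sided normal
tail (~4.55%). Writes ``results/04_null_calibration.json``.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np
from scipy.stats import norm

from crisprsel import preset, score_simulated_screen

base = preset("lowdose", n_selective=0, n_sensitizing=0)
n_total = n_exceed = 0
for seed in range(20):
    cfg = dataclasses.replace(base, seed=100 + seed)
    result, _ = score_simulated_screen(cfg)
    z = result.gene_table["selective_z"]
    n_total += len(z)
    n_exceed += int((z.abs() >= 2).sum())

p_expected = 2 * norm.sf(2.0)
fraction = n_exceed / n_total
report = {
    "n_genes_total": n_total,
    "n_exceeding_2": n_exceed,
    "fraction_abs_z_ge_2": fraction,
    "normal_tail_expectation": p_expected,
    "binomial_sd": float(np.sqrt(p_expected * (1 - p_expected) / n_total)),
}
print(
    f"|z|>=2 in {n_exceed}/{n_total} genes = {fraction:.4f} "
    f"(normal expectation {p_expected:.4f})"
)
out = Path("results/04_null_calibration.json")
out.parent.mkdir(parents=True, exist_ok=True)
out.write_text(json.dumps(report, indent=2) + "\n")
print(f"wrote {out}")
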