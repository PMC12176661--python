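#!/usr/bin/env python
"""Simulate the two screen designs (moderate-dose and high-dose) with ground truth.

Writes count, annotation and truth tables for each design under
``results/01_screens/<preset>/`` so the later steps can score them.
"""

from pathlib import Path

from crisprsel import make_fixture

SEED = 7
OUT = Path("results/01_screens")

for name in ("lowdose", "highdose"):
    paths = make_fixture(seed=SEED, size=name, outdir=OUT / name)
    print(f"{name}: wrote {len(paths)} files under {OUT / name}")
    for key, p in paths.items():
        print(f"  {key}: {p}")
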