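#!/usr/bin/env python
"""Fold a synthetic panel of structured and unstructured RNAs.

Generates 20 perfect hairpins and 20 length-matched AU-rich random sequences
(200 nt), runs the full ensemble analysis on each, and writes the per-RNA
table to results/01_ensemble_panel.tsv.  The headline finding: hairpins sit
at NED ~ 1e-4 while AU-rich sequences sit at NED ~ 0.2-0.3, i.e. the two
condensate-morphology classes are separated by orders of magnitude in
ensemble diversity.
"""

import numpy as np
import pandas as pd

from meshrna.energy import STACKING
from meshrna.ensemble import find_ldrs, fold
from meshrna.synth import gen_hairpin, gen_unstructured

SEED = 0
N_SEEDS = 20
LENGTH = 200

rows = []
for k in range(N_SEEDS):
    for kind, seq in (
        ("hairpin", gen_hairpin((LENGTH - 4) // 2, 4, 1.0, seed=SEED + k)),
        ("unstructured", gen_unstructured(LENGTH, 0.8, seed=SEED + k)),
    ):
        s = fold(seq, STACKING)
        ldrs = find_ldrs(s.unpaired, tau=0.5, min_ldr_length=30)
        rows.append(
            dict(id=seq.id, kind=kind, length=seq.n, ned=round(s.ned, 6),
                 ensemble_diversity=round(s.ensemble_diversity, 3),
                 mfe_kcal_mol=round(s.mfe_energy, 2), n_ldrs=len(ldrs))
        )

table = pd.DataFrame(rows)
table.to_csv("results/01_ensemble_panel.tsv", sep="\t", index=False)
med = table.groupby("kind").ned.median()
print(table.groupby("kind")[["ned", "n_ldrs"]].median())
print(
    f"\nmedian NED: hairpin {med['hairpin']:.5f} vs unstructured "
    f"{med['unstructured']:.5f} -> unstructured RNAs are "
    f"{med['unstructured'] / max(med['hairpin'], 1e-9):.0f}x more heterogeneous"
)
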