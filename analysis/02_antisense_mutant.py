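#!/usr/bin/env python
"""Antisense-insertion loss-of-function analysis.

For 20 seeded AU-rich 200-nt RNAs, inserts two 15-nt segments perfectly
complementary to upstream donor windows (leaving every AUUUA element intact)
and compares the NED of mutant vs wild type.  Writes
results/02_antisense_mutants.tsv.  Finding: forcing strong local base-pairing
lowers the median NED — the in-silico analogue of converting a network-forming
3'UTR into a sphere-forming one.
"""

import numpy as np
import pandas as pd

from meshrna.energy import STACKING
from meshrna.ensemble import fold
from meshrna.features import count_ares
from meshrna.synth import find_antisense_insertion, gen_unstructured

SEED = 0
N_SEEDS = 20
LENGTH = 200

rows = []
for k in range(N_SEEDS):
    wt = gen_unstructured(LENGTH, 0.8, seed=SEED + k)
    mut = find_antisense_insertion(wt, insert_len=15, copies=2, seed=SEED + k)
    ned_wt = fold(wt, STACKING).ned
    ned_mut = fold(mut, STACKING).ned
    rows.append(
        dict(seed=SEED + k, ned_wt=round(ned_wt, 5), ned_mut=round(ned_mut, 5),
             delta=round(ned_mut - ned_wt, 5),
             n_are_wt=count_ares(wt), n_are_mut=count_ares(mut))
    )

table = pd.DataFrame(rows)
table.to_csv("results/02_antisense_mutants.tsv", sep="\t", index=False)
assert (table.n_are_wt == table.n_are_mut).all()
print(table.describe().loc[["50%", "mean"]])
print(
    f"\nmedian NED: wild type {table.ned_wt.median():.4f} -> "
    f"mutant {table.ned_mut.median():.4f} "
    f"(median paired change {table.delta.median():+.4f}; AREs untouched)"
)
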