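#!/usr/bin/env python
"""Cohort statistics and NED-threshold classification on a synthetic cohort.

Generates an initial (19 sphere + 28 network) and a validation (10 + 14)
cohort with the calibrated NED and length shifts, runs the full
reproduce-stats panel (Mann-Whitney Z per feature, classifier accuracy,
quartile checks), and writes results/03_cohort_stats.txt.  If a real
per-RNA source-data TSV is passed as argv[1], the same panel is computed on
it instead.
"""

import sys

import pandas as pd

from meshrna.config import DEFAULTS
from meshrna.pipeline import cmd_reproduce_stats
from meshrna.synth import CohortSpec, gen_cohort

cfg = dict(DEFAULTS)
if len(sys.argv) > 1:
    table = sys.argv[1]
    source = table
else:
    initial = gen_cohort(CohortSpec(seed=11), cohort="initial")
    validation = gen_cohort(
        CohortSpec(n_sphere=10, n_network=14, seed=12), cohort="validation"
    )
    table = pd.concat([initial, validation], ignore_index=True)
    source = "synthetic cohort (seeds 11/12)"

report = cmd_reproduce_stats(table, cfg)
text = f"# source: {source}\n" + report.to_text(cfg)
with open("results/03_cohort_stats.txt", "w") as fh:
    fh.write(text)
print(text)
print(
    f"NED separates the morphology groups (z = "
    f"{report.comparisons.set_index('panel').loc['ned_initial', 'z']}), and the "
    f"dual-threshold rule calls {report.n_correct}/{report.n_validation} "
    "validation RNAs correctly."
)
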