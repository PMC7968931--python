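#!/usr/bin/env python
"""CLIP-tag counting over synthetic 3'UTR tracks.

Generates 150 synthetic UTRs with two CLIP-peak datasets (20% of UTRs
10-fold enriched), counts tags per UTR under the union-of-tags rule, bins
UTRs by union count (0 / 1-4 / >=5), and writes results/05_clip_counts.tsv.
Finding: the top count bin recovers the truth-enriched UTRs with high
precision, i.e. binding-site counting over interval intersections separates
target from non-target UTRs.
"""

import pandas as pd

from meshrna.intervals import count_tags, group_by_count
from meshrna.synth import gen_clip_tracks

utrs, peak_sets, truth = gen_clip_tracks(
    n_utrs=150, enrichment_factor=10.0, enriched_fraction=0.2, seed=0
)
counts = count_tags(utrs, peak_sets, strand_mode="aware")
counts["bin"] = group_by_count(counts["union"], ((0, 0), (1, 4), (5, float("inf"))))
counts["truth_enriched"] = truth.values
counts.reset_index(names="utr").to_csv(
    "results/05_clip_counts.tsv", sep="\t", index=False
)

by_bin = counts.groupby("bin").truth_enriched.agg(["size", "mean"])
print(by_bin)
top = counts[counts["bin"] == ">=5"]
print(
    f"\ntop bin (>=5 union tags): {len(top)} UTRs, "
    f"precision {top.truth_enriched.mean():.2f} for truth-enriched UTRs"
)
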