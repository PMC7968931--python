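# meshrna

Tools for predicting and modelling the RNA-driven morphology of biomolecular
condensates.

Phase-separated RNA–protein condensates are usually spherical, but some —
TIS granules on the endoplasmic reticulum, L-bodies in frog oocytes — form
irregular, mesh-like networks. Whether an mRNA 3′UTR drives a sphere or a
mesh is an intrinsic property of the RNA: largely unstructured RNAs engage in
extensive intermolecular RNA–RNA interactions and act as a condensate
skeleton, while stably folded RNAs stay globular and let droplets fuse.
`meshrna` implements the computational side of that programme for people who
work on RNA condensates and 3′UTR biology: a thermodynamic-ensemble folding
engine, the **normalised ensemble diversity (NED)** statistic and its
dual-threshold morphology classifier, 3′UTR sequence features and CLIP-peak
interval analysis, the supporting rank statistics, and a stochastic model of
multivalent RNA dimerization networks — all exercisable end to end on
synthetic data.

## The statistics at the core

For an RNA of length *n*, the Boltzmann ensemble over all pseudoknot-free
secondary structures is computed with an inside–outside (McCaskill-type)
dynamic programme, giving the partition sum *Z*, base-pair probabilities
*p<sub>ij</sub>*, the MFE structure, and the centroid structure
({(i,j) : p<sub>ij</sub> > ½}). The **ensemble diversity** is the expected
base-pair distance between two independent draws from the ensemble,

&nbsp;&nbsp;&nbsp;&nbsp;*d* = 2 Σ<sub>i&lt;j</sub> p<sub>ij</sub>(1 − p<sub>ij</sub>),

and **NED = d / n**. Low NED means one dominant, stably folded conformation;
high NED means a heterogeneous, largely disordered ensemble. RNAs with
NED > 0.280 are predicted network-forming and NED < 0.265 sphere-forming
(values in the gap are assigned to the nearer threshold by default).
Contiguous stretches of high unpaired probability are reported as large
disordered regions (LDRs).

The folding engine uses a deliberately simplified nearest-neighbour energy
model (stacking bonuses, logarithmic hairpin and linear interior-loop
penalties, Watson–Crick + GU pairs, min hairpin 3 nt) and is verified
against exhaustive structure enumeration to 1e−9; it reproduces the
structured-vs-unstructured contrast, not absolute free energies of the full
Turner parameter set.

Multivalency is modelled two ways: a contiguous antiparallel duplex scanner
between two sequences, and a site-matching simulator in which each molecule
carries dimerization-element sites (e.g. the heterotypic D1a↔D1b pair plus
homotypic D2) that are matched randomly and irreversibly — one site per
molecule yields only dimers, two sites per molecule percolate into a
network-spanning component.

## Worked example

```bash
meshrna demo --quick --seed 2
```

prints (abridged):

```
median_ned_structured   0.00012782189213734335
median_ned_unstructured 0.313587461235799
ned_classifier_accuracy 1.0
two_site_fraction_in_largest 0.49
one_site_largest_component   2
clip_top_bin_precision  1.0
```

Reading: synthetic hairpins sit at NED ≈ 1e−4 while length-matched AU-rich
RNAs sit at ≈ 0.31 — a three-orders-of-magnitude separation, so an NED cut
classifies the two morphology classes perfectly here. In the site-matching
simulation, two-site molecules connect 49% of the (deliberately small,
quick-mode) pool into one network component while one-site molecules never
exceed dimers — at the full 500+500-copy pool of `analysis/04` the median
fraction is 0.862 — and the ≥5-tag CLIP bin contains only truth-enriched
UTRs.

The numbered scripts under `analysis/` run the same analyses at full size and
write tables to `results/`: `01` folds a 20+20 synthetic panel (median NED
0.00008 vs 0.24736), `02` shows that inserting two 15-nt antisense segments
(AU-rich elements untouched) lowers median NED from 0.2474 to 0.2246, `03`
computes the cohort statistics panel (e.g. NED Mann–Whitney z = −5.51,
validation accuracy 22/24 on the synthetic cohort), `04` quantifies the
percolation contrast (median largest-component fraction 0.001 / 0.002 / 0.862
for 0 / 1 / 2 sites), and `05` the CLIP-count recovery (top-bin precision
0.93).

With a real per-RNA source-data table (TSV with gene, cohort, observed
morphology, length, ARE count, GC content, NED — supplementary-style column
names are accepted), the same panel of printed statistics is produced by

```bash
meshrna reproduce-stats your_source_data.tsv
```

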