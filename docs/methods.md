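# Methods

This note documents the models implemented in `meshrna`, the parameter
choices that matter, the numerical machinery, and what the synthetic-data
experiments do and do not establish about real data.

## Secondary-structure ensemble

Structures are pseudoknot-free sets of base pairs over Watson–Crick (AU, UA,
CG, GC) and wobble (GU, UG) pair types, with a minimum hairpin loop of 3 nt.
Two energy models (kcal/mol throughout; temperature default 310.15 K,
RT = 0.0019872·T) are shipped:

* **pairsum** — structure energy is the sum of per-pair energies
  (GC −3.0, AU −2.0, GU −1.0). Every ensemble quantity has a closed form on
  small examples, which makes this the model for exact hand-checked tests and
  the enumeration oracle.
* **stacking** (default for analyses) — a simplified nearest-neighbour model
  defined by the unique loop decomposition of a structure. A pair stacked
  directly on another contributes −(s₁ + s₂) where s is a per-pair-type
  stacking strength (CG/GC 1.6, AU/UA 1.1, GU/UG 0.6), so a GC/GC stack is
  −3.2. A hairpin-closing pair contributes a + b·ln(L/3) (a = 3.5,
  b = 1.5) for loop size L; an interior loop or bulge with side sizes
  (s₁, s₂) contributes a′ + b′·(s₁+s₂) (a′ = 2.0, b′ = 0.3); multiloops and
  the exterior loop are neutral. Stability therefore comes only from helix
  stacking, opposed by loop entropy — the qualitative physics that separates
  stably folded from disordered RNAs.

The **linear** (rather than logarithmic) interior-loop penalty is a
deliberate design choice: a size-additive penalty factorises across the two
loop sides, which reduces the interior-loop terms of both the inside and the
outside recursion to constant-time prefix updates (the whole engine is then
O(n²) cells with O(n) work in the multiloop sums) instead of an explicit
O(n²)-per-cell loop scan. Within the realistic size range (interior loops of
1–30 nt) a linear penalty with slope 0.3 tracks a logarithmic one closely.

These parameters are the package's own; they are *not* the Turner 2004 set,
and absolute energies, probabilities and NED values differ from ViennaRNA's
RNAfold. Parity with RNAfold is an explicit non-goal; what the model must
(and does) reproduce is the contrast between structure classes.

### Partition function and probabilities

The inside pass computes, per segment, the conditional partition function of
a closed pair (hairpin + stack/interior + multiloop terms, the latter via
"at least one/two branch" auxiliary arrays) and the free-segment partition;
the open chain has weight 1, so Zq ≥ 1 always. The outside pass conditions
on the innermost enclosing pair and accumulates the stack, interior-loop
(prefix-decay arrays) and multiloop (bilinear segment-partition forms,
evaluated as matrix–vector products) contexts in order of decreasing span;
p_ij is the product of inside and outside weights over Z.

All arrays carry a per-nucleotide rescaling factor σ = exp(−1.05·E_MFE/(n·RT))
(σ ≥ 1), the standard guard against overflow on long, stable sequences:
probabilities are scale-invariant, and the partition sum is reported as
log Z (exact; the `Zq` accessor raises rather than returning infinity when
exp(log Z) is unrepresentable). Agreement with exhaustive enumeration is
~1e−13 relative on sequences up to 20 nt for both models, against a
tolerance of 1e−9.

### MFE, centroid, diversity, LDRs

The MFE programme mirrors the inside recursion in min-plus algebra with
analogous prefix-min arrays for interior loops. Traceback is deterministic:
at equal energy, "position unpaired" is preferred over "paired", then the
smallest closing partner; interior-loop candidates are re-scanned explicitly
only along the trace path.

The centroid is the set of pairs with p_ij > ½ (two conflicting pairs cannot
both exceed ½, so the result needs no repair). Ensemble diversity is the
expected base-pair distance between two independent ensemble draws,
d = 2·Σ_{i<j} p_ij(1−p_ij); the factor-2 convention is pinned by the
brute-force oracle, which computes the literal probability-weighted double
sum over enumerated structure pairs on small inputs. NED = d/n ∈ [0, 1].

Unpaired probabilities are q_i = 1 − Σ_j p_ij. Large disordered regions
(LDRs) are maximal runs with q_i > τ of at least a minimum length; "large"
is not quantified in the underlying experimental work, so the defaults
τ = 0.5 and 30 nt are package choices, configurable and echoed in output
headers. Sequences longer than 7500 nt are refused by default (the folding
length limit of the original analyses), overridable via `fold.max_length`.

## Morphology classifier

NED > 0.280 → network, NED < 0.265 → sphere. The cut-offs are the published
operating points at which 75% of each experimentally characterised group
falls on the expected side. The classifier never observes morphology labels;
they enter only in evaluation. Values in the open gap (0.265, 0.280) get the
nearer label (exact midpoint → network) under the default `nearest` rule, or
an explicit third label under `indeterminate` (counted incorrect in
accuracy). With lo = hi the rule degenerates to a single cut and the gap rule
is irrelevant by construction.

## Statistics

Pairwise comparisons use the two-sided Mann–Whitney test reported as a Z
statistic: U₁ from midranks, σ tie-corrected, no continuity correction in
the reported default (a continuity flag exists), p from the standard normal.
For n₁+n₂ ≤ 12 an exact permutation p over all group assignments
(P(|U−μ| ≥ |obs|)) is reported alongside. The uncorrected normal p can
deviate from the exact p by ~0.1–0.2 near the null centre because U is
discrete; the continuity-corrected p tracks the exact p within 0.05, which
is the comparison the calibration tests make. Group orientation is fixed —
sphere first — so Z signs are comparable across runs. Kruskal–Wallis
(tie-corrected, χ² with k−1 df) and Pearson's r delegate to scipy; for two
tie-free groups H = Z² is verified numerically. No multiple-testing
correction is applied anywhere.

## Interval analysis

BED3/BED6, 0-based half-open, stranded. A CLIP peak counts for a 3′UTR at
≥ 1 bp overlap (configurable) and matching strand (PAR-CLIP is stranded;
strand-aware is the default, `ignore` available). The union over datasets is
the per-UTR maximum of per-dataset counts — "detected in at least one
dataset"; an alternative that merges overlapping peaks across datasets
before counting is available behind `clip.union_rule=merge`. Count bins
default to 0 / 1–4 / ≥5.

## Multivalency

`duplex_scan` reports the minimum-energy run of ≥ min_len consecutive
allowed pairs between two antiparallel sequences — contiguous only, no
interior loops, so a reverse complement always yields the full-length duplex
and the oracle is trivial. `match_sites` matches compatible free sites
(declared as symmetric element partnerships, e.g. D1a↔D1b heterotypic, D2
homotypic) uniformly at random on distinct molecules, irreversibly, until
exhaustion. This is the simplest model that distinguishes valency: one-site
pools provably cap at dimers, two-site complementary circuits connect the
majority of molecules into one component (median largest-component fraction
0.86 at 500+500 copies). It makes no claim about equilibrium, kinetics, or
condensate geometry; it encodes the connectivity logic of appending two
dimerization elements to a structured RNA.

## Synthetic data: what it emulates, and what it does not

The generators are pure functions of their arguments including the seed
(byte-identical reruns):

* hairpins (stem + A-loop + reverse complement) emulate strong local
  structure; AU-rich i.i.d. sequences (P(A)=P(U)=0.4 by default) emulate
  disordered, network-forming 3′UTRs;
* the antisense mutant inserts reverse-complement copies of upstream donor
  windows (default 2 × 15 nt) downstream, refusing any insertion that would
  split or create an AUUUA element — the explicit constraint of the original
  mutant design; donor and insert positions are free parameters searched
  under a seed;
* cohorts draw NED from truncated normals (0.24 vs 0.31, sd 0.03 —
  straddling the classifier cut-offs), lengths log-normal (medians ~0.9 vs
  ~1.6 kb, network longer), ARE counts Poisson at 5/kb, GC at 0.40 ± 0.05,
  with 19 + 28 RNAs by default;
* CLIP tracks place Poisson peaks (0.5/kb/dataset background) on synthetic
  UTRs, with a 20% subset enriched 10-fold and truth labels returned. At
  these defaults the ≥5-tag bin recovers enriched UTRs with precision > 0.8.

None of this emulates real genomic sequence composition, real 3′UTR length
distributions, transcript isoforms, or RNAfold's energy surface. Passing
tests therefore establish that the *machinery* is correct and that the
*directions* hold under controlled conditions — lower NED for structured
RNAs, NED reduction under antisense insertion, valency-2 percolation —
not that any particular real 3′UTR is classified as in the published
experiments. Reproducing the published cohort statistics requires supplying
the real per-RNA source-data table to `reproduce-stats`, which accepts the
supplementary column naming.

## Problem sizes and runtime choices

Analyses and acceptance checks run at 200 nt × 20 seeds for the NED
experiments, 500 + 500 copies × 20 seeds for percolation, 2000 simulations
for the type-I error and 200 for power — sizes chosen so the entire suite
folds in minutes on one CPU while keeping every comparison far from its
decision boundary (the structured/unstructured NED gap at these sizes is
>1000-fold). Quick mode (`demo --quick`) reduces to 120 nt and smaller
pools.

## Known limitations

No pseudoknots, suboptimal sampling, dangles, or coaxial stacking; absolute
NED values are model-specific (the published transcriptome-wide NED
scale — e.g. tRNA ≈ 0.04, values up to 0.44 — is tied to RNAfold's Turner
parameterisation and is not reproduced here); the duplex scanner ignores
interior loops; the site-matching model is irreversible and
stoichiometry-agnostic beyond copy counts; interval analysis assumes
consistent chromosome naming between tracks.
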