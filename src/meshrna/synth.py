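"""Synthetic-data generators: every input the pipeline needs, from a seed.

The generators emulate the statistical structure of the study inputs rather
than real genomic sequence:

* ``gen_hairpin`` — stem-loop sequences (strong local structure, low NED);
* ``gen_unstructured`` — i.i.d. AU-rich sequences (high conformational
  heterogeneity, high NED);
* ``insert_antisense`` — the antisense-insertion mutant design: insert
  reverse-complement copies of upstream donor windows to force strong local
  base-pairing without touching any AUUUA element;
* ``gen_cohort`` — a two-group per-RNA feature table (sphere vs network
  morphology) with configurable NED / length shifts;
* ``gen_clip_tracks`` — UTR and CLIP-peak BED tracks with configurable
  per-UTR enrichment and known truth labels.

Every generator is a pure function of its arguments including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
import pandas as pd

from .features import ARE_MOTIF, count_ares
from .intervals import GenomicInterval
from .seq import RnaSequence, reverse_complement


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def gen_hairpin(
    stem_len: int, loop_len: int, gc_frac: float = 1.0, seed: int = 0
) -> RnaSequence:
    """A perfect stem-loop: random stem + A-loop + reverse complement."""
    if loop_len < 3:
        raise ValueError("loop_len must be >= 3 (minimum hairpin loop)")
    rng = _rng(seed)
    p = [gc_frac / 2, gc_frac / 2, (1 - gc_frac) / 2, (1 - gc_frac) / 2]
    stem = "".join(rng.choice(list("GCAU"), size=stem_len, p=p))
    residues = stem + "A" * loop_len + reverse_complement(stem)
    return RnaSequence(id=f"hairpin_s{stem_len}_l{loop_len}_seed{seed}", residues=residues)


def gen_unstructured(length: int, au_frac: float = 0.8, seed: int = 0) -> RnaSequence:
    """i.i.d. residues with P(A) = P(U) = au_frac/2 (AU-rich by default)."""
    if not 0.0 <= au_frac <= 1.0:
        raise ValueError("au_frac must be in [0, 1]")
    rng = _rng(seed)
    p = [au_frac / 2, au_frac / 2, (1 - au_frac) / 2, (1 - au_frac) / 2]
    residues = "".join(rng.choice(list("AUGC"), size=length, p=p))
    return RnaSequence(id=f"unstructured_n{length}_seed{seed}", residues=residues)


def _are_spans(residues: str) -> List[Tuple[int, int]]:
    spans = []
    start = 0
    while True:
        k = residues.find(ARE_MOTIF, start)
        if k < 0:
            return spans
        spans.append((k, k + len(ARE_MOTIF)))
        start = k + 1


def insert_antisense(
    seq: RnaSequence,
    donor_start: int,
    insert_pos: int,
    insert_len: int = 15,
    copies: int = 2,
) -> RnaSequence:
    """Insert reverse-complement copies of upstream donor windows downstream.

    Copy c takes the donor window [donor_start + c*insert_len, +insert_len)
    and inserts its reverse complement at ``insert_pos`` (all copies land at
    the same point, consecutively).  The insertion must neither split nor
    create an AUUUA element; violations raise ValueError listing the
    conflicting positions.  ``insert_len = 0`` is the identity.
    """
    if insert_len < 0 or copies < 0:
        raise ValueError("insert_len and copies must be >= 0")
    if insert_len == 0 or copies == 0:
        return seq
    r = seq.residues
    if not (0 <= donor_start and donor_start + copies * insert_len <= len(r)):
        raise ValueError("donor window out of bounds")
    if not (0 <= insert_pos <= len(r)):
        raise ValueError("insert position out of bounds")
    if donor_start <= insert_pos < donor_start + copies * insert_len:
        raise ValueError("insert position lies inside the donor window")
    conflicts = [
        s for (s, e) in _are_spans(r) if s < insert_pos < e
    ]
    if conflicts:
        raise ValueError(
            f"insertion at {insert_pos} would split AUUUA element(s) starting at "
            f"{conflicts}"
        )
    insert = "".join(
        reverse_complement(r[donor_start + c * insert_len : donor_start + (c + 1) * insert_len])
        for c in range(copies)
    )
    out = r[:insert_pos] + insert + r[insert_pos:]
    result = RnaSequence(id=f"{seq.id}_antisense", residues=out)
    before, after = count_ares(seq), count_ares(result)
    if after != before:
        raise ValueError(
            f"insertion changes the AUUUA count ({before} -> {after}); "
            "choose a different donor window or insert position"
        )
    return result


def find_antisense_insertion(
    seq: RnaSequence,
    insert_len: int = 15,
    copies: int = 2,
    seed: int = 0,
    max_tries: int = 200,
) -> RnaSequence:
    """Search donor/insert positions (seeded) until the element-preserving
    constraints hold; raises after ``max_tries`` failures."""
    rng = _rng(seed)
    span = copies * insert_len
    if seq.n <= span + 1:
        raise ValueError("sequence too short for the requested insertion")
    for _ in range(max_tries):
        donor = int(rng.integers(0, seq.n - span))
        # insert downstream of the donor window
        lo = donor + span
        pos = int(rng.integers(lo, seq.n + 1))
        try:
            return insert_antisense(seq, donor, pos, insert_len, copies)
        except ValueError:
            continue
    raise ValueError("no valid antisense insertion found")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic two-group per-RNA feature table.

    Defaults are calibrated to the study conditions: 19 sphere- and 28
    network-forming RNAs; group NED means straddling the 0.265/0.280
    classifier cut-offs with spread 0.03; log-normal lengths spanning roughly
    500-3000 nt with network-forming RNAs longer; ~5 AU-rich elements per kb.
    """

    n_sphere: int = 19
    n_network: int = 28
    ned_mean_sphere: float = 0.24
    ned_mean_network: float = 0.31
    ned_sd: float = 0.03
    length_logmean_sphere: float = 6.8   # ~900 nt median
    length_logmean_network: float = 7.4  # ~1640 nt median
    length_logsd: float = 0.5
    are_rate: float = 5.0  # AREs per kb
    gc_mean: float = 0.40
    gc_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sphere < 1 or self.n_network < 1:
            raise ValueError("group sizes must be >= 1")
        if self.ned_sd <= 0 or self.length_logsd <= 0:
            raise ValueError("spreads must be positive")


def gen_cohort(spec: CohortSpec, cohort: str = "initial") -> pd.DataFrame:
    """Synthetic per-RNA table in the canonical source-data schema."""
    rng = _rng(spec.seed)
    rows = []
    for group, n, ned_mean, llm in (
        ("sphere", spec.n_sphere, spec.ned_mean_sphere, spec.length_logmean_sphere),
        ("network", spec.n_network, spec.ned_mean_network, spec.length_logmean_network),
    ):
        ned = np.clip(rng.normal(ned_mean, spec.ned_sd, size=n), 0.0, 1.0)
        length = np.maximum(50, rng.lognormal(llm, spec.length_logsd, size=n)).astype(int)
        n_are = rng.poisson(spec.are_rate * length / 1000.0)
        gc = np.clip(rng.normal(spec.gc_mean, spec.gc_sd, size=n), 0.0, 1.0)
        for k in range(n):
            rows.append(
                dict(
                    gene=f"{group[:3].upper()}{k + 1:03d}",
                    cohort=cohort,
                    observed=group,
                    length=int(length[k]),
                    n_are=int(n_are[k]),
                    gc_frac=float(gc[k]),
                    ned=float(ned[k]),
                )
            )
    return pd.DataFrame(rows)


def gen_clip_tracks(
    n_utrs: int = 200,
    utr_len_range: Tuple[int, int] = (500, 3000),
    n_datasets: int = 2,
    background_rate: float = 0.5,   # expected peaks per kb per dataset
    enriched_fraction: float = 0.2,
    enrichment_factor: float = 10.0,
    seed: int = 0,
) -> Tuple[List[GenomicInterval], List[List[GenomicInterval]], pd.Series]:
    """Synthetic 3'UTR track plus CLIP-peak tracks with known enrichment.

    UTRs are laid end-to-end (with spacers) on one synthetic chromosome with
    random strands; each dataset places Poisson-distributed peaks per UTR,
    with an ``enrichment_factor``-fold higher rate on a random
    ``enriched_fraction`` of UTRs.  Returns (utrs, peak sets, truth labels).
    """
    if background_rate <= 0 or enrichment_factor <= 0:
        raise ValueError("rates must be positive")
    rng = _rng(seed)
    utrs: List[GenomicInterval] = []
    pos = 1000
    lengths = rng.integers(utr_len_range[0], utr_len_range[1] + 1, size=n_utrs)
    strands = rng.choice(["+", "-"], size=n_utrs)
    enriched = rng.random(n_utrs) < enriched_fraction
    for k in range(n_utrs):
        utrs.append(
            GenomicInterval(
                chrom="chrS",
                start=pos,
                end=pos + int(lengths[k]),
                strand=str(strands[k]),
                name=f"utr{k + 1:04d}",
            )
        )
        pos += int(lengths[k]) + 500
    peak_sets: List[List[GenomicInterval]] = []
    for d in range(n_datasets):
        peaks: List[GenomicInterval] = []
        for k, utr in enumerate(utrs):
            rate = background_rate * (enrichment_factor if enriched[k] else 1.0)
            n_pk = rng.poisson(rate * (utr.end - utr.start) / 1000.0)
            for j in range(n_pk):
                w = int(rng.integers(20, 41))
                s = int(rng.integers(utr.start, max(utr.start + 1, utr.end - w)))
                peaks.append(
                    GenomicInterval(
                        chrom="chrS",
                        start=s,
                        end=s + w,
                        strand=utr.strand,
                        name=f"d{d + 1}_pk{k}_{j}",
                        dataset=f"dataset{d + 1}",
                    )
                )
        peak_sets.append(peaks)
    truth = pd.Series(enriched, index=[u.name for u in utrs], name="enriched")
    return utrs, peak_sets, truth
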