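"""Stranded genomic intervals: 3'UTRs vs CLIP-peak tracks.

BED3/BED6 input (0-based half-open).  A peak "falls into" a UTR when they
overlap by at least ``min_overlap`` bp (default 1) on the same chromosome and,
in strand-aware mode, the same strand.  Counting across several CLIP datasets
follows the union-of-tags rule: a UTR's union count is the maximum of its
per-dataset counts, i.e. the number of tags detected in at least one dataset.
An alternative rule that merges overlapping peaks across datasets before
counting is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Tuple, Union

import pandas as pd
from intervaltree import IntervalTree

STRANDS = ("+", "-", ".")


class BedError(ValueError):
    pass


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = "."
    dataset: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise BedError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise BedError(f"invalid strand {self.strand!r}")

    def overlap(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


def read_bed(path: Union[str, Path], dataset: str = "") -> List[GenomicInterval]:
    """Read BED3/BED6; malformed lines raise BedError with the line number."""
    out: List[GenomicInterval] = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedError(f"{path}:{ln}: expected >= 3 tab-separated fields")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedError(f"{path}:{ln}: non-integer coordinates") from exc
            name = fields[3] if len(fields) > 3 else "."
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(
                    GenomicInterval(
                        chrom=fields[0], start=start, end=end,
                        strand=strand, name=name, dataset=dataset,
                    )
                )
            except BedError as exc:
                raise BedError(f"{path}:{ln}: {exc}") from exc
    return out


def write_bed(path: Union[str, Path], intervals: Sequence[GenomicInterval]) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n"
            )


def _merge(intervals: Sequence[GenomicInterval]) -> List[GenomicInterval]:
    """Merge overlapping/adjacent intervals per (chrom, strand)."""
    merged: List[GenomicInterval] = []
    by_key: Dict[Tuple[str, str], List[GenomicInterval]] = {}
    for iv in intervals:
        by_key.setdefault((iv.chrom, iv.strand), []).append(iv)
    for (chrom, strand), ivs in sorted(by_key.items()):
        ivs = sorted(ivs, key=lambda v: (v.start, v.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_s, cur_e, strand, "merged"))
                cur_s, cur_e = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_s, cur_e, strand, "merged"))
    return merged


def count_tags(
    utrs: Sequence[GenomicInterval],
    peak_sets: Sequence[Sequence[GenomicInterval]],
    strand_mode: str = "aware",
    min_overlap: int = 1,
    union_rule: str = "max",
) -> pd.DataFrame:
    """Per-UTR CLIP-tag counts per dataset plus a union count.

    union_rule='max' (default): union count = max across datasets (a tag
    counted if detected in >= 1 dataset).  union_rule='merge': peaks from all
    datasets are merged into non-redundant intervals first, then counted.
    Returns a table indexed like ``utrs`` with one column per dataset and a
    ``union`` column.
    """
    if strand_mode not in ("aware", "ignore"):
        raise ValueError("strand_mode must be 'aware' or 'ignore'")
    if union_rule not in ("max", "merge"):
        raise ValueError("union_rule must be 'max' or 'merge'")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")

    def count_one(peaks: Sequence[GenomicInterval]) -> List[int]:
        trees: Dict[str, IntervalTree] = {}
        for pk in peaks:
            trees.setdefault(pk.chrom, IntervalTree()).addi(pk.start, pk.end, pk)
        counts = []
        for utr in utrs:
            tree = trees.get(utr.chrom)
            c = 0
            if tree is not None:
                for hit in tree.overlap(utr.start, utr.end):
                    pk = hit.data
                    if pk.overlap(utr) < min_overlap:
                        continue
                    if strand_mode == "aware" and pk.strand != utr.strand:
                        continue
                    c += 1
            counts.append(c)
        return counts

    data: Dict[str, List[int]] = {}
    names = []
    for k, peaks in enumerate(peak_sets):
        label = peaks[0].dataset if len(peaks) and peaks[0].dataset else f"dataset{k + 1}"
        names.append(label)
        data[label] = count_one(peaks)
    df = pd.DataFrame(data, index=[u.name for u in utrs])
    if union_rule == "max":
        df["union"] = df[names].max(axis=1) if names else 0
    else:
        merged = _merge([pk for peaks in peak_sets for pk in peaks])
        df["union"] = count_one(merged)
    return df


def group_by_count(
    counts: pd.Series, bins: Sequence[Tuple[int, Union[int, float]]]
) -> pd.Series:
    """Assign each UTR to exactly one count bin.

    ``bins`` is a list of inclusive (lo, hi) ranges, e.g.
    ``[(0, 0), (1, 4), (5, float('inf'))]``; ranges must be disjoint and
    cover every observed count.
    """
    for a, b in bins:
        if a > b:
            raise ValueError(f"bin ({a}, {b}) is empty")
    for i, (a1, b1) in enumerate(bins):
        for a2, b2 in bins[i + 1 :]:
            if a1 <= b2 and a2 <= b1:
                raise ValueError("bins overlap")

    def label(c: int) -> str:
        for a, b in bins:
            if a <= c <= b:
                return f"{a}" if a == b else (f">={a}" if b == float("inf") else f"{a}-{b}")
        raise ValueError(f"count {c} not covered by any bin")

    return counts.map(label)
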