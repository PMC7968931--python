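"""RNA sequence container and FASTA input.

Sequences are held as uppercase RNA over {A, C, G, U}.  DNA input is accepted
and normalised (T -> U); IUPAC ambiguity codes are rejected because every
downstream thermodynamic quantity requires a fully specified sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Union

from Bio import SeqIO

RNA_ALPHABET = frozenset("ACGU")


class SequenceError(ValueError):
    """Raised for sequences that cannot be interpreted as plain RNA."""


@dataclass(frozen=True)
class RnaSequence:
    """A validated RNA sequence with an identifier.

    Parameters
    ----------
    id:
        Record identifier (FASTA header word).
    residues:
        Uppercase RNA string; use :func:`RnaSequence.from_string` to
        normalise arbitrary case / DNA input.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise SequenceError(f"{self.id!r}: empty sequence")
        bad = set(self.residues) - RNA_ALPHABET
        if bad:
            raise SequenceError(
                f"{self.id!r}: invalid residues {sorted(bad)}; "
                "only A/C/G/U (or T, via from_string) are supported"
            )

    @classmethod
    def from_string(cls, residues: str, id: str = "seq") -> "RnaSequence":
        """Build a sequence, uppercasing and converting T to U."""
        return cls(id=id, residues=residues.upper().replace("T", "U"))

    @property
    def n(self) -> int:
        return len(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, i) -> str:
        return self.residues[i]


def read_fasta(path: Union[str, Path]) -> list[RnaSequence]:
    """Read a (multi-)FASTA file into validated RNA sequences.

    T/t is converted to U; any other non-ACGU character raises
    :class:`SequenceError` naming the offending record.
    """
    records = list(iter_fasta(path))
    if not records:
        raise SequenceError(f"{path}: no FASTA records found")
    return records


def iter_fasta(path: Union[str, Path]) -> Iterator[RnaSequence]:
    for rec in SeqIO.parse(str(path), "fasta"):
        yield RnaSequence.from_string(str(rec.seq), id=rec.id)


def write_fasta(path: Union[str, Path], seqs: list[RnaSequence]) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, s.n, 70):
                fh.write(s.residues[i : i + 70] + "\n")


def reverse_complement(residues: str) -> str:
    """Reverse complement in RNA space (A<->U, C<->G)."""
    table = str.maketrans("ACGU", "UGCA")
    return residues.upper().replace("T", "U").translate(table)[::-1]
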