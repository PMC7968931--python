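"""Sequence-level 3'UTR features and cellular mRNA concentration arithmetic.

Features: length, number of canonical AU-rich elements (the pentamer AUUUA,
the binding site class of TIS11B and HuR) and GC content.  Occurrences are
counted overlapping by default; a non-overlapping mode is provided because
clustered AREs (AUUUAUUUA...) differ between the two conventions.

Concentration arithmetic converts mRNA copies per cell into molar and mass
concentrations under standard assumptions (HeLa cell volume 2000 µm³; mean
mRNA length 3500 nt; 330 Da per nucleotide, i.e. 3500 nt = 1155 kDa).
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .seq import RnaSequence

ARE_MOTIF = "AUUUA"
AVOGADRO = 6.02214e23
DEFAULT_CELL_VOLUME_UM3 = 2000.0
DEFAULT_NT_MASS_DA = 330.0  # from the 3500 nt <-> 1155 kDa equivalence


@dataclass(frozen=True)
class FeatureRecord:
    id: str
    length: int
    n_are: int
    gc_frac: float


def count_ares(seq: RnaSequence, overlapping: bool = True) -> int:
    """Number of AUUUA occurrences (case/T-U handled at sequence construction)."""
    if overlapping:
        return len(re.findall(f"(?={ARE_MOTIF})", seq.residues))
    return len(re.findall(ARE_MOTIF, seq.residues))


def gc_content(seq: RnaSequence) -> float:
    """(#G + #C) / length."""
    r = seq.residues
    return (r.count("G") + r.count("C")) / seq.n


def feature_record(seq: RnaSequence, overlapping: bool = True) -> FeatureRecord:
    return FeatureRecord(
        id=seq.id,
        length=seq.n,
        n_are=count_ares(seq, overlapping=overlapping),
        gc_frac=gc_content(seq),
    )


def copies_to_molar(copies: float, volume_um3: float = DEFAULT_CELL_VOLUME_UM3) -> float:
    """Molar concentration of `copies` molecules in a volume given in µm³.

    1 µm³ = 1e-15 L, so 10 copies in a 2000 µm³ cell is ~8.3e-12 M (8 pM) and
    10,000 copies is ~8.3e-9 M (8 nM).
    """
    if copies < 0:
        raise ValueError("copies must be >= 0")
    if volume_um3 <= 0:
        raise ValueError("volume must be positive")
    return copies / (AVOGADRO * volume_um3 * 1e-15)


def rna_molecular_weight(length_nt: int, per_nt_mass_da: float = DEFAULT_NT_MASS_DA) -> float:
    """Molecular weight in Da of an RNA of the given length."""
    if length_nt < 1:
        raise ValueError("length must be >= 1")
    return length_nt * per_nt_mass_da


def molar_to_mass(
    molar: float, length_nt: int, per_nt_mass_da: float = DEFAULT_NT_MASS_DA
) -> float:
    """Mass concentration in g/L (== µg/µl * 1e-3 ... i.e. ng/µl == mg/L)."""
    return molar * rna_molecular_weight(length_nt, per_nt_mass_da)


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Copies-per-cell converted to molarity and mass concentration."""

    copies: float
    volume_um3: float
    length_nt: int
    per_nt_mass_da: float
    molar: float
    mass_g_per_l: float

    @classmethod
    def from_copies(
        cls,
        copies: float,
        volume_um3: float = DEFAULT_CELL_VOLUME_UM3,
        length_nt: int = 3500,
        per_nt_mass_da: float = DEFAULT_NT_MASS_DA,
    ) -> "ConcentrationEstimate":
        molar = copies_to_molar(copies, volume_um3)
        return cls(
            copies=copies,
            volume_um3=volume_um3,
            length_nt=length_nt,
            per_nt_mass_da=per_nt_mass_da,
            molar=molar,
            mass_g_per_l=molar_to_mass(molar, length_nt, per_nt_mass_da),
        )
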