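"""Secondary structures: validation, dot-bracket IO, loop decomposition, energy.

A structure is a set of 0-based base pairs (i, j), i < j.  Validity requires:
each position in at most one pair; no crossing pairs (pseudoknot-free); a
minimum hairpin loop; and an allowed pair type at every paired position.

``structure_energy`` evaluates the energy of an explicit structure by loop
decomposition.  It is deliberately independent of the dynamic-programming
recursions in :mod:`meshrna.ensemble`, so that exhaustive enumeration plus this
function can serve as a brute-force oracle for the partition function.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Tuple

from .energy import EnergyModel, pair_type
from .seq import RnaSequence


class StructureError(ValueError):
    """Raised when a structure violates a validity invariant."""


@dataclass(frozen=True)
class SecondaryStructure:
    """An RNA secondary structure over a sequence of length ``n``."""

    pairs: FrozenSet[Tuple[int, int]]
    n: int

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[int, int]], n: int) -> "SecondaryStructure":
        norm = frozenset((min(i, j), max(i, j)) for i, j in pairs)
        return cls(pairs=norm, n=n)

    @classmethod
    def open_chain(cls, n: int) -> "SecondaryStructure":
        return cls(pairs=frozenset(), n=n)

    # -- validation ---------------------------------------------------------

    def validate(self, seq: RnaSequence = None, model: EnergyModel = None) -> None:
        """Check all structural invariants, raising StructureError on the first
        violation.  Sequence/model checks are skipped when not supplied."""
        seen: Dict[int, Tuple[int, int]] = {}
        for (i, j) in self.pairs:
            if not (0 <= i < j < self.n):
                raise StructureError(f"pair {(i, j)} out of range for n={self.n}")
            for pos in (i, j):
                if pos in seen:
                    raise StructureError(
                        f"position {pos} in both pairs {seen[pos]} and {(i, j)}"
                    )
                seen[pos] = (i, j)
        plist = sorted(self.pairs)
        for a in range(len(plist)):
            i, j = plist[a]
            for b in range(a + 1, len(plist)):
                k, l = plist[b]
                if k >= j:
                    break
                if i < k < j < l:
                    raise StructureError(f"crossing pairs {(i, j)} and {(k, l)}")
        if model is not None:
            for (i, j) in self.pairs:
                if j - i - 1 < model.min_hairpin:
                    raise StructureError(
                        f"pair {(i, j)} closes a loop shorter than min_hairpin="
                        f"{model.min_hairpin}"
                    )
        if seq is not None:
            if seq.n != self.n:
                raise StructureError("sequence length does not match structure")
            for (i, j) in self.pairs:
                if pair_type(seq[i], seq[j]) is None:
                    raise StructureError(
                        f"residues {seq[i]}{seq[j]} at pair {(i, j)} cannot pair"
                    )

    # -- dot-bracket --------------------------------------------------------

    def to_dot_bracket(self) -> str:
        chars = ["."] * self.n
        for (i, j) in self.pairs:
            chars[i] = "("
            chars[j] = ")"
        return "".join(chars)

    @classmethod
    def from_dot_bracket(cls, db: str) -> "SecondaryStructure":
        stack: List[int] = []
        pairs = set()
        for pos, c in enumerate(db):
            if c == "(":
                stack.append(pos)
            elif c == ")":
                if not stack:
                    raise StructureError(f"unbalanced ')' at position {pos}")
                pairs.add((stack.pop(), pos))
            elif c != ".":
                raise StructureError(f"invalid dot-bracket character {c!r} at {pos}")
        if stack:
            raise StructureError(f"unbalanced '(' at position {stack[-1]}")
        return cls(pairs=frozenset(pairs), n=len(db))

    # -- loop decomposition -------------------------------------------------

    def children_of(self) -> Dict[Tuple[int, int], List[Tuple[int, int]]]:
        """Map each pair (plus the virtual exterior ``(-1, n)``) to the pairs
        directly nested inside it (its helix/loop branches)."""
        root = (-1, self.n)
        children: Dict[Tuple[int, int], List[Tuple[int, int]]] = {root: []}
        stack: List[Tuple[int, int]] = [root]
        for p in sorted(self.pairs):
            while stack[-1][1] < p[1]:
                stack.pop()
            children[stack[-1]].append(p)
            children[p] = []
            stack.append(p)
        return children

    def __len__(self) -> int:
        return len(self.pairs)


def base_pair_distance(a: SecondaryStructure, b: SecondaryStructure) -> int:
    """Number of pairs present in exactly one of the two structures."""
    return len(a.pairs ^ b.pairs)


def structure_energy(
    seq: RnaSequence, s: SecondaryStructure, model: EnergyModel
) -> float:
    """Energy (kcal/mol) of an explicit structure under the given model.

    pairsum: sum of per-pair energies.  stacking: unique loop decomposition —
    each pair closes either a hairpin (penalty), a two-sided interior
    loop/bulge (stack energy when both sides are empty, linear penalty
    otherwise), or a multiloop / the exterior loop (neutral).
    """
    s.validate(seq, model)
    if model.kind == "pairsum":
        return sum(model.pair_e(pair_type(seq[i], seq[j])) for (i, j) in s.pairs)
    children = s.children_of()
    energy = 0.0
    for (i, j) in s.pairs:
        kids = children[(i, j)]
        if not kids:
            energy += model.hairpin_penalty(j - i - 1)
        elif len(kids) == 1:
            k, l = kids[0]
            s1, s2 = k - i - 1, j - l - 1
            if s1 == 0 and s2 == 0:
                energy += model.stack_energy(
                    pair_type(seq[i], seq[j]), pair_type(seq[k], seq[l])
                )
            else:
                energy += model.internal_bulge_penalty(s1, s2)
        # multiloop (>= 2 branches): neutral
    return energy
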