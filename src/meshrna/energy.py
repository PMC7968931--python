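"""Simplified nearest-neighbour energy models for secondary-structure ensembles.

Two model kinds are shipped:

``pairsum``
    The energy of a structure is the sum of per-pair energies.  Every quantity
    is hand-checkable, which makes this the model of choice for exact unit
    tests and for the exhaustive-enumeration oracle.

``stacking``
    A small nearest-neighbour model: helically stacked pairs contribute a
    stacking energy, hairpin loops a logarithmic penalty, and interior
    loops/bulges a linear penalty; multiloops and the exterior loop are
    neutral.  This is the default for analyses.  It is a deliberately
    simplified model — it reproduces the qualitative structured-vs-unstructured
    contrast, not absolute free energies of the full Turner parameter set.

Only the six canonical/wobble pair types (AU, UA, CG, GC, GU, UG) are allowed;
the minimum hairpin loop is 3 nt.  Energies are in kcal/mol, temperature in
Kelvin, RT = 0.0019872 * T kcal/mol.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

GAS_CONSTANT = 0.0019872  # kcal / (mol K)

#: canonical + wobble pair types, fixed order used for indexing
PAIR_TYPES: Tuple[str, ...] = ("AU", "UA", "CG", "GC", "GU", "UG")

_PAIR_INDEX: Dict[str, int] = {p: i for i, p in enumerate(PAIR_TYPES)}

DEFAULT_PAIR_ENERGY: Dict[str, float] = {
    "CG": -3.0, "GC": -3.0,
    "AU": -2.0, "UA": -2.0,
    "GU": -1.0, "UG": -1.0,
}

# Per-pair stacking strength; a stack of pairs t1 over t2 contributes
# -(strength[t1] + strength[t2]).  The additive form keeps the table symmetric
# under reading the helix in either direction.
DEFAULT_STACK_STRENGTH: Dict[str, float] = {
    "CG": 1.6, "GC": 1.6,
    "AU": 1.1, "UA": 1.1,
    "GU": 0.6, "UG": 0.6,
}


class EnergyModelError(ValueError):
    pass


def pair_type(a: str, b: str) -> Optional[str]:
    """Return the pair-type string for residues (a, b), or None if unpairable."""
    p = a + b
    return p if p in _PAIR_INDEX else None


@dataclass(frozen=True)
class EnergyModel:
    """Parameters of the folding energy function.

    Attributes
    ----------
    kind:
        ``"pairsum"`` or ``"stacking"``.
    pair_energy:
        Per-pair-type energy in kcal/mol (used by the pairsum kind and by the
        intermolecular duplex scanner).
    stack_strength:
        Per-pair-type stacking strength; stack(t1, t2) = -(s[t1] + s[t2]).
    hairpin_a, hairpin_b:
        Hairpin-closing penalty  a + b * ln(L / min_hairpin)  for loop size L.
    internal_a, internal_b:
        Interior-loop / bulge penalty  a + b * (s1 + s2)  for side sizes s1, s2
        (s1 + s2 >= 1; the (0, 0) case is a stack).
    min_hairpin:
        Minimum hairpin loop size in nt (j - i - 1 >= min_hairpin).
    temperature:
        Kelvin.
    """

    kind: str = "stacking"
    pair_energy: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PAIR_ENERGY))
    stack_strength: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STACK_STRENGTH))
    hairpin_a: float = 3.5
    hairpin_b: float = 1.5
    internal_a: float = 2.0
    internal_b: float = 0.3
    min_hairpin: int = 3
    temperature: float = 310.15

    def __post_init__(self) -> None:
        if self.kind not in ("pairsum", "stacking"):
            raise EnergyModelError(f"unknown energy model kind {self.kind!r}")
        if self.min_hairpin < 3:
            raise EnergyModelError("min_hairpin must be >= 3")
        if self.temperature <= 0:
            raise EnergyModelError("temperature must be positive (Kelvin)")
        for table in (self.pair_energy, self.stack_strength):
            for k, v in table.items():
                if k not in _PAIR_INDEX:
                    raise EnergyModelError(f"unknown pair type {k!r}")
                if not math.isfinite(v):
                    raise EnergyModelError(f"non-finite energy for {k!r}")

    @property
    def RT(self) -> float:
        return GAS_CONSTANT * self.temperature

    def pair_e(self, t: str) -> float:
        return self.pair_energy[t]

    def stack_energy(self, outer: str, inner: str) -> float:
        return -(self.stack_strength[outer] + self.stack_strength[inner])

    def hairpin_penalty(self, loop_len: int) -> float:
        if loop_len < self.min_hairpin:
            raise EnergyModelError(f"hairpin loop of {loop_len} nt below minimum")
        return self.hairpin_a + self.hairpin_b * math.log(loop_len / self.min_hairpin)

    def internal_bulge_penalty(self, s1: int, s2: int) -> float:
        if s1 < 0 or s2 < 0 or s1 + s2 < 1:
            raise EnergyModelError("interior loop sides must be >= 0 with total >= 1")
        return self.internal_a + self.internal_b * (s1 + s2)


PAIRSUM = EnergyModel(kind="pairsum")
STACKING = EnergyModel(kind="stacking")


def model_from_config(cfg: Dict[str, str]) -> EnergyModel:
    """Build a model from flat ``energy.*`` / ``fold.*`` config keys."""
    kwargs = {}
    if "energy.kind" in cfg:
        kwargs["kind"] = cfg["energy.kind"]
    if "energy.temperature_K" in cfg:
        kwargs["temperature"] = float(cfg["energy.temperature_K"])
    if "fold.min_hairpin" in cfg:
        kwargs["min_hairpin"] = int(cfg["fold.min_hairpin"])
    return EnergyModel(**kwargs)
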