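"""Intermolecular RNA-RNA interaction models.

Two levels of abstraction:

* ``duplex_scan`` finds the best contiguous antiparallel duplex between two
  sequences — the physical basis of RNA dimerization (one degree of
  multivalency).  Contiguous-only by design: no interior loops, so the result
  is trivially checkable.

* ``match_sites`` is a stochastic site-matching simulator of the
  dimerization-element network logic: each molecule carries an ordered list
  of element sites (e.g. D1 and D2 modules appended to a structured core);
  compatible free sites on distinct molecules are matched uniformly at random,
  irreversibly, until none remain.  Molecules with one site can only dimerize;
  molecules with two sites in a complementary circuit percolate into a
  network-spanning component.  The simulator supports property-level claims
  (dimers vs networks), not thermodynamic fits.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .energy import EnergyModel, pair_type
from .seq import RnaSequence


class PoolConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# duplex scanning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Duplex:
    start_a: int
    start_b: int
    length: int
    energy: float


def duplex_scan(
    a: RnaSequence, b: RnaSequence, model: EnergyModel, min_len: int = 4
) -> Optional[Duplex]:
    """Minimum-energy run of >= min_len consecutive allowed pairs between
    ``a`` and ``b`` read antiparallel.

    Position t of the duplex pairs a[start_a + t] with b[start_b + length - 1 - t].
    pairsum: sum of pair energies; stacking: sum of the length-1 stack
    energies.  Ties break to the smallest (start_a, start_b); None when no
    qualifying run exists.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    best: Optional[Duplex] = None
    # scan maximal pairable runs along anti-diagonals of (a, reversed b)
    br = b.residues[::-1]
    for x0 in range(a.n):
        for z0 in range(b.n):
            if x0 > 0 and z0 > 0:
                continue  # each anti-diagonal is visited from its boundary cell
            x, z = x0, z0
            while x < a.n and z < b.n:
                t = pair_type(a[x], br[z])
                if t is None:
                    x += 1
                    z += 1
                    continue
                run: List[str] = []
                xs = x
                while x < a.n and z < b.n:
                    t = pair_type(a[x], br[z])
                    if t is None:
                        break
                    run.append(t)
                    x += 1
                    z += 1
                if len(run) >= min_len:
                    if model.kind == "pairsum":
                        energy = sum(model.pair_e(t) for t in run)
                    else:
                        energy = sum(
                            model.stack_energy(run[k], run[k + 1])
                            for k in range(len(run) - 1)
                        )
                    # b-index of the *last* duplex position (smallest b coord)
                    z_last = z - 1
                    cand = Duplex(
                        start_a=xs,
                        start_b=b.n - 1 - z_last,
                        length=len(run),
                        energy=energy,
                    )
                    if (
                        best is None
                        or cand.energy < best.energy
                        or (
                            cand.energy == best.energy
                            and (cand.start_a, cand.start_b)
                            < (best.start_a, best.start_b)
                        )
                    ):
                        best = cand
    return best


# ---------------------------------------------------------------------------
# site-matching network simulator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ElementRegistry:
    """Dimerization element types and their (symmetric) partnerships."""

    partner: Dict[str, str]

    def __post_init__(self) -> None:
        for name, p in self.partner.items():
            if p not in self.partner or self.partner[p] != name:
                raise PoolConfigError(
                    f"partnership of element {name!r} is not symmetric"
                )

    def compatible(self, t1: str, t2: str) -> bool:
        return self.partner[t1] == t2

    @classmethod
    def from_pairs(cls, pairs: Sequence[Tuple[str, str]]) -> "ElementRegistry":
        d: Dict[str, str] = {}
        for a, b in pairs:
            d[a] = b
            d[b] = a
        return cls(partner=d)


@dataclass(frozen=True)
class Construct:
    """One molecule species: a named core carrying an ordered list of sites."""

    name: str
    sites: Tuple[str, ...] = ()

    @property
    def valency(self) -> int:
        return len(self.sites)


@dataclass
class MatchResult:
    n_molecules: int
    molecule_labels: List[str]
    edges: List[Tuple[int, int]]  # (site_index, site_index) in the flat site list
    site_molecule: np.ndarray     # flat site index -> molecule index
    component_sizes: Counter      # size -> count of components

    @property
    def largest(self) -> int:
        return max(self.component_sizes) if self.component_sizes else 0

    @property
    def fraction_in_largest(self) -> float:
        return self.largest / self.n_molecules if self.n_molecules else 0.0


def match_sites(
    pool: Dict[Construct, int],
    registry: ElementRegistry,
    seed: int,
) -> MatchResult:
    """Irreversible random matching of compatible free sites.

    Repeatedly draws uniformly at random among all currently free compatible
    site pairs on distinct molecules and matches them until none remain.
    Deterministic given the seed.
    """
    for construct in pool:
        for s in construct.sites:
            if s not in registry.partner:
                raise PoolConfigError(f"element {s!r} not declared in the registry")
    rng = np.random.default_rng(seed)

    site_molecule: List[int] = []
    site_type: List[str] = []
    labels: List[str] = []
    mol = 0
    for construct, copies in pool.items():
        if copies < 0:
            raise PoolConfigError("copy counts must be >= 0")
        for _ in range(copies):
            labels.append(construct.name)
            for s in construct.sites:
                site_molecule.append(mol)
                site_type.append(s)
            mol += 1
    n_sites = len(site_type)
    sm = np.array(site_molecule, dtype=int) if n_sites else np.zeros(0, dtype=int)

    free = list(range(n_sites))
    edges: List[Tuple[int, int]] = []
    parent = list(range(mol))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def compatible(s1: int, s2: int) -> bool:
        return (
            site_molecule[s1] != site_molecule[s2]
            and registry.compatible(site_type[s1], site_type[s2])
        )

    def all_pairs() -> List[Tuple[int, int]]:
        return [
            (free[a], free[b])
            for a in range(len(free))
            for b in range(a + 1, len(free))
            if compatible(free[a], free[b])
        ]

    # rejection sampling is uniform over compatible pairs; fall back to
    # explicit enumeration when the free pool becomes sparse in partners
    while len(free) >= 2:
        picked = None
        for _ in range(60):
            a, b = rng.choice(len(free), size=2, replace=False)
            if compatible(free[a], free[b]):
                picked = (free[int(a)], free[int(b)])
                break
        if picked is None:
            pairs = all_pairs()
            if not pairs:
                break
            picked = pairs[int(rng.integers(len(pairs)))]
        s1, s2 = picked
        edges.append((min(s1, s2), max(s1, s2)))
        ra, rb = find(site_molecule[s1]), find(site_molecule[s2])
        if ra != rb:
            parent[ra] = rb
        free.remove(s1)
        free.remove(s2)

    comp_sizes = Counter()
    roots = Counter(find(m) for m in range(mol))
    for size in roots.values():
        comp_sizes[size] += 1
    return MatchResult(
        n_molecules=mol,
        molecule_labels=labels,
        edges=edges,
        site_molecule=sm,
        component_sizes=comp_sizes,
    )


@dataclass(frozen=True)
class ComponentStats:
    histogram: Dict[int, int]  # component size -> number of components
    n_molecules: int
    largest: int
    mean_size: float
    fraction_in_largest: float


def component_stats(result: MatchResult) -> ComponentStats:
    hist = dict(sorted(result.component_sizes.items()))
    n_comp = sum(hist.values())
    total = sum(size * cnt for size, cnt in hist.items())
    if total != result.n_molecules:
        raise AssertionError("component sizes do not sum to the molecule count")
    return ComponentStats(
        histogram=hist,
        n_molecules=result.n_molecules,
        largest=result.largest,
        mean_size=total / n_comp if n_comp else 0.0,
        fraction_in_largest=result.fraction_in_largest,
    )


def read_pool_tsv(
    pool_path, elements_path
) -> Tuple[Dict[Construct, int], ElementRegistry]:
    """Pool spec: construct_name <tab> comma-separated sites <tab> copies.
    Element declarations: name <tab> partner."""
    pairs = []
    with open(elements_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, partner = line.split("\t")[:2]
            pairs.append((name.strip(), partner.strip()))
    registry = ElementRegistry.from_pairs(pairs)
    pool: Dict[Construct, int] = {}
    with open(pool_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            name, sites_str, copies = line.split("\t")[:3]
            sites = tuple(s.strip() for s in sites_str.split(",") if s.strip())
            pool[Construct(name=name.strip(), sites=sites)] = int(copies)
    return pool, registry
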