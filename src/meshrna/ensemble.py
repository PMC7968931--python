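"""Thermodynamic ensemble of RNA secondary structures.

Implements the inside-outside (McCaskill-style) partition function over the
simplified energy models in :mod:`meshrna.energy`, yielding:

* the partition sum ``Zq`` (open chain contributes weight 1, so ``Zq >= 1``),
* the base-pair probability matrix ``p_ij``,
* the minimum free energy structure (deterministic traceback),
* the centroid structure (pairs with ``p_ij > 0.5``),
* the ensemble diversity — the expected base-pair distance between two
  independent draws from the Boltzmann ensemble, ``2 * sum p_ij (1 - p_ij)`` —
  and its length-normalised form NED = diversity / n, the morphology
  predictor used throughout this package,
* the per-position unpaired probability profile and "large disordered region"
  (LDR) calls derived from it.

Numerics: all partition arrays are rescaled by a per-nucleotide factor
derived from the MFE (the standard trick for avoiding overflow on long
sequences); probabilities are scale-invariant and ``log Zq`` is always exact.
An exhaustive-enumeration oracle (`enumerate_structures`) provides the ground
truth for short sequences.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .energy import EnergyModel, pair_type
from .seq import RnaSequence
from .structure import SecondaryStructure, structure_energy

DEFAULT_MAX_LENGTH = 7500  # longest sequence the folding engine will accept
ENUMERATION_GUARD = 25

_TIE_TOL = 1e-9


class FoldSizeError(ValueError):
    """Sequence exceeds the configured folding length limit."""


# ---------------------------------------------------------------------------
# exhaustive enumeration oracle
# ---------------------------------------------------------------------------

def enumerate_structures(
    seq: RnaSequence, model: EnergyModel, guard: int = ENUMERATION_GUARD
) -> List[SecondaryStructure]:
    """Every valid secondary structure of ``seq`` (including the open chain).

    Brute force by recursion over non-crossing matchings; refuses sequences
    longer than ``guard`` nucleotides because the count grows exponentially.
    """
    n = seq.n
    if n > guard:
        raise FoldSizeError(
            f"enumeration limited to {guard} nt; got {n} (raise `guard` explicitly "
            "only if you accept exponential cost)"
        )
    mh = model.min_hairpin
    pairable = _pairable_matrix(seq, model)

    memo: dict = {}

    def rec(i: int, j: int) -> List[Tuple[Tuple[int, int], ...]]:
        if j - i + 1 <= mh:  # too short to hold any pair
            return [()]
        key = (i, j)
        if key in memo:
            return memo[key]
        out = list(rec(i + 1, j))
        for k in range(i + mh + 1, j + 1):
            if pairable[i, k]:
                for inner in rec(i + 1, k - 1):
                    for outer in rec(k + 1, j):
                        out.append(((i, k),) + inner + outer)
        memo[key] = out
        return out

    return [
        SecondaryStructure(pairs=frozenset(p), n=n) for p in rec(0, n - 1)
    ]


def _pairable_matrix(seq: RnaSequence, model: EnergyModel) -> np.ndarray:
    n = seq.n
    mh = model.min_hairpin
    m = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + mh + 1, n):
            if pair_type(seq[i], seq[j]) is not None:
                m[i, j] = True
    return m


# ---------------------------------------------------------------------------
# MFE (min-plus dynamic programme)
# ---------------------------------------------------------------------------

INF = float("inf")


def mfe_fold(
    seq: RnaSequence, model: EnergyModel, max_length: int = DEFAULT_MAX_LENGTH
) -> Tuple[SecondaryStructure, float]:
    """Minimum free energy structure and its energy.

    Ties are broken deterministically: at every decomposition step "position
    unpaired" is preferred over "position paired", and the smallest closing
    partner is preferred.
    """
    _check_length(seq, max_length)
    arrays = _mfe_arrays(seq, model)
    pairs = _mfe_traceback(seq, model, arrays)
    s = SecondaryStructure(pairs=frozenset(pairs), n=seq.n)
    return s, float(arrays["W"][0, seq.n - 1]) if seq.n > 0 else 0.0


def _pairsum_energy_matrix(seq: RnaSequence, model: EnergyModel) -> np.ndarray:
    n = seq.n
    e = np.full((n, n), INF)
    for i in range(n):
        for j in range(i + model.min_hairpin + 1, n):
            t = pair_type(seq[i], seq[j])
            if t is not None:
                e[i, j] = model.pair_e(t)
    return e


def _mfe_arrays(seq: RnaSequence, model: EnergyModel) -> dict:
    n = seq.n
    mh = model.min_hairpin
    VB = np.full((n, n), INF)
    # free-segment minimum (>= 0 branches; all-unpaired = 0)
    W = np.zeros((n, n))
    if model.kind == "pairsum":
        e = _pairsum_energy_matrix(seq, model)
        for d in range(mh + 1, n):
            for i in range(0, n - d):
                j = i + d
                if e[i, j] < INF:
                    inner = W[i + 1, j - 1] if j - 1 >= i + 1 else 0.0
                    VB[i, j] = e[i, j] + inner
                # W[i, j]: i unpaired, or i paired to some l
                best = W[i + 1, j]
                ls = np.arange(i + mh + 1, j + 1)
                if ls.size:
                    right = np.where(ls + 1 <= j, W[np.minimum(ls + 1, j), j], 0.0)
                    cand = VB[i, ls] + right
                    m = cand.min()
                    best = min(best, m)
                W[i, j] = best
        return {"VB": VB, "W": W, "M1": None, "M2": None, "e": e}

    # stacking kind
    stw = _stack_energy_matrix(seq, model)
    pairable = _pairable_matrix(seq, model)
    il_a, il_b = model.internal_a, model.internal_b
    M1 = np.full((n, n), INF)  # >= 1 branch
    M2 = np.full((n, n), INF)  # >= 2 branches
    # GM[a, b]: min over k >= a, l <= b of il_b*((k-a)+(b-l)) + VB[k, l]
    GM = np.full((n, n), INF)
    # RowGM[a, b]: min over l <= b of il_b*(b-l) + VB[a, l]
    RowGM = np.full((n, n), INF)
    for d in range(0, n):
        for i in range(0, n - d):
            j = i + d
            if d > mh and pairable[i, j]:
                v = model.hairpin_penalty(j - i - 1)
                if j - 1 >= i + 1:
                    if VB[i + 1, j - 1] < INF:
                        v = min(v, stw[i, j, 0] + VB[i + 1, j - 1])
                    # interior loops excluding the stack position
                    if i + 2 <= j - 1 and GM[i + 2, j - 1] < INF:
                        v = min(v, il_a + il_b + GM[i + 2, j - 1])
                    if j - 2 >= i + 1 and RowGM[i + 1, j - 2] < INF:
                        v = min(v, il_a + il_b + RowGM[i + 1, j - 2])
                    if M2[i + 1, j - 1] < INF:
                        v = min(v, M2[i + 1, j - 1])
                VB[i, j] = v
            # helper arrays (anchored at (i, j))
            g = VB[i, j]
            if i + 1 <= j and GM[i + 1, j] < INF:
                g = min(g, il_b + GM[i + 1, j])
            if j - 1 >= i and GM[i, j - 1] < INF:
                g = min(g, il_b + GM[i, j - 1])
            GM[i, j] = g
            r = VB[i, j]
            if j - 1 >= i and RowGM[i, j - 1] < INF:
                r = min(r, il_b + RowGM[i, j - 1])
            RowGM[i, j] = r
            # M1 / M2 (multiloop segments; unpaired and branches cost 0)
            m1 = M1[i + 1, j] if i + 1 <= j else INF
            m2 = M2[i + 1, j] if i + 1 <= j else INF
            ls = np.arange(i + mh + 1, j + 1)
            if ls.size:
                vb_row = VB[i, ls]
                rest_free = np.array(
                    [W[l + 1, j] if l + 1 <= j else 0.0 for l in ls]
                )
                rest_m1 = np.array(
                    [M1[l + 1, j] if l + 1 <= j else INF for l in ls]
                )
                with np.errstate(invalid="ignore"):
                    m1 = min(m1, np.min(vb_row + rest_free))
                    m2 = min(m2, np.min(vb_row + rest_m1))
            M1[i, j] = m1
            M2[i, j] = m2
            # exterior-style free segment
            w = W[i + 1, j] if i + 1 <= j else 0.0
            W[i, j] = min(w, M1[i, j]) if d > 0 else 0.0
    return {"VB": VB, "W": W, "M1": M1, "M2": M2, "stw": stw,
            "GM": GM, "RowGM": RowGM}


def _stack_energy_matrix(seq: RnaSequence, model: EnergyModel) -> np.ndarray:
    """stw[i, j, 0] = stacking energy of pair (i, j) over (i+1, j-1)."""
    n = seq.n
    stw = np.zeros((n, n, 1))
    for i in range(n - 1):
        for j in range(i + 1, n):
            t1 = pair_type(seq[i], seq[j])
            if t1 is None or j - 1 < i + 1:
                continue
            t2 = pair_type(seq[i + 1], seq[j - 1])
            if t2 is not None:
                stw[i, j, 0] = model.stack_energy(t1, t2)
    return stw


def _mfe_traceback(seq: RnaSequence, model: EnergyModel, arrays: dict) -> set:
    n = seq.n
    mh = model.min_hairpin
    VB, W = arrays["VB"], arrays["W"]
    pairs: set = set()

    def close(v: float, w: float) -> bool:
        if math.isinf(v) or math.isinf(w):
            return v == w
        return abs(v - w) <= _TIE_TOL * max(1.0, abs(v), abs(w))

    def trace_free(i: int, j: int) -> None:
        # segment with >= 0 branches, cost-free otherwise (exterior/multiloop)
        while i <= j:
            if close(W[i, j], W[i + 1, j] if i + 1 <= j else 0.0):
                i += 1
                continue
            for l in range(i + mh + 1, j + 1):
                rest = W[l + 1, j] if l + 1 <= j else 0.0
                if VB[i, l] < INF and close(W[i, j], VB[i, l] + rest):
                    trace_pair(i, l)
                    i = l + 1
                    break
            else:  # numerical safety net: treat as unpaired
                i += 1

    def trace_m1(i: int, j: int) -> None:
        M1 = arrays["M1"]
        while i <= j:
            if i + 1 <= j and close(M1[i, j], M1[i + 1, j]):
                i += 1
                continue
            for l in range(i + mh + 1, j + 1):
                rest = W[l + 1, j] if l + 1 <= j else 0.0
                if VB[i, l] < INF and close(M1[i, j], VB[i, l] + rest):
                    trace_pair(i, l)
                    trace_free(l + 1, j)
                    return
            i += 1

    def trace_pair(i: int, j: int) -> None:
        pairs.add((i, j))
        v = VB[i, j]
        if model.kind == "pairsum":
            if j - 1 >= i + 1:
                trace_free(i + 1, j - 1)
            return
        if close(v, model.hairpin_penalty(j - i - 1)):
            return
        stw = arrays["stw"]
        if j - 1 >= i + 1 and VB[i + 1, j - 1] < INF and close(
            v, stw[i, j, 0] + VB[i + 1, j - 1]
        ):
            trace_pair(i + 1, j - 1)
            return
        # interior loop: explicit scan (only on the trace path)
        for k in range(i + 1, j):
            for l in range(k + mh + 1, j):
                if (k, l) == (i + 1, j - 1) or VB[k, l] >= INF:
                    continue
                pen = model.internal_bulge_penalty(k - i - 1, j - l - 1)
                if close(v, pen + VB[k, l]):
                    trace_pair(k, l)
                    return
        # multiloop
        M2 = arrays["M2"]
        if j - 1 >= i + 1 and M2[i + 1, j - 1] < INF and close(v, M2[i + 1, j - 1]):
            a, b = i + 1, j - 1
            while a <= b:
                if a + 1 <= b and close(M2[a, b], M2[a + 1, b]):
                    a += 1
                    continue
                M1 = arrays["M1"]
                for l in range(a + mh + 1, b + 1):
                    rest = M1[l + 1, b] if l + 1 <= b else INF
                    if VB[a, l] < INF and rest < INF and close(
                        M2[a, b], VB[a, l] + rest
                    ):
                        trace_pair(a, l)
                        trace_m1(l + 1, b)
                        return
                a += 1

    if n > 0:
        trace_free(0, n - 1)
    return pairs


# ---------------------------------------------------------------------------
# partition function (inside) and pair probabilities (outside)
# ---------------------------------------------------------------------------

@dataclass
class PartitionResult:
    """Inside-pass result; all arrays share the per-nucleotide scale sigma."""

    log_z: float
    sigma: float
    QB: np.ndarray       # scaled conditional partition, (i, j) paired
    M: np.ndarray        # scaled >= 1 branch segment partition
    M2: Optional[np.ndarray]
    G: Optional[np.ndarray]  # interior-loop decay prefix (stacking only)
    seq: RnaSequence
    model: EnergyModel

    @property
    def Z(self) -> float:
        """Partition sum as a float; raises OverflowError if unrepresentable."""
        if self.log_z > 700:
            raise OverflowError(
                f"Zq = exp({self.log_z:.1f}) exceeds float range; use log_z"
            )
        return math.exp(self.log_z)

    @property
    def ensemble_free_energy(self) -> float:
        return -self.model.RT * self.log_z

    def zseg(self, a: int, b: int) -> float:
        """Scaled full partition of segment [a, b] (1 for an empty segment)."""
        if a > b:
            return 1.0
        return self.sigma ** (-(b - a + 1)) + self.M[a, b]


def partition_function(
    seq: RnaSequence,
    model: EnergyModel,
    max_length: int = DEFAULT_MAX_LENGTH,
    mfe_energy: Optional[float] = None,
) -> PartitionResult:
    """Inside pass: Zq = sum over all structures of exp(-E/RT)."""
    _check_length(seq, max_length)
    n = seq.n
    mh = model.min_hairpin
    RT = model.RT

    # per-nucleotide rescaling factor from the MFE
    if mfe_energy is None:
        _, mfe_energy = mfe_fold(seq, model, max_length=max_length)
    sigma = max(1.0, math.exp(-1.05 * mfe_energy / (n * RT)))
    sp = sigma ** -np.arange(n + 2, dtype=float)  # sp[t] = sigma^-t

    pairable = _pairable_matrix(seq, model)
    QB = np.zeros((n, n))
    M = np.zeros((n, n))
    M2 = np.zeros((n, n)) if model.kind == "stacking" else None
    G = np.zeros((n, n)) if model.kind == "stacking" else None

    if model.kind == "pairsum":
        e = _pairsum_energy_matrix(seq, model)
        pw = np.where(np.isfinite(e), np.exp(-np.where(np.isfinite(e), e, 0.0) / RT), 0.0)
    else:
        stw = _stack_energy_matrix(seq, model)
        hp_w = np.zeros((n, n))
        for i in range(n):
            for j in range(i + mh + 1, n):
                if pairable[i, j]:
                    hp_w[i, j] = math.exp(-model.hairpin_penalty(j - i - 1) / RT)
        phi = math.exp(-model.internal_b / RT) / sigma
        ia_w = math.exp(-model.internal_a / RT)

    for d in range(1, n):
        for i in range(0, n - d):
            j = i + d
            if d > mh and pairable[i, j]:
                if model.kind == "pairsum":
                    inner = sp[d - 1] + (M[i + 1, j - 1] if j - 1 >= i + 1 else 0.0)
                    QB[i, j] = pw[i, j] * sp[2] * inner
                else:
                    v = hp_w[i, j] * sp[d + 1]
                    if j - 1 >= i + 1:
                        qb_in = QB[i + 1, j - 1]
                        g_in = G[i + 1, j - 1]
                        # stack (both sides empty)
                        if qb_in > 0.0:
                            v += math.exp(-stw[i, j, 0] / RT) * sp[2] * qb_in
                        # interior loops / bulges (total side length >= 1)
                        v += ia_w * sp[2] * (g_in - qb_in)
                        # multiloop (>= 2 branches)
                        v += sp[2] * M2[i + 1, j - 1]
                    QB[i, j] = v
            if model.kind == "stacking":
                g = QB[i, j]
                if i + 1 <= j:
                    g += phi * G[i + 1, j]
                if j - 1 >= i:
                    g += phi * G[i, j - 1]
                if i + 1 <= j - 1:
                    g -= phi * phi * G[i + 1, j - 1]
                G[i, j] = g
            # M / M2 over segment [i, j]
            m = M[i, j - 1] / sigma if j - 1 >= i else 0.0
            ks = np.arange(i, j + 1 - mh - 1)
            if ks.size:
                qb_col = QB[ks, j]
                left_empty = sp[ks - i]
                left_m = np.concatenate(([0.0], M[i, i : j - mh - 1])) if ks.size else None
                # left_m[t] = M[i, ks[t]-1]  (0 when the left segment is empty)
                m += float(qb_col @ (left_empty + left_m))
                if M2 is not None:
                    m2 = M2[i, j - 1] / sigma if j - 1 >= i else 0.0
                    m2 += float(qb_col @ left_m)
                    M2[i, j] = m2
            else:
                if M2 is not None:
                    M2[i, j] = M2[i, j - 1] / sigma if j - 1 >= i else 0.0
            M[i, j] = m

    z_scaled = sp[n] + (M[0, n - 1] if n > 0 else 0.0)
    log_z = math.log(z_scaled) + n * math.log(sigma)
    return PartitionResult(
        log_z=log_z, sigma=sigma, QB=QB, M=M, M2=M2, G=G, seq=seq, model=model
    )


def pair_probabilities(
    seq: RnaSequence,
    model: EnergyModel,
    max_length: int = DEFAULT_MAX_LENGTH,
    inside: Optional[PartitionResult] = None,
) -> np.ndarray:
    """Outside pass: symmetric matrix of base-pairing probabilities p_ij."""
    pf = inside if inside is not None else partition_function(seq, model, max_length)
    n = seq.n
    model = pf.model
    RT = model.RT
    sigma = pf.sigma
    sp = sigma ** -np.arange(n + 2, dtype=float)
    mh = model.min_hairpin
    QB, M = pf.QB, pf.M
    z_scaled = pf.zseg(0, n - 1)

    pairable = _pairable_matrix(seq, model)
    # padded scaled segment partitions: ZS[a, b+1] = zseg(a, b); 1 when empty
    ZS = np.ones((n + 1, n + 1))
    for a in range(n):
        for b in range(a, n):
            ZS[a, b + 1] = sp[b - a + 1] + M[a, b]

    QH = np.zeros((n, n))
    if model.kind == "pairsum":
        e = _pairsum_energy_matrix(seq, model)
        pw = np.where(np.isfinite(e), np.exp(-np.where(np.isfinite(e), e, 0.0) / RT), 0.0)
        QHW = np.zeros((n, n))  # QH * pair weight * sigma^-2, for enclosing sums
        for d in range(n - 1, mh, -1):
            for i in range(0, n - d):
                j = i + d
                if not pairable[i, j]:
                    continue
                v = ZS[0, i] * ZS[j + 1, n]
                if i > 0 and j < n - 1:
                    # sum over enclosing pairs (p, q), p < i, q > j
                    vl = ZS[1 : i + 1, i]      # zseg(p+1, i-1), p = 0..i-1
                    vr = ZS[j + 1, j + 1 : n]  # zseg(j+1, q-1), q = j+1..n-1
                    v += float(vl @ QHW[0:i, j + 1 : n] @ vr)
                QH[i, j] = v
                QHW[i, j] = v * pw[i, j] * sp[2]
    else:
        stw = _stack_energy_matrix(seq, model)
        phi = math.exp(-model.internal_b / RT) / sigma
        ia_w = math.exp(-model.internal_a / RT)
        GH = np.zeros((n, n))   # interior-loop decay prefix over QH
        GHs = np.zeros((n, n))  # plain sigma-decay prefix over QH
        for d in range(n - 1, mh, -1):
            for i in range(0, n - d):
                j = i + d
                gh_self = 0.0
                if pairable[i, j]:
                    v = ZS[0, i] * ZS[j + 1, n]
                    if i > 0 and j < n - 1:
                        qh_out = QH[i - 1, j + 1]
                        if qh_out > 0.0:
                            v += math.exp(-stw[i - 1, j + 1, 0] / RT) * sp[2] * qh_out
                        v += ia_w * sp[2] * (GH[i - 1, j + 1] - qh_out)
                        # multiloop context: (i, j) a branch with >= 1 sibling
                        vl = ZS[1 : i + 1, i]
                        vr = ZS[j + 1, j + 1 : n]
                        v += sp[2] * (
                            float(vl @ QH[0:i, j + 1 : n] @ vr) - GHs[i - 1, j + 1]
                        )
                    QH[i, j] = v
                    gh_self = v
                g = gh_self
                gs = gh_self
                if i - 1 >= 0:
                    g += phi * GH[i - 1, j]
                    gs += GHs[i - 1, j] / sigma
                if j + 1 <= n - 1:
                    g += phi * GH[i, j + 1]
                    gs += GHs[i, j + 1] / sigma
                if i - 1 >= 0 and j + 1 <= n - 1:
                    g -= phi * phi * GH[i - 1, j + 1]
                    gs -= GHs[i - 1, j + 1] / (sigma * sigma)
                GH[i, j] = g
                GHs[i, j] = gs

    P = QB * QH / z_scaled
    P = P + P.T
    np.clip(P, 0.0, 1.0, out=P)
    return P


# ---------------------------------------------------------------------------
# derived ensemble quantities
# ---------------------------------------------------------------------------

def centroid_structure(bppm: np.ndarray) -> SecondaryStructure:
    """Pairs with probability > 0.5 (mutually exclusive pairs cannot both
    exceed 0.5, so the result is always a valid structure)."""
    n = bppm.shape[0]
    iu = np.triu_indices(n, k=1)
    sel = bppm[iu] > 0.5
    pairs = frozenset(zip(iu[0][sel].tolist(), iu[1][sel].tolist()))
    return SecondaryStructure(pairs=pairs, n=n)


def ensemble_diversity(bppm: np.ndarray) -> float:
    """Expected base-pair distance between two independent ensemble draws."""
    iu = np.triu_indices(bppm.shape[0], k=1)
    p = bppm[iu]
    return float(2.0 * np.sum(p * (1.0 - p)))


def unpaired_profile(bppm: np.ndarray) -> np.ndarray:
    q = 1.0 - bppm.sum(axis=1)
    return np.clip(q, 0.0, 1.0)


@dataclass(frozen=True)
class LdrCall:
    """A large disordered region: a long run of mostly-unpaired positions."""

    start: int
    end: int  # half-open
    mean_unpaired: float


def find_ldrs(
    profile: np.ndarray, tau: float = 0.5, min_ldr_length: int = 30
) -> List[LdrCall]:
    """Maximal runs of positions with unpaired probability > tau that are at
    least ``min_ldr_length`` nt long."""
    if not (0.0 < tau < 1.0):
        raise ValueError("tau must be in (0, 1)")
    if min_ldr_length < 1:
        raise ValueError("min_ldr_length must be >= 1")
    calls: List[LdrCall] = []
    above = np.asarray(profile) > tau
    i = 0
    n = len(above)
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_ldr_length:
                calls.append(
                    LdrCall(start=i, end=j, mean_unpaired=float(np.mean(profile[i:j])))
                )
            i = j
        else:
            i += 1
    return calls


@dataclass
class EnsembleSummary:
    """Full ensemble characterisation of one RNA."""

    seq_id: str
    n: int
    log_z: float
    ensemble_free_energy: float
    mfe_structure: SecondaryStructure
    mfe_energy: float
    centroid: SecondaryStructure
    bppm: np.ndarray
    ensemble_diversity: float
    ned: float
    unpaired: np.ndarray

    @property
    def Zq(self) -> float:
        if self.log_z > 700:
            raise OverflowError("Zq exceeds float range; use log_z")
        return math.exp(self.log_z)


def fold(
    seq: RnaSequence,
    model: EnergyModel,
    max_length: int = DEFAULT_MAX_LENGTH,
) -> EnsembleSummary:
    """Run the full ensemble analysis on one sequence."""
    _check_length(seq, max_length)
    mfe_s, mfe_e = mfe_fold(seq, model, max_length)
    pf = partition_function(seq, model, max_length, mfe_energy=mfe_e)
    bppm = pair_probabilities(seq, model, max_length, inside=pf)
    div = ensemble_diversity(bppm)
    return EnsembleSummary(
        seq_id=seq.id,
        n=seq.n,
        log_z=pf.log_z,
        ensemble_free_energy=pf.ensemble_free_energy,
        mfe_structure=mfe_s,
        mfe_energy=mfe_e,
        centroid=centroid_structure(bppm),
        bppm=bppm,
        ensemble_diversity=div,
        ned=div / seq.n,
        unpaired=unpaired_profile(bppm),
    )


def ned(
    seq: RnaSequence, model: EnergyModel, max_length: int = DEFAULT_MAX_LENGTH
) -> float:
    """Normalised ensemble diversity: expected base-pair distance / length."""
    pf = partition_function(seq, model, max_length)
    bppm = pair_probabilities(seq, model, max_length, inside=pf)
    return ensemble_diversity(bppm) / seq.n


def _check_length(seq: RnaSequence, max_length: int) -> None:
    if seq.n > max_length:
        raise FoldSizeError(
            f"sequence {seq.id!r} has {seq.n} nt; the folding engine accepts "
            f"at most {max_length} nt"
        )


def boltzmann_oracle(
    seq: RnaSequence, model: EnergyModel, guard: int = ENUMERATION_GUARD
) -> dict:
    """Brute-force ensemble quantities from exhaustive enumeration.

    Independent of the dynamic programmes above: sums Boltzmann weights of
    every enumerated structure using the loop-decomposition energy function.
    Returns Z, the pair-probability matrix, the MFE energy, and the ensemble
    diversity computed as the weighted mean pairwise base-pair distance.
    """
    structures = enumerate_structures(seq, model, guard=guard)
    RT = model.RT
    energies = np.array([structure_energy(seq, s, model) for s in structures])
    w = np.exp(-energies / RT)
    Z = float(w.sum())
    n = seq.n
    P = np.zeros((n, n))
    for s, wt in zip(structures, w):
        for (i, j) in s.pairs:
            P[i, j] += wt
    P /= Z
    P = P + P.T
    # Expected base-pair distance between two independent draws.  For small
    # ensembles this is the literal double sum over structure pairs (bitmask
    # xor + popcount); for larger ones it is reduced to per-pair indicator
    # frequencies from the same enumeration, E[d] = sum_p 2 f_p (1 - f_p).
    probs = w / Z
    if len(structures) <= 400:
        pair_ids = {pr: k for k, pr in enumerate(
            sorted({pr for s in structures for pr in s.pairs})
        )}
        masks = [
            sum(1 << pair_ids[pr] for pr in s.pairs) for s in structures
        ]
        div = 0.0
        for a, ma in enumerate(masks):
            for b in range(a + 1, len(masks)):
                div += 2 * probs[a] * probs[b] * (ma ^ masks[b]).bit_count()
    else:
        freq = np.zeros((n, n))
        for s, pb in zip(structures, probs):
            for (i, j) in s.pairs:
                freq[i, j] += pb
        iu = np.triu_indices(n, k=1)
        f = freq[iu]
        div = float(np.sum(2.0 * f * (1.0 - f)))
    return {
        "Z": Z,
        "P": P,
        "mfe_energy": float(energies.min()),
        "diversity": div,
        "structures": structures,
        "energies": energies,
    }
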