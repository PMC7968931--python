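"""Ensemble engine: hand-derived examples, invariants, and oracle equivalence.

The exhaustive-enumeration oracle (every structure + loop-decomposition
energies) is the arbiter for the partition function, pair probabilities,
MFE, and ensemble diversity on short sequences.
"""

import math

import numpy as np
import pytest

from meshrna import ensemble as E
from meshrna.energy import EnergyModel
from meshrna.seq import RnaSequence
from meshrna.structure import SecondaryStructure

RT_37 = 0.0019872 * 310.15


def rna(s):
    return RnaSequence.from_string(s)


# ---------------------------------------------------------------------------
# enumeration
# ---------------------------------------------------------------------------

def test_enumeration_counts(pairsum):
    assert len(E.enumerate_structures(rna("AAAAA"), pairsum)) == 1
    assert len(E.enumerate_structures(rna("GAAAC"), pairsum)) == 2
    # sum over k of C(3, k)^2 nested G-C matchings = 1 + 9 + 9 + 1 = 20
    assert len(E.enumerate_structures(rna("GGGAAAACCC"), pairsum)) == 20


def test_enumeration_is_duplicate_free_and_valid(pairsum, random_seq):
    seq = random_seq(14, seed=3)
    structures = E.enumerate_structures(seq, pairsum)
    keys = {frozenset(s.pairs) for s in structures}
    assert len(keys) == len(structures)
    for s in structures:
        s.validate(seq, pairsum)


def test_enumeration_guard():
    with pytest.raises(E.FoldSizeError):
        E.enumerate_structures(rna("A" * 30), EnergyModel(kind="pairsum"))


# ---------------------------------------------------------------------------
# partition function / probabilities: hand-derived examples
# ---------------------------------------------------------------------------

def test_partition_sum_trivial_and_two_state(pairsum):
    assert E.partition_function(rna("AAAAA"), pairsum).Z == pytest.approx(1.0)
    # GAAAC has exactly two structures: open (w=1) and one GC pair (w=e^{3/RT})
    z = E.partition_function(rna("GAAAC"), pairsum).Z
    assert z == pytest.approx(1.0 + math.exp(3.0 / RT_37), rel=1e-12)


def test_pair_probability_two_state(pairsum):
    P = E.pair_probabilities(rna("GAAAC"), pairsum)
    w = math.exp(3.0 / RT_37)
    assert P[0, 4] == pytest.approx(w / (1.0 + w), rel=1e-12)
    assert P[4, 0] == P[0, 4]
    assert np.all(P >= 0.0)


def test_all_zero_matrix_for_unpairable(pairsum):
    P = E.pair_probabilities(rna("AAAAA"), pairsum)
    assert np.all(P == 0.0)


def test_ensemble_diversity_examples(pairsum):
    P = E.pair_probabilities(rna("GAAAC"), pairsum)
    p = P[0, 4]
    assert E.ensemble_diversity(P) == pytest.approx(2 * p * (1 - p), rel=1e-12)
    single = np.zeros((8, 8))
    single[0, 7] = single[7, 0] = 0.5
    assert E.ensemble_diversity(single) == pytest.approx(0.5)
    assert E.ensemble_diversity(np.zeros((5, 5))) == 0.0


def test_ned_examples(pairsum):
    assert E.ned(rna("AAAAA"), pairsum) == 0.0
    w = math.exp(3.0 / RT_37)
    p = w / (1 + w)
    assert E.ned(rna("GAAAC"), pairsum) == pytest.approx(2 * p * (1 - p) / 5, rel=1e-9)


def test_length_cap_refusal(pairsum):
    seq = rna("A" * 50)
    with pytest.raises(E.FoldSizeError):
        E.partition_function(seq, pairsum, max_length=49)
    with pytest.raises(E.FoldSizeError):
        E.ned(seq, pairsum, max_length=49)


# ---------------------------------------------------------------------------
# MFE
# ---------------------------------------------------------------------------

def test_mfe_examples(pairsum):
    s, e = E.mfe_fold(rna("AAAAA"), pairsum)
    assert (s.to_dot_bracket(), e) == (".....", 0.0)
    s, e = E.mfe_fold(rna("GAAAC"), pairsum)
    assert (s.to_dot_bracket(), e) == ("(...)", -3.0)
    s, e = E.mfe_fold(rna("GGGAAAACCC"), pairsum)
    assert e == pytest.approx(-9.0)
    assert s.to_dot_bracket() == "(((....)))"


def test_mfe_is_minimum_over_enumeration(model, random_seq):
    for seed in range(8):
        seq = random_seq(int(np.random.default_rng(seed).integers(6, 17)), seed=seed)
        o = E.boltzmann_oracle(seq, model)
        s, e = E.mfe_fold(seq, model)
        assert e == pytest.approx(o["mfe_energy"], abs=1e-9)
        s.validate(seq, model)


def test_mfe_traceback_deterministic(model, random_seq):
    seq = random_seq(18, seed=11)
    s1, _ = E.mfe_fold(seq, model)
    s2, _ = E.mfe_fold(seq, model)
    assert s1.pairs == s2.pairs


# ---------------------------------------------------------------------------
# centroid
# ---------------------------------------------------------------------------

def test_centroid_rule_and_validity(pairsum):
    assert E.centroid_structure(np.zeros((6, 6))).pairs == frozenset()
    P = E.pair_probabilities(rna("GAAAC"), pairsum)
    assert E.centroid_structure(P).to_dot_bracket() == "(...)"
    m = np.zeros((10, 10))
    m[0, 9] = m[9, 0] = 0.6
    m[1, 8] = m[8, 1] = 0.7
    assert E.centroid_structure(m).pairs == frozenset({(0, 9), (1, 8)})


def test_centroid_never_needs_repair(model, random_seq):
    for seed in range(10):
        seq = random_seq(40, seed=100 + seed, alphabet="ACGU")
        P = E.pair_probabilities(seq, model)
        E.centroid_structure(P).validate(seq, model)


# ---------------------------------------------------------------------------
# unpaired profile and LDRs
# ---------------------------------------------------------------------------

def test_unpaired_profile_examples(pairsum):
    q = E.unpaired_profile(E.pair_probabilities(rna("AAAAA"), pairsum))
    assert np.allclose(q, 1.0)
    P = E.pair_probabilities(rna("GAAAC"), pairsum)
    q = E.unpaired_profile(P)
    assert q[0] == pytest.approx(1 - P[0, 4], rel=1e-12)
    assert np.allclose(q[1:4], 1.0)
    # conservation: row sum + q_i == 1
    assert np.allclose(P.sum(axis=1) + q, 1.0)


def test_find_ldrs_rules():
    q = np.array([0.9] * 40 + [0.1] * 10)
    calls = E.find_ldrs(q, tau=0.5, min_ldr_length=30)
    assert [(c.start, c.end) for c in calls] == [(0, 40)]
    assert calls[0].mean_unpaired == pytest.approx(0.9)
    assert E.find_ldrs(np.full(50, 0.1), 0.5, 30) == []
    assert E.find_ldrs(np.array([0.9] * 10), 0.5, 30) == []
    with pytest.raises(ValueError):
        E.find_ldrs(q, tau=1.5, min_ldr_length=30)


# ---------------------------------------------------------------------------
# physical behaviour
# ---------------------------------------------------------------------------

def test_temperature_monotonicity():
    """Boltzmann behaviour: pairing probability decreases with temperature."""
    probs = []
    for temp in (290.0, 310.15, 330.0, 360.0):
        m = EnergyModel(kind="pairsum", temperature=temp)
        probs.append(E.pair_probabilities(rna("GAAAC"), m)[0, 4])
    assert all(a > b for a, b in zip(probs, probs[1:]))


def test_invariants_on_random_sequences(model, random_seq):
    for seed in range(12):
        n = int(np.random.default_rng(seed).integers(5, 30))
        seq = random_seq(n, seed=1000 + seed)
        pf = E.partition_function(seq, model)
        assert pf.Z >= 1.0
        P = E.pair_probabilities(seq, model, inside=pf)
        assert np.allclose(P, P.T)
        assert P.min() >= 0.0
        rowsums = P.sum(axis=1)
        assert rowsums.max() <= 1.0 + 1e-9
        # entries at or below the hairpin distance are zero
        for i in range(n):
            for j in range(i, min(n, i + model.min_hairpin + 1)):
                assert P[i, j] == 0.0
        div = E.ensemble_diversity(P)
        assert 0.0 <= div / n <= 1.0


def test_oracle_equivalence_spot(model, random_seq):
    """DP vs exhaustive enumeration on a handful of sequences (the full
    100-sequence sweep runs in the acceptance suite)."""
    for seed in (0, 1, 2, 3):
        seq = random_seq(12 + seed, seed=seed)
        o = E.boltzmann_oracle(seq, model)
        pf = E.partition_function(seq, model)
        P = E.pair_probabilities(seq, model, inside=pf)
        assert pf.Z == pytest.approx(o["Z"], rel=1e-9)
        assert np.max(np.abs(P - o["P"])) < 1e-9
        assert E.ensemble_diversity(P) == pytest.approx(o["diversity"], rel=1e-9, abs=1e-12)


def test_scaling_handles_long_structured_sequences(stacking):
    """A 300-nt perfect duplex would overflow a naive partition sum; the
    scaled recursion must return a finite log Z and sane probabilities."""
    from meshrna.seq import reverse_complement

    stem = ("GC" * 74)[:148]
    seq = rna(stem + "AAAA" + reverse_complement(stem))
    summary = E.fold(seq, stacking)
    assert math.isfinite(summary.log_z)
    assert summary.log_z > 700  # beyond exp() range: scaling was required
    with pytest.raises(OverflowError):
        _ = summary.Zq
    assert 0.0 <= summary.ned <= 1.0
    assert summary.ned < 0.01  # a perfect hairpin is structurally homogeneous
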