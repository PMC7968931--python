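import numpy as np
import pytest

from meshrna.ensemble import mfe_fold
from meshrna.features import count_ares, gc_content
from meshrna.synth import (
    CohortSpec,
    find_antisense_insertion,
    gen_clip_tracks,
    gen_cohort,
    gen_hairpin,
    gen_unstructured,
    insert_antisense,
)


def test_gen_hairpin_shape_and_fold(pairsum):
    hp = gen_hairpin(4, 3, gc_frac=1.0, seed=1)
    assert hp.n == 11
    s, e = mfe_fold(hp, pairsum)
    assert len(s.pairs) == 4  # the full stem forms
    assert e == pytest.approx(-12.0)  # four GC pairs under pairsum
    assert gen_hairpin(0, 5).residues == "AAAAA"


def test_generators_are_deterministic():
    assert gen_hairpin(10, 4, 0.8, seed=3).residues == gen_hairpin(10, 4, 0.8, seed=3).residues
    assert gen_unstructured(50, 0.8, seed=3).residues == gen_unstructured(50, 0.8, seed=3).residues
    a = gen_cohort(CohortSpec(seed=5))
    b = gen_cohort(CohortSpec(seed=5))
    assert a.equals(b)
    assert not a.equals(gen_cohort(CohortSpec(seed=6)))


def test_gen_unstructured_composition():
    assert set(gen_unstructured(100, 1.0, seed=0).residues) <= {"A", "U"}
    for seed in range(5):
        s = gen_unstructured(400, 0.8, seed=seed)
        assert gc_content(s) == pytest.approx(0.2, abs=0.1)


def test_insert_antisense_identity_and_length():
    seq = gen_unstructured(200, 0.8, seed=1)
    assert insert_antisense(seq, 10, 100, insert_len=0) is seq
    mutant = find_antisense_insertion(seq, insert_len=15, copies=2, seed=1)
    assert mutant.n == seq.n + 30
    assert count_ares(mutant) == count_ares(seq)


def test_insert_antisense_refuses_to_split_elements():
    seq_str = "G" * 20 + "AUUUA" + "G" * 20
    from meshrna.seq import RnaSequence

    seq = RnaSequence.from_string(seq_str)
    with pytest.raises(ValueError, match="split AUUUA"):
        insert_antisense(seq, 0, 22, insert_len=5, copies=1)
    # inserting outside the element is fine
    out = insert_antisense(seq, 0, 40, insert_len=5, copies=1)
    assert count_ares(out) == 1


def test_gen_cohort_shape_and_moments():
    table = gen_cohort(CohortSpec())
    assert len(table) == 47  # 19 sphere + 28 network
    assert set(table.observed) == {"sphere", "network"}
    big = gen_cohort(CohortSpec(n_sphere=1000, n_network=1000, seed=0))
    sph = big[big.observed == "sphere"]
    net = big[big.observed == "network"]
    spec = CohortSpec()
    se = spec.ned_sd / np.sqrt(1000)
    assert sph.ned.mean() == pytest.approx(spec.ned_mean_sphere, abs=4 * se)
    assert net.ned.mean() == pytest.approx(spec.ned_mean_network, abs=4 * se)
    assert np.log(net.length).mean() > np.log(sph.length).mean()
    # ARE counts scale with length at ~are_rate per kb
    rate = (big.n_are / (big.length / 1000)).mean()
    assert rate == pytest.approx(spec.are_rate, rel=0.1)
    assert (big.ned >= 0).all() and (big.ned <= 1).all()


def test_gen_clip_tracks_determinism_and_enrichment():
    utrs1, peaks1, truth1 = gen_clip_tracks(n_utrs=40, seed=2)
    utrs2, peaks2, truth2 = gen_clip_tracks(n_utrs=40, seed=2)
    assert [u.__dict__ for u in utrs1] == [u.__dict__ for u in utrs2]
    assert [p.__dict__ for ps in peaks1 for p in ps] == [
        p.__dict__ for ps in peaks2 for p in ps
    ]
    assert truth1.equals(truth2)

    from meshrna.intervals import count_tags

    utrs, peaks, truth = gen_clip_tracks(
        n_utrs=120, enrichment_factor=10.0, seed=3
    )
    counts = count_tags(utrs, peaks)
    enriched_mean = counts["union"][truth.values].mean()
    background_mean = counts["union"][~truth.values].mean()
    assert enriched_mean > 3 * background_mean


def test_clip_top_bin_recovers_enriched_utrs():
    """At default rates, UTRs in the >=5-union-tag bin are overwhelmingly the
    truth-enriched ones (precision > 0.8)."""
    from meshrna.intervals import count_tags, group_by_count

    for seed in range(3):
        utrs, peaks, truth = gen_clip_tracks(
            n_utrs=150, enrichment_factor=10.0, seed=seed
        )
        counts = count_tags(utrs, peaks)
        top = group_by_count(
            counts["union"], ((0, 0), (1, 4), (5, float("inf")))
        ) == ">=5"
        assert top.any()
        assert truth[top.values].mean() > 0.8


def test_gen_clip_tracks_null_enrichment_is_flat():
    """With enrichment_factor 1 the truth-'enriched' UTRs carry no extra tags
    (per-kb rates compared, since counts scale with UTR length)."""
    utrs, peaks, truth = gen_clip_tracks(
        n_utrs=200, enrichment_factor=1.0, seed=4
    )
    from meshrna.intervals import count_tags

    kb = np.array([(u.end - u.start) / 1000.0 for u in utrs])
    rate = count_tags(utrs, peaks)["union"].to_numpy() / kb
    a, b = rate[truth.values], rate[~truth.values]
    se = np.sqrt(a.var() / len(a) + b.var() / len(b))
    assert abs(a.mean() - b.mean()) < 2.5 * se


def test_cohort_spec_validation():
    with pytest.raises(ValueError):
        CohortSpec(n_sphere=0)
    with pytest.raises(ValueError):
        CohortSpec(ned_sd=0.0)
    with pytest.raises(ValueError):
        gen_unstructured(10, au_frac=1.5)
    with pytest.raises(ValueError):
        gen_hairpin(4, 2)
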