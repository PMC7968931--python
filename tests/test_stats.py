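"""Rank statistics: hand-enumerated examples, invariants, and a scipy
cross-check of the asymptotic p-values."""

import numpy as np
import pytest
from scipy import stats as sps

from meshrna.stats import (
    compare_groups,
    kruskal_wallis,
    mann_whitney,
    pearson_r,
)
from meshrna.synth import CohortSpec, gen_cohort


def test_mann_whitney_fully_separated_small_sample():
    """x entirely below y: U1 = 0; exact p from all C(6,3)=20 arrangements."""
    r = mann_whitney([1, 2, 3], [4, 5, 6])
    assert r.u1 == 0.0
    assert r.z == pytest.approx(-4.5 / np.sqrt(9 * 7 / 12), rel=1e-9)  # -1.9640
    assert r.p_exact == pytest.approx(2 / 20)
    assert 0 <= r.p_two_sided <= 1


def test_identical_groups_give_zero_z():
    r = mann_whitney([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
    assert r.z == 0.0
    assert r.u1 == r.n1 * r.n2 / 2


def test_antisymmetry_under_group_swap():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=9), rng.normal(1.0, size=11)
    a, b = mann_whitney(x, y), mann_whitney(y, x)
    assert a.z == pytest.approx(-b.z, rel=1e-12)
    assert a.u1 + b.u1 == len(x) * len(y)


def test_tie_correction_shrinks_sigma():
    """sigma with ties <= sigma without; equality iff tie-free."""
    from meshrna.stats import _tie_corrected_sigma

    tied = np.array([1, 1, 2, 2, 3, 3], dtype=float)
    free = np.array([1, 2, 3, 4, 5, 6], dtype=float)
    assert _tie_corrected_sigma(tied, 3, 3) < _tie_corrected_sigma(free, 3, 3)


def test_asymptotic_p_matches_scipy():
    rng = np.random.default_rng(0)
    for _ in range(20):
        x = rng.normal(size=rng.integers(5, 30))
        y = rng.normal(0.5, size=rng.integers(5, 30))
        ours = mann_whitney(x, y)
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        assert ours.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)


def test_exact_vs_asymptotic_agreement_small_samples():
    """Tie-free n1+n2 <= 12: the continuity-corrected normal p tracks the
    exact permutation p within 0.05 absolute.  (The uncorrected p — the
    reported default — can deviate by ~0.1-0.2 near the null centre because U
    is discrete; that is why the continuity flag exists.)"""
    rng = np.random.default_rng(42)
    for _ in range(100):
        n1 = int(rng.integers(3, 7))
        n2 = int(rng.integers(3, 13 - n1))
        x, y = rng.normal(size=n1), rng.normal(0.8, size=n2)
        r = mann_whitney(x, y, continuity=True)
        assert r.p_exact is not None
        assert abs(r.p_two_sided - r.p_exact) < 0.05


def test_kruskal_wallis_hand_value_and_mw_identity():
    h, p = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
    assert h == pytest.approx(32 / 7, rel=1e-9)  # 4.571 by hand ranks
    h0, _ = kruskal_wallis([[1, 2, 3]] * 3)
    assert h0 == pytest.approx(0.0, abs=1e-12)
    # two tie-free groups: H == z^2
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=10), rng.normal(1, size=12)
    h2, _ = kruskal_wallis([x, y])
    assert h2 == pytest.approx(mann_whitney(x, y).z ** 2, rel=1e-9)
    with pytest.raises(ValueError):
        kruskal_wallis([[1, 2]])


def test_pearson_examples_and_errors():
    assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
    assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
    rng = np.random.default_rng(3)
    for seed in range(5):
        x = np.random.default_rng(seed).normal(size=50)
        y = -x + np.random.default_rng(seed + 100).normal(scale=0.5, size=50)
        assert pearson_r(x, y) < 0
    with pytest.raises(ValueError):
        pearson_r([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        pearson_r([1, 2], [1, 2])


def test_compare_groups_orientation_and_subset():
    """Sphere is always group 1, so a longer network group gives z < 0."""
    table = gen_cohort(CohortSpec(seed=9))
    r = compare_groups(table, "length")
    assert r.z < 0
    r2 = compare_groups(table, "ned", subset=lambda t: t.length < 2000)
    assert r2.n1 + r2.n2 == int((table.length < 2000).sum())
    with pytest.raises(ValueError):
        compare_groups(table, "banana")
    with pytest.raises(ValueError):
        compare_groups(table, "ned", subset=lambda t: t.length < 0)


def test_null_z_is_calibrated():
    """Same-distribution groups: |z| < 1.96 in >= 90% of seeded runs."""
    hits = 0
    runs = 100
    for seed in range(runs):
        rng = np.random.default_rng(seed)
        r = mann_whitney(rng.normal(size=50), rng.normal(size=50))
        hits += abs(r.z) < 1.96
    assert hits >= 0.90 * runs
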