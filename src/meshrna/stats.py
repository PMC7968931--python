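"""Rank statistics used for the cohort comparisons.

The central tool is the two-sided Mann-Whitney test reported as a Z statistic:
U1 is computed from midranks, Z = (U1 - n1*n2/2) / sigma with the tie-corrected
standard deviation and *no* continuity correction, and the two-sided p comes
from the standard normal tail.  For small samples (n1 + n2 <= 12) an exact
permutation p-value over all group assignments is computed as well.

Group orientation is fixed (sphere first, network second) by
:func:`compare_groups` so that signed Z values are comparable across runs.

Kruskal-Wallis and Pearson correlation are standard and delegated to scipy;
the Mann-Whitney machinery is explicit because the Z statistic and its exact
small-sample companion are the quantities this package reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_LIMIT = 12  # n1 + n2 up to which the exact permutation p is computed


@dataclass(frozen=True)
class MannWhitneyResult:
    u1: float
    z: float
    p_two_sided: float
    n1: int
    n2: int
    p_exact: Optional[float] = None  # permutation p, small samples only


def mann_whitney(
    x: Sequence[float], y: Sequence[float], continuity: bool = False
) -> MannWhitneyResult:
    """Two-sided Mann-Whitney test of group 1 (x) vs group 2 (y).

    Returns the rank-sum statistic U1 of group 1, the (optionally
    continuity-corrected) tie-corrected normal-approximation Z, its two-sided
    p, and — when n1 + n2 <= 12 — the exact permutation p.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    u1 = _u_statistic(x, y)
    mu = n1 * n2 / 2.0
    sigma = _tie_corrected_sigma(np.concatenate([x, y]), n1, n2)
    if sigma == 0.0:
        z = 0.0
        p = 1.0
    else:
        d = u1 - mu
        if continuity and d != 0.0:
            d -= math.copysign(0.5, d)
        z = d / sigma
        p = 2.0 * sps.norm.sf(abs(z))
    p_exact = None
    if n1 + n2 <= EXACT_LIMIT:
        p_exact = _exact_two_sided_p(np.concatenate([x, y]), n1, u1)
    return MannWhitneyResult(
        u1=float(u1), z=float(z), p_two_sided=float(min(p, 1.0)),
        n1=n1, n2=n2, p_exact=p_exact,
    )


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U1 from midranks of the pooled sample."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)  # midranks
    r1 = ranks[: len(x)].sum()
    return r1 - len(x) * (len(x) + 1) / 2.0


def _tie_corrected_sigma(pooled: np.ndarray, n1: int, n2: int) -> float:
    n = n1 + n2
    if n < 2:
        return 0.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    return math.sqrt(max(var, 0.0))


def _exact_two_sided_p(pooled: np.ndarray, n1: int, u_obs: float) -> float:
    """Permutation p: fraction of group-1 assignments with |U - mu| >= |obs|."""
    n = len(pooled)
    mu = n1 * (n - n1) / 2.0
    ranks = sps.rankdata(pooled)
    const = n1 * (n1 + 1) / 2.0
    thresh = abs(u_obs - mu) - 1e-12
    hits = 0
    total = 0
    for idx in combinations(range(n), n1):
        u = ranks[list(idx)].sum() - const
        if abs(u - mu) >= thresh:
            hits += 1
        total += 1
    return hits / total


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-square p (k-1 df)."""
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    h, p = sps.kruskal(*groups)
    return float(h), float(p)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length signal vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("zero variance")
    return float(sps.pearsonr(x, y).statistic)


COHORT_FEATURES = ("length", "n_are", "gc_frac", "ned")


def compare_groups(
    records: pd.DataFrame,
    feature: str,
    subset: Optional[Callable[[pd.DataFrame], pd.Series]] = None,
    continuity: bool = False,
) -> MannWhitneyResult:
    """Mann-Whitney comparison of a feature between morphology groups.

    Group 1 is always the sphere-forming group and group 2 the network-forming
    group, so the sign of Z is reproducible.  ``subset`` is an optional
    predicate on the table (e.g. ``lambda t: t.length < 2000``).
    """
    if feature not in COHORT_FEATURES:
        raise ValueError(f"feature must be one of {COHORT_FEATURES}")
    t = records
    if subset is not None:
        t = t[subset(t)]
    sphere = t.loc[t.observed == "sphere", feature].to_numpy()
    network = t.loc[t.observed == "network", feature].to_numpy()
    if len(sphere) == 0 or len(network) == 0:
        raise ValueError(f"empty morphology group after subsetting ({feature})")
    return mann_whitney(sphere, network, continuity=continuity)
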