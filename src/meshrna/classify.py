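"""NED-threshold classification of condensate morphology.

RNAs whose 3'UTR has a normalised ensemble diversity (NED) above the upper
cut-off are predicted to drive mesh-like ("network") condensates; those below
the lower cut-off are predicted sphere-forming.  The default cut-offs are
0.280 and 0.265, the values at which three quarters of each experimentally
characterised morphology group fall on the expected side.  Values inside the
open gap are handled by a configurable rule: assigned to the nearer threshold
(midpoint to network) or reported as an explicit third label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, Optional, Union

import pandas as pd

NED_HI_DEFAULT = 0.280
NED_LO_DEFAULT = 0.265

MORPHOLOGIES = ("sphere", "network")
COHORTS = ("initial", "validation")

#: tolerated aliases for the supplementary-table column names
COLUMN_ALIASES: Dict[str, tuple] = {
    "gene": ("gene", "id", "name", "rna", "3utr"),
    "cohort": ("cohort", "set", "group_set"),
    "observed": ("observed", "morphology", "phenotype", "condensate"),
    "length": ("length", "length_nt", "len", "size_nt"),
    "n_are": ("n_are", "are", "ares", "number_of_au-rich_elements", "n_aure"),
    "gc_frac": ("gc_frac", "gc", "gc_content", "gc-content"),
    "ned": ("ned", "normalized_ensemble_diversity", "ned_value"),
}


@dataclass(frozen=True)
class ClassifierThresholds:
    hi: float = NED_HI_DEFAULT
    lo: float = NED_LO_DEFAULT
    gap_rule: str = "nearest"  # or "indeterminate"

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("lo threshold must be <= hi threshold")
        if self.gap_rule not in ("nearest", "indeterminate"):
            raise ValueError("gap_rule must be 'nearest' or 'indeterminate'")


def classify_ned(ned: float, t: ClassifierThresholds = ClassifierThresholds()) -> str:
    """Predict morphology from a NED value: 'network', 'sphere', or
    'indeterminate' (gap values only, under gap_rule='indeterminate')."""
    if ned < 0:
        raise ValueError("NED must be >= 0")
    if ned > t.hi:
        return "network"
    if ned < t.lo:
        return "sphere"
    if t.lo == t.hi:
        # degenerate gap: a single-cut rule, gap_rule irrelevant
        return "network"
    if t.gap_rule == "indeterminate":
        return "indeterminate"
    # nearest threshold; the exact midpoint goes to network
    return "network" if ned - t.lo >= t.hi - ned else "sphere"


@dataclass
class EvaluationResult:
    n: int
    n_correct: int
    accuracy: float
    confusion: pd.DataFrame  # rows = observed, columns = predicted


def evaluate_predictions(
    records: pd.DataFrame, t: ClassifierThresholds = ClassifierThresholds()
) -> EvaluationResult:
    """Confusion counts and accuracy of the NED rule against observed
    morphology.  Indeterminate predictions count as incorrect."""
    if len(records) == 0:
        raise ValueError("empty record table")
    pred = records.ned.map(lambda v: classify_ned(v, t))
    labels = list(MORPHOLOGIES) + (
        ["indeterminate"] if (pred == "indeterminate").any() else []
    )
    confusion = pd.crosstab(records.observed, pred).reindex(
        index=MORPHOLOGIES, columns=labels, fill_value=0
    )
    n_correct = int((pred == records.observed).sum())
    return EvaluationResult(
        n=len(records),
        n_correct=n_correct,
        accuracy=n_correct / len(records),
        confusion=confusion,
    )


def quartile_check(
    records: pd.DataFrame, group: str, cut: float, side: str
) -> float:
    """Fraction of the given morphology group strictly above/below a NED cut."""
    if group not in MORPHOLOGIES:
        raise ValueError(f"unknown group {group!r}")
    if side not in ("above", "below"):
        raise ValueError("side must be 'above' or 'below'")
    vals = records.loc[records.observed == group, "ned"]
    if len(vals) == 0:
        raise ValueError(f"no records in group {group!r}")
    if side == "above":
        return float((vals > cut).mean())
    return float((vals < cut).mean())


def load_source_table(
    path_or_df: Union[str, Path, pd.DataFrame],
    column_map: Optional[Dict[str, str]] = None,
) -> pd.DataFrame:
    """Load a per-RNA source-data table (TSV) into the canonical schema.

    Canonical columns: gene, cohort, observed, length, n_are, gc_frac, ned.
    Column names are matched case-insensitively against known aliases; an
    explicit ``column_map`` (canonical -> actual) overrides the aliases.
    ``cohort`` is optional (defaults to 'initial').
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t", comment="#")
    lower = {c.lower().strip().replace(" ", "_"): c for c in df.columns}
    rename: Dict[str, str] = {}
    for canon, aliases in COLUMN_ALIASES.items():
        if column_map and canon in column_map:
            if column_map[canon] not in df.columns:
                raise KeyError(f"mapped column {column_map[canon]!r} not in table")
            rename[column_map[canon]] = canon
            continue
        for alias in aliases:
            if alias in lower:
                rename[lower[alias]] = canon
                break
    df = df.rename(columns=rename)
    missing = {"gene", "observed", "ned"} - set(df.columns)
    if missing:
        raise KeyError(f"source table is missing required column(s): {sorted(missing)}")
    if "cohort" not in df.columns:
        df["cohort"] = "initial"
    df["observed"] = df.observed.str.lower().str.strip()
    bad = set(df.observed) - set(MORPHOLOGIES)
    if bad:
        raise ValueError(f"unknown morphology label(s): {sorted(bad)}")
    df["cohort"] = df.cohort.str.lower().str.strip()
    badc = set(df.cohort) - set(COHORTS)
    if badc:
        raise ValueError(f"unknown cohort label(s): {sorted(badc)}")
    if (df.ned < 0).any():
        raise ValueError("NED values must be >= 0")
    return df
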