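import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from meshrna.classify import (
    ClassifierThresholds,
    classify_ned,
    evaluate_predictions,
    load_source_table,
    quartile_check,
)
from meshrna.synth import CohortSpec, gen_cohort

T = ClassifierThresholds()


@pytest.mark.parametrize(
    "ned,expected",
    [
        (0.30, "network"),   # above the 0.280 cut-off
        (0.20, "sphere"),    # below the 0.265 cut-off
        (0.2725, "network"), # the exact midpoint goes to network
        (0.270, "sphere"),   # closer to 0.265
        (0.278, "network"),  # closer to 0.280
    ],
)
def test_classify_ned_thresholds(ned, expected):
    assert classify_ned(ned, T) == expected


def test_gap_rule_indeterminate():
    t = ClassifierThresholds(gap_rule="indeterminate")
    assert classify_ned(0.27, t) == "indeterminate"
    assert classify_ned(0.30, t) == "network"
    assert classify_ned(0.20, t) == "sphere"


def test_single_cut_when_thresholds_coincide():
    for rule in ("nearest", "indeterminate"):
        t = ClassifierThresholds(hi=0.28, lo=0.28, gap_rule=rule)
        assert classify_ned(0.281, t) == "network"
        assert classify_ned(0.279, t) == "sphere"
        assert classify_ned(0.28, t) == "network"  # boundary value, gap of size 0


def test_invalid_thresholds_and_ned():
    with pytest.raises(ValueError):
        ClassifierThresholds(hi=0.2, lo=0.3)
    with pytest.raises(ValueError):
        classify_ned(-0.1, T)


@settings(derandomize=True, max_examples=200)
@given(
    ned=st.floats(min_value=0.0, max_value=1.0),
    bump=st.floats(min_value=0.0, max_value=0.5),
)
def test_monotonicity_raising_ned_never_moves_toward_sphere(ned, bump):
    order = {"sphere": 0, "network": 1}
    a, b = classify_ned(ned, T), classify_ned(min(ned + bump, 1.0), T)
    assert order[b] >= order[a]


def test_evaluate_predictions_perfect_and_empty():
    perfect = pd.DataFrame(
        dict(gene=["a", "b"], observed=["network", "network"], ned=[0.4, 0.35])
    )
    ev = evaluate_predictions(perfect, T)
    assert ev.accuracy == 1.0
    assert ev.confusion.loc["network", "network"] == 2
    with pytest.raises(ValueError):
        evaluate_predictions(perfect.iloc[:0], T)


def test_evaluation_indeterminate_counts_as_incorrect():
    t = ClassifierThresholds(gap_rule="indeterminate")
    table = pd.DataFrame(
        dict(gene=["a", "b"], observed=["network", "sphere"], ned=[0.27, 0.20])
    )
    ev = evaluate_predictions(table, t)
    assert ev.n_correct == 1
    assert ev.accuracy == 0.5
    assert "indeterminate" in ev.confusion.columns


def test_accuracy_approaches_one_with_separation():
    """Cohorts whose group NED means straddle the thresholds far beyond the
    spread are classified almost perfectly."""
    accs = []
    for sep in (0.01, 0.10, 0.25):
        spec = CohortSpec(
            ned_mean_sphere=max(0.2725 - sep, 0.01),
            ned_mean_network=0.2725 + sep,
            ned_sd=0.02,
            n_sphere=50,
            n_network=50,
            seed=7,
        )
        accs.append(evaluate_predictions(gen_cohort(spec), T).accuracy)
    assert accs == sorted(accs)
    assert accs[-1] > 0.99


def test_quartile_check():
    table = pd.DataFrame(
        dict(
            gene=list("abcdefgh"),
            observed=["network"] * 4 + ["sphere"] * 4,
            ned=[0.30, 0.29, 0.27, 0.32, 0.20, 0.22, 0.27, 0.25],
        )
    )
    assert quartile_check(table, "network", 0.28, "above") == 0.75
    assert quartile_check(table, "sphere", 0.265, "below") == 0.75
    assert quartile_check(table, "network", 0.0, "above") == 1.0
    with pytest.raises(ValueError):
        quartile_check(table, "blob", 0.28, "above")


def test_load_source_table_aliases_and_errors(tmp_path):
    p = tmp_path / "sd.tsv"
    p.write_text(
        "Gene\tCohort\tMorphology\tLength_nt\tNumber_of_AU-rich_elements\tGC-content\tNED\n"
        "CD47\tinitial\tNetwork\t4400\t8\t0.35\t0.31\n"
        "TLR8\tvalidation\tSphere \t1200\t3\t0.45\t0.21\n"
    )
    df = load_source_table(p)
    assert list(df.columns[:3]) == ["gene", "cohort", "observed"]
    assert df.observed.tolist() == ["network", "sphere"]
    assert df.n_are.tolist() == [8, 3]

    bad = tmp_path / "bad.tsv"
    bad.write_text("gene\tobserved\nX\tnetwork\n")
    with pytest.raises(KeyError, match="ned"):
        load_source_table(bad)

    weird = tmp_path / "weird.tsv"
    weird.write_text("gene\tobserved\tned\nX\tblobby\t0.3\n")
    with pytest.raises(ValueError, match="morphology"):
        load_source_table(weird)
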