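"""APOBEC-high/low classification, paired enrichment and survival logic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apobec_emt import (
    annotate_cohort,
    association_test,
    classify_apobec,
    group_survival_summary,
    paired_enrichment,
    survivor_class,
)


def test_fixed_threshold_classification():
    labels, cut = classify_apobec([0.01, 0.02, 0.05, 0.10], mode="fixed", threshold=0.04)
    assert list(labels) == ["low", "low", "high", "high"]
    assert cut == 0.04


def test_boundary_fraction_is_low():
    labels, _ = classify_apobec([0.04], mode="fixed", threshold=0.04)
    assert list(labels) == ["low"]


def test_upper_quartile_all_ties_are_low():
    labels, cut = classify_apobec([0.03] * 8, mode="upper_quartile")
    assert list(labels) == ["low"] * 8
    assert cut == pytest.approx(0.03)


def test_upper_quartile_threshold_is_75th_percentile():
    fracs = [0.01, 0.02, 0.03, 0.08]
    labels, cut = classify_apobec(fracs, mode="upper_quartile")
    assert cut == pytest.approx(np.percentile(fracs, 75))
    assert list(labels) == ["low", "low", "low", "high"]


def test_classify_rejects_empty_and_out_of_range():
    with pytest.raises(ValueError):
        classify_apobec([])
    with pytest.raises(ValueError):
        classify_apobec([1.2])


@settings(max_examples=30, derandomize=True, deadline=None)
@given(
    st.lists(st.floats(0, 1), min_size=2, max_size=20),
    st.integers(0, 19),
    st.floats(0, 0.5),
)
def test_classification_is_monotone(fracs, idx, bump):
    """Raising one fraction never flips its label high -> low."""
    idx = idx % len(fracs)
    before, _ = classify_apobec(fracs, mode="fixed", threshold=0.04)
    raised = list(fracs)
    raised[idx] = min(1.0, raised[idx] + bump)
    after, _ = classify_apobec(raised, mode="fixed", threshold=0.04)
    if before.iloc[idx] == "high":
        assert after.iloc[idx] == "high"


def _cohort(rows):
    return pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "site", "apobec_fraction"]
    )


def test_paired_enrichment_single_pair():
    table = _cohort(
        [("a", "p1", "primary", 0.02), ("b", "p1", "metastatic", 0.12)]
    )
    enr = paired_enrichment(table)
    assert enr.per_patient["ratio"].iloc[0] == pytest.approx(6.0)
    assert enr.pooled_ratio == pytest.approx(6.0)


def test_paired_enrichment_zero_primary_is_undefined_but_pooled_holds():
    table = _cohort(
        [
            ("a", "p1", "primary", 0.0),
            ("b", "p1", "metastatic", 0.0),
            ("c", "p2", "primary", 0.05),
            ("d", "p2", "metastatic", 0.10),
        ]
    )
    enr = paired_enrichment(table)
    assert enr.n_undefined == 1
    assert enr.pooled_ratio == pytest.approx(0.10 / 0.05)
    assert enr.geometric_mean_ratio == pytest.approx(2.0)


def test_paired_enrichment_requires_complete_pairs():
    with pytest.raises(ValueError):
        paired_enrichment(_cohort([("a", "p1", "primary", 0.05)]))


def test_pooled_ratio_invariant_to_patient_order():
    rows = [
        ("a", "p1", "primary", 0.01),
        ("b", "p1", "metastatic", 0.05),
        ("c", "p2", "primary", 0.03),
        ("d", "p2", "metastatic", 0.21),
    ]
    fwd = paired_enrichment(_cohort(rows)).pooled_ratio
    rev = paired_enrichment(_cohort(rows[::-1])).pooled_ratio
    assert fwd == pytest.approx(rev)


@pytest.mark.parametrize(
    "days,expected",
    [
        (730, "short"),  # ~2.0 years
        (2200, "long"),  # ~6.0 years
        (1500, "intermediate"),  # ~4.1 years
        (float("nan"), "missing"),
    ],
)
def test_survivor_class(days, expected):
    assert survivor_class(days) == expected


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.floats(min_value=1, max_value=20000))
def test_survivor_class_partitions(days):
    assert survivor_class(days) in {"short", "long", "intermediate"}


def test_group_survival_summary_reproduces_group_means():
    """Constructed groups reproduce the reported cohort averages: high
    816.7 days, low 1,655.3 days."""
    table = pd.DataFrame(
        {
            "sample_id": ["a", "b", "c"],
            "patient_id": ["p1", "p2", "p3"],
            "site": ["metastatic"] * 3,
            "apobec_fraction": [0.1, 0.1, 0.01],
            "survival_days": [800.0, 833.4, 1655.3],
            "apobec_label": ["high", "high", "low"],
        }
    )
    summary = group_survival_summary(table)
    assert summary.means["high"] == pytest.approx(816.7)
    assert summary.means["low"] == pytest.approx(1655.3)
    assert summary.difference == pytest.approx(816.7 - 1655.3)


def test_group_survival_identical_groups_zero_difference():
    table = pd.DataFrame(
        {
            "sample_id": list("abcd"),
            "patient_id": list("abcd"),
            "site": ["metastatic"] * 4,
            "apobec_fraction": [0.1, 0.1, 0.01, 0.01],
            "survival_days": [900.0, 1100.0, 900.0, 1100.0],
            "apobec_label": ["high", "high", "low", "low"],
        }
    )
    summary = group_survival_summary(table)
    assert summary.difference == pytest.approx(0.0)
    assert summary.p_value == pytest.approx(1.0)


def test_group_survival_missing_label_flagged():
    table = pd.DataFrame(
        {
            "sample_id": ["a"],
            "patient_id": ["p"],
            "site": ["metastatic"],
            "apobec_fraction": [0.1],
            "survival_days": [500.0],
            "apobec_label": ["high"],
        }
    )
    summary = group_survival_summary(table)
    assert summary.missing_labels == ["low"]
    assert summary.difference is None


def _fisher_two_sided(table):
    """Independent oracle: enumerate the hypergeometric distribution."""
    (a, b), (c, d) = table
    n1, n2, m = a + b, c + d, a + c
    total = math.comb(n1 + n2, m)
    p_obs = math.comb(n1, a) * math.comb(n2, c) / total
    p = 0.0
    for x in range(max(0, m - n2), min(n1, m) + 1):
        px = math.comb(n1, x) * math.comb(n2, m - x) / total
        if px <= p_obs * (1 + 1e-12):
            p += px
    return p


@pytest.mark.parametrize(
    "table", [[[10, 0], [0, 10]], [[5, 5], [5, 5]], [[8, 2], [3, 7]], [[1, 9], [9, 1]]]
)
def test_association_test_matches_enumeration(table):
    res = association_test(table)
    assert res.p_value == pytest.approx(_fisher_two_sided(table), abs=1e-10)


def test_association_test_perfect_separation_value():
    res = association_test([[10, 0], [0, 10]])
    assert res.p_value == pytest.approx(2 / math.comb(20, 10), abs=1e-10)
    assert res.p_value == pytest.approx(1.083e-5, rel=1e-3)


def test_association_test_degenerate_margin():
    res = association_test([[1, 0], [0, 0]])
    assert res.p_value == 1.0
    assert not res.or_defined


def test_association_test_no_association():
    res = association_test([[5, 5], [5, 5]])
    assert res.p_value == pytest.approx(1.0)
    assert res.odds_ratio == pytest.approx(1.0)


def test_annotate_cohort_patient_labels_follow_metastatic_site():
    table = _cohort(
        [
            ("a", "p1", "primary", 0.06),
            ("b", "p1", "metastatic", 0.01),
            ("c", "p2", "primary", 0.01),
            ("d", "p2", "metastatic", 0.08),
        ]
    )
    table["survival_days"] = [900.0, 900.0, 2200.0, 2200.0]
    out = annotate_cohort(table, mode="fixed", threshold=0.04)
    by_sample = out.set_index("sample_id")
    # per-sample labels use each sample's own fraction
    assert by_sample.loc["a", "apobec_label"] == "high"
    # patient labels follow the metastatic sample
    assert by_sample.loc["a", "patient_apobec_label"] == "low"
    assert by_sample.loc["c", "patient_apobec_label"] == "high"
    assert by_sample.loc["a", "survivor_class"] == "short"
    assert by_sample.loc["c", "survivor_class"] == "long"
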