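"""APOBEC-high/low classification, paired primary-metastatic enrichment,
and survival summaries for paired tumor cohorts.

The cohort table has one row per sample: ``sample_id``, ``patient_id``,
``site`` (primary / metastatic / precursor), ``apobec_fraction`` (the
SBS2+SBS13 relative contribution), and optionally ``survival_days``.
Classification follows the upper-quartile rule with a strict > 4% cut as
the fixed-threshold default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DAYS_PER_YEAR = 365.25
DEFAULT_THRESHOLD = 0.04

COHORT_COLUMNS = [
    "sample_id",
    "patient_id",
    "site",
    "apobec_fraction",
    "survival_days",
]


def classify_apobec(
    fractions, mode: str = "fixed", threshold: float = DEFAULT_THRESHOLD
) -> tuple[pd.Series, float]:
    """Label samples APOBEC-high/low from their SBS2+13 fraction.

    ``fixed`` mode uses the supplied threshold; ``upper_quartile`` sets it
    to the 75th percentile of the inputs. The comparison is strictly
    greater-than, so a fraction exactly at the threshold is low.

    Returns ``(labels, threshold_used)``.
    """
    frac = pd.Series(fractions, dtype=float)
    if frac.empty:
        raise ValueError("no fractions to classify")
    if ((frac < 0) | (frac > 1)).any():
        raise ValueError("fractions must lie in [0, 1]")
    if mode == "fixed":
        if threshold is None:
            raise ValueError("fixed mode requires a threshold")
        cut = float(threshold)
    elif mode == "upper_quartile":
        cut = float(np.percentile(frac.to_numpy(), 75))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    labels = pd.Series(np.where(frac > cut, "high", "low"), index=frac.index)
    return labels, cut


@dataclass
class PairedEnrichment:
    """Metastatic/primary APOBEC-fraction enrichment for a paired cohort."""

    per_patient: pd.DataFrame  # patient_id, primary, metastatic, ratio
    pooled_ratio: float  # sum of met fractions / sum of primary fractions
    geometric_mean_ratio: float  # over patients with a defined ratio
    n_pairs: int
    n_undefined: int


def paired_enrichment(cohort: pd.DataFrame) -> PairedEnrichment:
    """Per-patient and pooled metastatic/primary APOBEC enrichment.

    Patients need one primary and one metastatic sample (extra samples per
    site are averaged). A patient with primary fraction 0 has an undefined
    per-patient ratio — excluded from the geometric mean but still counted
    in the pooled ratio of summed fractions.
    """
    df = cohort[cohort["site"].isin(["primary", "metastatic"])]
    wide = df.pivot_table(
        index="patient_id", columns="site", values="apobec_fraction", aggfunc="mean"
    )
    if "primary" not in wide or "metastatic" not in wide:
        raise ValueError("cohort has no complete primary/metastatic pairs")
    wide = wide.dropna(subset=["primary", "metastatic"])
    if wide.empty:
        raise ValueError("cohort has no complete primary/metastatic pairs")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = wide["metastatic"] / wide["primary"]
    ratio = ratio.where(wide["primary"] > 0)
    per_patient = wide.reset_index().rename_axis(None, axis=1)
    per_patient["ratio"] = ratio.to_numpy()
    defined = ratio.dropna()
    defined = defined[defined > 0]
    geo = float(np.exp(np.log(defined).mean())) if len(defined) else math.nan
    prim_sum = wide["primary"].sum()
    pooled = float(wide["metastatic"].sum() / prim_sum) if prim_sum > 0 else math.inf
    return PairedEnrichment(
        per_patient=per_patient,
        pooled_ratio=pooled,
        geometric_mean_ratio=geo,
        n_pairs=len(wide),
        n_undefined=int(ratio.isna().sum()),
    )


def survivor_class(
    survival_days: float | None,
    short_cut_years: float = 3.5,
    long_cut_years: float = 5.0,
) -> str:
    """Short-term (< 3.5 y), long-term (> 5 y) or intermediate survivor.

    Both cuts are strict; missing survival maps to "missing".
    """
    if survival_days is None or (
        isinstance(survival_days, float) and math.isnan(survival_days)
    ):
        return "missing"
    if survival_days <= 0:
        raise ValueError("survival_days must be positive")
    years = survival_days / DAYS_PER_YEAR
    if years < short_cut_years:
        return "short"
    if years > long_cut_years:
        return "long"
    return "intermediate"


@dataclass
class SurvivalSummary:
    means: dict  # label -> mean survival in days
    n: dict  # label -> sample count
    difference: float | None  # mean(high) - mean(low) when both present
    p_value: float | None  # Welch two-sided t-test
    missing_labels: list


def group_survival_summary(cohort: pd.DataFrame, label_col: str = "apobec_label") -> SurvivalSummary:
    """Mean survival per APOBEC label with a Welch (unequal-variance) test.

    The test is descriptive only; labels are never revised from it.
    """
    df = cohort.dropna(subset=["survival_days"])
    groups = {
        lab: sub["survival_days"].to_numpy(dtype=float)
        for lab, sub in df.groupby(label_col)
    }
    means = {lab: float(v.mean()) for lab, v in groups.items()}
    ns = {lab: int(len(v)) for lab, v in groups.items()}
    missing = [lab for lab in ("high", "low") if lab not in groups]
    diff = p = None
    if not missing:
        hi, lo = groups["high"], groups["low"]
        diff = float(hi.mean() - lo.mean())
        if len(hi) > 1 and len(lo) > 1:
            p = float(stats.ttest_ind(hi, lo, equal_var=False).pvalue)
    return SurvivalSummary(means=means, n=ns, difference=diff, p_value=p, missing_labels=missing)


@dataclass
class AssociationResult:
    odds_ratio: float
    p_value: float
    or_defined: bool


def association_test(table) -> AssociationResult:
    """Fisher's exact test (two-sided) on a 2x2 count table.

    The odds ratio uses the Haldane 0.5 correction when any cell is zero;
    a table with an all-zero margin returns p = 1 and an undefined OR.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("expected a 2x2 table of non-negative integers")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return AssociationResult(odds_ratio=math.nan, p_value=1.0, or_defined=False)
    p = float(stats.fisher_exact(t.astype(int), alternative="two-sided").pvalue)
    if (t == 0).any():
        t = t + 0.5
    odds = float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))
    return AssociationResult(odds_ratio=odds, p_value=p, or_defined=True)


def annotate_cohort(
    cohort: pd.DataFrame,
    mode: str = "fixed",
    threshold: float = DEFAULT_THRESHOLD,
    label_site: str = "metastatic",
) -> pd.DataFrame:
    """Attach apobec_label and survivor_class columns to a cohort table.

    Per-sample labels come from :func:`classify_apobec`. Patient-level
    labels follow the sample from ``label_site`` (the metastatic sample by
    default, matching the definition of high tumors by their metastatic
    SBS2+13 contribution); pass ``label_site="max"`` to use each patient's
    maximum fraction instead.
    """
    df = cohort.copy()
    labels, cut = classify_apobec(df["apobec_fraction"], mode=mode, threshold=threshold)
    df["apobec_label"] = labels
    df.attrs["threshold_used"] = cut
    if label_site == "max":
        patient_frac = df.groupby("patient_id")["apobec_fraction"].max()
    else:
        patient_frac = (
            df[df["site"] == label_site]
            .groupby("patient_id")["apobec_fraction"]
            .mean()
        )
    patient_label = pd.Series(
        np.where(patient_frac > cut, "high", "low"), index=patient_frac.index
    )
    df["patient_apobec_label"] = df["patient_id"].map(patient_label)
    if "survival_days" in df:
        df["survivor_class"] = df["survival_days"].map(survivor_class)
    return df
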