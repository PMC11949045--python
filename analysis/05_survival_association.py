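#!/usr/bin/env python
"""Survival by APOBEC group and the short/long survivor association.

Takes the fitted, annotated cohort from 02_fit_signatures.py, summarizes
mean survival for APOBEC-high versus -low patients (classified by their
metastatic sample at the strict > 4% SBS2+SBS13 cut), assigns short-term
(< 3.5 y) / long-term (> 5 y) survivor classes, and tests the high/low x
short/long association with Fisher's exact test.
"""

from pathlib import Path

import pandas as pd

from apobec_emt import association_test, group_survival_summary, io

SCRATCH = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    path = RESULTS / "cohort_annotated.tsv"
    if not path.exists():
        raise SystemExit("run analysis/02_fit_signatures.py first")
    table = io.read_cohort_table(path)
    patients = (
        table[table["site"] == "metastatic"]
        .drop(columns=["apobec_label"])
        .rename(columns={"patient_apobec_label": "apobec_label_patient"})
        .copy()
    )

    summary = group_survival_summary(
        patients.rename(columns={"apobec_label_patient": "apobec_label"}),
    )
    lines = []
    for label in ("high", "low"):
        if label in summary.means:
            lines.append(
                f"APOBEC-{label}: mean survival {summary.means[label]:.1f} days "
                f"(n={summary.n[label]})"
            )
    print("\n".join(lines))
    if summary.difference is not None:
        print(
            f"difference of means {summary.difference:.1f} days "
            f"(Welch two-sided p = {summary.p_value:.3g})"
        )

    crosstab = pd.crosstab(
        patients["apobec_label_patient"], patients["survivor_class"]
    )
    counts = [
        [
            int(crosstab.at[lab, cls]) if cls in crosstab.columns and lab in crosstab.index else 0
            for cls in ("short", "long")
        ]
        for lab in ("high", "low")
    ]
    fisher = association_test(counts)
    print(
        f"short/long survivor table (high: {counts[0]}, low: {counts[1]}): "
        f"Fisher exact p = {fisher.p_value:.3g}, odds ratio "
        f"{fisher.odds_ratio:.2f}" if fisher.or_defined else "odds ratio undefined"
    )

    out = patients[
        ["patient_id", "apobec_fraction", "apobec_label_patient", "survival_days", "survivor_class"]
    ]
    out.to_csv(RESULTS / "survival_by_group.tsv", sep="\t", index=False)
    print(f"wrote {RESULTS}/survival_by_group.tsv")


if __name__ == "__main__":
    main()
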