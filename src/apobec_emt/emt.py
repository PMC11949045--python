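"""Expression-derived scores: relative fold change, DEG filtering, the
EMT trajectory score and the IL6-correlated gene score.

The EMT trajectory score summarizes differential expression over three
curated gene programs — epithelial, hybrid EMT (hEMT), and mesenchymal.
Per-gene fold changes are averaged within each program; the hEMT and
mesenchymal scores are then reported relative to the epithelial mean, so
a positive value marks a program over-represented versus the epithelial
baseline and a value below zero an under-represented one.

The IL6-correlated gene score sums expression differences (case minus
control, after replicate averaging) over genes co-expressed with IL6,
grouped by cellular function (inflammation, metabolism, cell cycle
control/apoptosis, motility/adhesion, proliferation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EMT_CATEGORIES = ("epithelial", "hEMT", "mesenchymal")
IL6_CATEGORIES = (
    "inflammation",
    "metabolism",
    "cell cycle control/apoptosis",
    "motility/adhesion",
    "proliferation",
)


@dataclass
class GeneSet:
    """A named gene program (EMT phenotype or IL6 functional category)."""

    name: str
    genes: tuple
    category: str | None = None

    def __post_init__(self) -> None:
        genes = tuple(self.genes)
        if not genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(genes)) != len(genes):
            raise ValueError(f"gene set {self.name!r} has duplicate identifiers")
        self.genes = genes

    def __len__(self) -> int:
        return len(self.genes)


def relative_fold_change(sample_value: float, reference_mean: float) -> float:
    """Linear relative fold change: (sample - reference_mean) / reference_mean.

    Bounded below by -1 for non-negative expression; 0 means no change.
    """
    if reference_mean <= 0:
        raise ValueError("reference mean must be positive")
    return (sample_value - reference_mean) / reference_mean


def fold_change_table(
    expr: pd.DataFrame,
    case_samples,
    control_samples,
    log2: bool = False,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-case-sample relative fold change of every gene versus the mean
    of the control samples. Genes whose control mean is zero are dropped
    and tallied in ``.attrs["n_dropped_zero_reference"]``.

    With ``log2=True`` a log2 ratio with a pseudocount is returned instead
    of the linear relative change.
    """
    case = expr[list(case_samples)]
    ref = expr[list(control_samples)].mean(axis=1)
    keep = ref > 0
    dropped = int((~keep).sum())
    case, ref = case[keep], ref[keep]
    if log2:
        fc = np.log2(case.add(pseudocount, axis=0).div(ref + pseudocount, axis=0))
    else:
        fc = case.sub(ref, axis=0).div(ref, axis=0)
    fc.attrs["n_dropped_zero_reference"] = dropped
    return fc


def filter_degs(stats: pd.DataFrame, p_cut: float = 0.01, fc_cut: float = 1.0) -> pd.DataFrame:
    """Keep genes with adjusted_p < p_cut and |fold_change| > fc_cut.

    Both comparisons are strict. Genes lacking an adjusted p-value are
    dropped and counted in ``.attrs["n_dropped_missing_p"]``.
    """
    if not (0 < p_cut <= 1):
        raise ValueError("p_cut must lie in (0, 1]")
    if fc_cut <= 0:
        raise ValueError("fc_cut must be positive")
    df = stats
    missing = df["adjusted_p"].isna()
    kept = df[~missing]
    out = kept[(kept["adjusted_p"] < p_cut) & (kept["fold_change"].abs() > fc_cut)]
    out = out.copy()
    out.attrs["n_dropped_missing_p"] = int(missing.sum())
    out.attrs["n_input"] = len(df)
    out.attrs["n_kept"] = len(out)
    return out


@dataclass
class EMTScore:
    sample_id: str
    epithelial: float
    hEMT: float
    mesenchymal: float
    n_genes_used: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "epithelial": self.epithelial,
            "hEMT": self.hEMT,
            "mesenchymal": self.mesenchymal,
        }


def emt_trajectory_score(
    fold_changes: pd.Series,
    epithelial: GeneSet,
    hemt: GeneSet,
    mesenchymal: GeneSet,
    sample_id: str = "",
) -> EMTScore:
    """EMT trajectory score from per-gene fold changes for one sample.

    epithelial = mean fold change over epithelial genes;
    hEMT = mean(hEMT genes) - mean(epithelial genes);
    mesenchymal = mean(mesenchymal genes) - mean(epithelial genes).

    Genes absent from ``fold_changes`` are skipped and reflected in
    ``n_genes_used``; a category with no gene present yields NaN.
    """
    means, used = {}, {}
    for cat, gs in zip(EMT_CATEGORIES, (epithelial, hemt, mesenchymal)):
        present = [g for g in gs.genes if g in fold_changes.index]
        used[cat] = len(present)
        means[cat] = float(fold_changes[present].mean()) if present else np.nan
    epi = means["epithelial"]
    return EMTScore(
        sample_id=sample_id,
        epithelial=epi,
        hEMT=means["hEMT"] - epi,
        mesenchymal=means["mesenchymal"] - epi,
        n_genes_used=used,
    )


def emt_scores_by_sample(
    fold_changes: pd.DataFrame,
    epithelial: GeneSet,
    hemt: GeneSet,
    mesenchymal: GeneSet,
) -> pd.DataFrame:
    """Apply :func:`emt_trajectory_score` to every column (sample)."""
    rows = [
        emt_trajectory_score(fold_changes[c], epithelial, hemt, mesenchymal, c).as_dict()
        for c in fold_changes.columns
    ]
    return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class IL6Score:
    scores: dict  # category -> summed expression difference
    n_genes_used: dict


def il6_gene_score(
    expr_case: pd.DataFrame,
    expr_control: pd.DataFrame,
    category_sets,
    direction: str = "case_minus_control",
) -> IL6Score:
    """Per-category IL6-correlated gene score.

    For each functional category, replicate expression is averaged per
    gene, summed over member genes, and the control total subtracted from
    the case total — positive means elevated in the case group. Set
    ``direction="control_minus_case"`` for the opposite convention. A
    category with no gene present in both matrices scores NaN.
    """
    if direction not in ("case_minus_control", "control_minus_case"):
        raise ValueError(f"unknown direction {direction!r}")
    case_mean = expr_case.mean(axis=1)
    control_mean = expr_control.mean(axis=1)
    scores, used = {}, {}
    for gs in category_sets:
        present = [
            g for g in gs.genes if g in case_mean.index and g in control_mean.index
        ]
        used[gs.name] = len(present)
        if not present:
            scores[gs.name] = np.nan
            continue
        delta = case_mean[present].sum() - control_mean[present].sum()
        scores[gs.name] = float(delta if direction == "case_minus_control" else -delta)
    return IL6Score(scores=scores, n_genes_used=used)
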