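# apobec-emt

Analysis pipeline linking APOBEC3 mutagenesis to metastasis in high-grade
serous ovarian cancer (HGSOC)-style paired tumor cohorts, with an
expression arm for the downstream epithelial–mesenchymal transition (EMT)
phenotype. It is aimed at cancer-genomics analysts who want the full chain
— somatic SNVs to signature activities to cohort-level conclusions — as a
tested, seedable library rather than a collection of notebook snippets.

## What it computes

**Mutation catalogs.** SNVs (VCF or TSV) plus a reference FASTA become
96-channel trinucleotide catalogs: six pyrimidine substitution classes
(C>A … T>G) × 16 flanking-base pairs, with purine-reference variants
mapped to the reverse-complement strand.

**Signature activities.** Catalogs are refit to a reference signature set
(COSMIC-shaped, channels × signatures) by non-negative least squares,

&nbsp;&nbsp;&nbsp;&nbsp;min<sub>a ≥ 0</sub> ‖v − S a‖₂ ,

giving absolute activities *a* and relative contributions *a*/Σ*a*. The
**APOBEC fraction** of a sample is the relative contribution summed over
the SBS2+SBS13 pair. De novo signatures are extracted by
multiplicative-update NMF minimizing the generalized Kullback–Leibler
divergence, with seeded restarts, and matched to references by optimal
one-to-one cosine assignment.

**Enzyme attribution.** Among SBS2/13-compatible mutations (C>T / C>G at
TpCpA), the base 5′ of the TpC separates APOBEC3A (YTCA, Y = C/T) from
APOBEC3B (RTCA, R = A/G). The attribution statistic is the
background-normalized ratio (ytca/f<sub>YTCA</sub>)/(rtca/f<sub>RTCA</sub>),
with the genomic 4-mer frequencies f computed over both strands.

**Cohort classification.** Samples are APOBEC-high when their fraction
strictly exceeds 4% (or the cohort's upper quartile); paired
primary/metastatic enrichment is the pooled ratio of summed metastatic to
summed primary fractions; survival is summarized per group with a Welch
test, survivor classes use the <3.5-year / >5-year cuts, and 2×2
associations use Fisher's exact test.

**Expression scores.** Per-gene relative fold change
(case − control mean)/control mean feeds the EMT trajectory score
(category means, with the epithelial mean subtracted from the hEMT and
mesenchymal means) and the IL6-correlated gene score (per-function summed
expression difference, case − control).

A synthetic-data module generates every input with full seed control:
random references, variants drawn from known signature mixtures and
placed at context-matching positions, paired cohorts with a planted
metastatic APOBEC fold, YTCA/RTCA-planted processes, and gamma-Poisson
expression with planted gene-set shifts.

## Worked example

```python
import numpy as np
from apobec_emt import (
    simulate_cohort, paired_enrichment, group_survival_summary,
)
from apobec_emt.pipeline import fit_cohort_fractions

sim = simulate_cohort(20, base_apobec=0.01, met_fold=6.0,
                      n_mutations=5000, seed=1)
table, exposures = fit_cohort_fractions(sim)
enr = paired_enrichment(table)
print(f"pooled met/primary APOBEC ratio: {enr.pooled_ratio:.2f}")
print(table[['sample_id', 'apobec_fraction', 'apobec_label']].head(4))
```

```
pooled met/primary APOBEC ratio: 6.61
  sample_id  apobec_fraction apobec_label
0   PT001_P         0.008281          low
1   PT001_M         0.060176         high
2   PT002_P         0.011639          low
3   PT002_M         0.058171         high
```

Each patient's metastatic sample carries the planted 6-fold APOBEC
increase (primary ≈ 1%, metastatic ≈ 6%), the NNLS refit recovers it from
the mutation catalogs alone, and the pooled ratio lands near the planted
fold of 6.

## The analysis

Numbered drivers under `analysis/` replay the full study on synthetic
cohorts and write their tables to `results/` (bulky intermediates go to
`scratch/`):

1. `01_simulate_cohort.py` — 35 paired patients, planted 6-fold metastatic
   APOBEC enrichment, survival tied to APOBEC group.
2. `02_fit_signatures.py` — catalogs, NNLS exposures, APOBEC fractions,
   pooled enrichment.
3. `03_denovo_signatures.py` — KL-NMF extraction on the cohort (negative
   control) and on a cell-line-style design where it cleanly separates the
   APOBEC spectrum.
4. `04_enzyme_attribution.py` — planted YTCA/RTCA processes recovered as
   A3A-like / A3B-like.
5. `05_survival_association.py` — survival means by APOBEC group,
   short/long survivor association (Fisher).
6. `06_emt_il6_scores.py` — planted EMT program shifts and IL6-function
   scores.

A CLI mirrors the pipeline stages (`apobec-emt simulate | catalog | fit |
extract | attribute | classify | emt-score | il6-score`).

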