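# Methods

This note documents the models behind `apobec_emt`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that affect results.

## Mutation catalogs

Somatic SNVs are classified into the standard 96 single-base-substitution
channels. Coordinates are 1-based and fully closed (VCF convention). A
variant whose reference base is a purine is reverse-complemented —
substitution and flanking context together — so every channel is written
with a C or T at the mutated position. Channel order is the de facto
standard layout: substitution classes C>A, C>G, C>T, T>A, T>C, T>G, and
within each class the 5′ flank varies slowest, both flanks in A,C,G,T
order.

Variants are never silently dropped: reference-mismatch, off-contig
windows, non-ACGT bases and multi-allelic leftovers are tallied per
reason in a skip report attached to the catalog. The production builder
is vectorized over encoded contigs; a naive per-variant implementation is
kept in the package (`build_catalog_naive`) purely as an oracle and is
asserted equal to the fast path in the tests.

Raw counts are used; no exome/genome opportunity renormalization is
applied by default because the analyses here compare relative
contributions within one platform. A per-channel opportunity weighting
hook would slot in at the signature-matrix level if needed.

## Signature refitting (NNLS)

Per sample, activities solve min‖v − S a‖₂ subject to a ≥ 0 (classic
non-negative least squares via `scipy.optimize.nnls`). Squared error was
chosen over a KL refit because it is the standard fit-to-signatures
behavior, is convex with a unique solution for linearly independent
reference columns, and admits an exhaustive independent oracle: on the
simplex of relative weights the optimal activity scale has a closed form,
so for ≤ 3 signatures a 10⁻³-step grid enumeration searches exactly the
NNLS objective and must agree with the solver (asserted within 2 × 10⁻³).

Relative contributions are activities divided by their per-sample total;
an all-zero sample gets zero activities and a missing (NaN) relative row
rather than an arbitrary renormalization. Refitting to a large reference
set is known to overfit, so an optional backward-elimination mode
(`prune_reference`) drops signatures whose removal changes the mean
cosine-to-data by < 0.01; it is off by default.

The shipped reference set (`example_signatures`) is a synthetic stand-in:
five COSMIC-shaped channel distributions — an APOBEC-like SBS2/SBS13 pair
(C>T and C>G at TpC), a CpG-deamination clock profile, a flat background
and an oxidative C>A profile — built in code with a small uniform floor
(4%) for realism. Pairwise cosines stay below 0.4, which is what makes
the recovery benchmarks meaningful. Any user-supplied COSMIC-format TSV
can be used instead.

## De novo extraction (KL-NMF)

`nmf_extract` implements multiplicative updates for the generalized
Kullback–Leibler divergence (the objective a Poisson count model
implies), with defaults of 20 random restarts, 2,000 iterations maximum
and a relative-improvement tolerance of 10⁻⁶. The restart with the lowest
final objective wins; the objective trace is recorded and must be
non-increasing (the tests allow 10⁻⁸ relative numerical slack).
Signature columns are renormalized to sum to 1 with the scale folded into
exposures, so exposures stay in mutation units. Rank is always
user-supplied; nothing auto-selects it. scikit-learn's KL-NMF serves as
an independent cross-check in the tests (our objective must be at least
as good within 2%), never as the implementation.

A practical finding reproduced by `analysis/03_denovo_signatures.py`:
rank-2 extraction on a cohort whose APOBEC burden is a few percent of all
mutations recovers background structure, not the APOBEC process. The
process only separates cleanly when APOBEC activity varies strongly
across samples (the cell-line-style design, activity spanning 0–90%).
Refitting, not extraction, is the right tool for low-burden cohorts.

## YTCA/RTCA enzyme attribution

Qualifying mutations are C>T or C>G at a TpCpA trinucleotide after
pyrimidine normalization — the substitution composition of SBS2/13. The
base 5′ of the T assigns YTCA (Y = C/T, APOBEC3A-like) or RTCA (R = A/G,
APOBEC3B-like); an edge or ambiguous 5′ base is tallied separately. The
statistic is the background-normalized ratio
(ytca/f_YTCA)/(rtca/f_RTCA), where the f are genomic 4-mer frequencies
counted over both strands (each window contributes once per strand).
This is the simplest statistic consistent with the Y/R dichotomy; it is
not a full A3A/A3B deconvolution, and no published enrichment formula is
claimed.

Defaults: minimum 20 informative mutations (below which the call is
indeterminate) and a decision margin of 0.10 — A3A-like above 1.1,
A3B-like below 1/1.1. Both guard against calls from noise and are
configurable. A zero denominator yields an infinite-ratio sentinel; the
label is still assigned when support suffices. Per-sample and pooled
modes are both available since either aggregation is defensible.

## Cohort classification and survival

APOBEC-high means the SBS2+SBS13 fraction strictly exceeds the threshold
— fixed 4% by default, or the cohort's 75th percentile in upper-quartile
mode (ties therefore classify low). Patient-level labels follow the
metastatic sample by default, with a `label_site="max"` alternative,
because the high/low definition is anchored to metastatic tumors.

Paired enrichment reports both a pooled ratio (sum of metastatic
fractions over sum of primary fractions — robust to zero-fraction
primaries, which stay in the sums) and per-patient ratios (geometric
mean over patients where the primary fraction is positive; zero-primary
patients are flagged undefined rather than imputed).

Survivor classes use strict cuts at 3.5 and 5 years with 365.25
days/year. Survival comparison is a difference of group means with a
Welch (unequal-variance) t-test; no censoring model is fitted because
the summaries being mirrored are plain group averages. Fisher's exact
test (two-sided, hypergeometric) handles 2×2 associations; the odds
ratio uses the Haldane 0.5 correction when a cell is zero and is flagged
undefined for a degenerate margin.

## Expression scores

The fold change is the linear relative change
(case − control mean)/control mean, bounded below by −1; a log2 option
exists but is not the default because the downstream score formulas are
stated on the linear scale. Genes with a zero control mean are dropped
and counted, never imputed. DEG filtering keeps genes with adjusted
P < p_cut AND |fold change| > fc_cut, both strict; genes lacking an
adjusted P are dropped and reported. Differential-expression model
fitting itself (DESeq2-style NB GLMs) is out of scope — the package
consumes expression matrices or precomputed statistics.

EMT trajectory score: per-category mean of per-gene fold changes, with
the epithelial mean subtracted from the hEMT and mesenchymal means, so
values below zero mark under-represented programs. Missing genes are
skipped and counted (`n_genes_used`); zeros are never imputed because
they would bias the epithelial-subtracted differences.

IL6-correlated gene score: replicate expression is averaged per gene
first, then summed over the genes of each functional category
(inflammation, metabolism, cell cycle control/apoptosis,
motility/adhesion, proliferation), and the control total is subtracted
from the case total. The sign convention (positive = elevated in the
case group) matches the direction in which the underlying biology is
reported — IL-6 secretion increases with A3A exposure — and a
`direction` switch provides the opposite convention, since the verbal
description of the subtraction order is ambiguous.

The shipped gene-set machinery (`assign_gene_sets`) carves disjoint
random sets out of a synthetic gene universe; these are stand-ins for
the curated epithelial/hEMT/mesenchymal and IL6-coexpression lists,
which are not reproduced. Real GMT files drop in unchanged.

## Synthetic-data generator

The generator is the ground-truth side of every benchmark.

- **References**: i.i.d. bases at a target GC (default 45%, human-like);
  contig lengths partition the requested total. 100 kb is the default
  working size — large enough that all 32 trinucleotide context classes
  have hundreds of supporting positions.
- **Variants**: the 96-channel signature is sampled multinomially, then
  each mutation is placed uniformly among genomic positions whose
  pyrimidine-normalized context matches the drawn channel (precomputed
  context index). This guarantees catalog/truth consistency by
  construction. Channels with no genomic support are resampled by
  renormalizing over supported channels; generation fails only if no
  positive-probability channel has support. Positions are drawn with
  replacement, so recurrent positions can occur (harmless for catalogs).
- **Paired cohorts**: per patient, the metastatic APOBEC weight is
  min(1, primary × fold), clamps recorded. The APOBEC weight is split
  evenly over SBS2/SBS13 and the remainder evenly over the background
  signatures. `base_apobec` accepts a scalar (exact-construction
  benchmarks) or per-patient values (heterogeneous cohorts). Defaults:
  5,000 mutations/sample — chosen for recovery power, since real
  per-sample exome counts for such cohorts are not published — and a
  planted fold of 6. Survival is normal with a floor at 1 day,
  conditioned on the truth label (metastatic weight above the 4%
  threshold), with default group means of 816.7 / 1,655.3 days and sd
  200 — the simplest model recoverable from group averages.
- **YTCA/RTCA processes**: positions restricted to the requested 4-mer
  class; substitutions C>T with probability 0.7, else C>G, mirroring the
  SBS2/13 composition.
- **Expression**: gamma-Poisson (negative binomial, variance
  μ + αμ²) with a common dispersion α; α → 0 recovers Poisson. NB is
  the standard bulk RNA-seq count assumption; nothing about the real
  data's noise is claimed. Control genes share one base mean; planted
  sets are scaled multiplicatively in the case group.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: real trinucleotide composition (i.i.d. bases
have no CpG suppression or isochores), exome capture territory, tumor
purity and subclonality, signature profile uncertainty (the stand-in
signatures are cleaner and better separated than COSMIC's), correlated
gene-gene expression structure, library-size variation, and censored
survival. Recovery benchmarks here are best-case calibrations of the
estimators, not claims about cohort data.

## Numerical choices and degenerate inputs

- NMF guards denominators and the KL log with ε = 10⁻¹²; 0·log 0 = 0.
- NNLS residuals are reported relative to the catalog L2 norm; cosine to
  data is also reported since it is scale-free.
- Cosine similarity raises on zero vectors rather than returning 0.
- Assignment matching uses `scipy.optimize.linear_sum_assignment` on the
  negated cosine matrix; pairs under a 0.75 reporting floor are flagged
  unassigned but still listed.
- The simplex grid oracle is chunked (50,000 points/block) to bound
  memory at the 10⁻³ step for three signatures.
- Seeds: every public generator takes an integer seed; internal
  sub-seeds are drawn from `numpy.random.default_rng(seed)` and kept
  below 2³¹.

## Problem sizes used in the test and acceptance runs

Catalog oracle: 1,000 variants on 100 kb. Exposure recovery: 20 samples
× 5,000 mutations, 5 signatures. NMF recovery: 30 samples × 5,000.
Enrichment: 50 replicates of 20 patients × 2 × 5,000 (tests) and a
20-replicate median (acceptance script). Attribution: 20 runs per
planted flavor at 60–100 informative mutations. Expression: 400–2,000
genes, 10–12 samples, 50 replicates for rate estimates. These sizes give
each estimator comfortable recovery margins while keeping a full run in
minutes on one CPU.

## Known limitations

- The attribution statistic is a ratio test, not a mixture model; it
  cannot apportion mixed A3A+A3B activity.
- No bootstrap confidence intervals on per-sample exposures (left as a
  hook).
- Upper-quartile thresholding is computed on whatever fractions are
  passed; the caller decides the anchoring population (all samples vs
  metastatic only).
- The EMT score weights every gene equally within a category; no
  variance stabilization is applied to fold changes.
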