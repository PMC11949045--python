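"""Synthetic data generation for the whole pipeline.

Everything the analysis consumes can be generated here with full seed
control: random references, variant sets drawn from known signature
mixtures (multinomial over the 96 channels, placed at genomic positions
whose context matches the drawn channel), paired primary/metastatic
cohorts with a planted metastatic APOBEC enrichment and survival
structure, YTCA/RTCA-planted APOBEC processes, and overdispersed
count-like expression matrices with planted gene-set shifts.

Every simulated object carries its generating truth; truth fields are
recorded at generation time, never inferred afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import cohort as cohort_mod
from .catalog import BASES, CHANNELS_96, VariantRecord, encode_sequence
from .emt import GeneSet
from .signatures import APOBEC_SIGNATURES, SignatureMatrix

_ALT_CODE_OF_SUB = np.array([0, 2, 3, 0, 1, 2], dtype=np.int8)  # A,G,T,A,C,G
_COMP = np.array([3, 2, 1, 0], dtype=np.int8)


@dataclass
class SyntheticReference:
    """A random reference: named contigs over {A,C,G,T} at a target GC."""

    contigs: dict
    gc_fraction: float

    def __post_init__(self) -> None:
        for name, seq in self.contigs.items():
            if len(seq) < 3:
                raise ValueError(f"contig {name!r} shorter than 3 bases")
            if set(seq) - set(BASES):
                raise ValueError(f"contig {name!r} has bases outside ACGT")

    def observed_gc(self) -> float:
        gc = total = 0
        for seq in self.contigs.values():
            gc += seq.count("G") + seq.count("C")
            total += len(seq)
        return gc / total


def make_reference(
    total_length: int, gc_fraction: float, n_contigs: int = 1, seed: int = 0
) -> SyntheticReference:
    """Generate a random reference whose contig lengths partition
    ``total_length`` and whose base composition targets ``gc_fraction``."""
    if total_length <= 0 or n_contigs <= 0:
        raise ValueError("total_length and n_contigs must be positive")
    if total_length < 3 * n_contigs:
        raise ValueError("need at least 3 bases per contig")
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_fraction) / 2, gc_fraction / 2, gc_fraction / 2, (1 - gc_fraction) / 2]
    )
    lengths = [total_length // n_contigs] * n_contigs
    for i in range(total_length % n_contigs):
        lengths[i] += 1
    contigs = {}
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i, L in enumerate(lengths):
        codes = rng.choice(4, size=L, p=p)
        contigs[f"chr{i + 1}"] = bases[codes].tobytes().decode("ascii")
    return SyntheticReference(contigs=contigs, gc_fraction=gc_fraction)


class ContextIndex:
    """Positions of every pyrimidine-normalized trinucleotide context.

    Context id = 16 * (0 for center C, 1 for center T) + 4 * f5 + f3 with
    flanks coded A=0..T=3 in normalized orientation. For each context the
    index stores contig ids, 0-based positions, and the plus-strand base
    code at the position (the pyrimidine itself or its purine complement).
    """

    def __init__(self, reference: SyntheticReference | Mapping[str, str]):
        contigs = reference.contigs if hasattr(reference, "contigs") else reference
        self.contig_names = list(contigs)
        buckets = {k: ([], [], []) for k in range(32)}
        for ci, name in enumerate(self.contig_names):
            code = encode_sequence(contigs[name])
            if len(code) < 3:
                continue
            l, c, r = code[:-2], code[1:-1], code[2:]
            valid = (l >= 0) & (c >= 0) & (r >= 0)
            pyr = valid & ((c == 1) | (c == 3))
            pur = valid & ((c == 0) | (c == 2))
            ctx = np.full(len(c), -1, dtype=np.int64)
            ctx[pyr] = (c[pyr] == 3) * 16 + l[pyr] * 4 + r[pyr]
            ctx[pur] = (c[pur] == 0) * 16 + _COMP[r[pur]] * 4 + _COMP[l[pur]]
            pos = np.arange(1, len(code) - 1)
            for k in range(32):
                sel = ctx == k
                if sel.any():
                    buckets[k][0].append(np.full(int(sel.sum()), ci, dtype=np.int32))
                    buckets[k][1].append(pos[sel].astype(np.int64))
                    buckets[k][2].append(c[sel].astype(np.int8))
        self._index = {}
        for k, (cis, poss, cents) in buckets.items():
            if cis:
                self._index[k] = (
                    np.concatenate(cis),
                    np.concatenate(poss),
                    np.concatenate(cents),
                )

    def support(self, ctx: int) -> int:
        entry = self._index.get(ctx)
        return 0 if entry is None else len(entry[1])

    def draw(self, ctx: int, k: int, rng: np.random.Generator):
        cis, poss, cents = self._index[ctx]
        pick = rng.integers(0, len(poss), size=k)
        return cis[pick], poss[pick], cents[pick]


def _context_of_channel(channel: int) -> int:
    sub, flank = divmod(channel, 16)
    return (0 if sub < 3 else 1) * 16 + flank


def sample_variants(
    reference: SyntheticReference,
    signature,
    n: int,
    seed: int = 0,
    sample_id: str = "S1",
    index: ContextIndex | None = None,
) -> list[VariantRecord]:
    """Draw ``n`` SNVs whose 96-channel spectrum follows ``signature``.

    Channels are drawn multinomially, then each mutation is placed
    uniformly among genomic positions whose pyrimidine-normalized context
    matches the channel, guaranteeing that rebuilding the catalog from the
    returned variants reproduces the channels drawn. Channels without any
    supporting genomic position are resampled (the signature is
    renormalized over supported channels).
    """
    sig = np.asarray(signature, dtype=float).ravel()
    if sig.shape != (96,) or (sig < 0).any() or not np.isclose(sig.sum(), 1.0, atol=1e-6):
        raise ValueError("signature must be a 96-channel probability vector")
    if n < 1:
        raise ValueError("n must be a positive integer")
    idx = index if index is not None else ContextIndex(reference)
    supported = np.array(
        [idx.support(_context_of_channel(c)) > 0 for c in range(96)], dtype=bool
    )
    p = np.where(supported, sig, 0.0)
    if p.sum() <= 0:
        raise RuntimeError(
            "no genomic position supports any positive-probability channel"
        )
    rng = np.random.default_rng(seed)
    counts = rng.multinomial(n, p / p.sum())
    records: list[VariantRecord] = []
    for chan in np.flatnonzero(counts):
        k = int(counts[chan])
        cis, poss, cents = idx.draw(_context_of_channel(chan), k, rng)
        alt_norm = _ALT_CODE_OF_SUB[chan // 16]
        purine = (cents == 0) | (cents == 2)
        alts = np.where(purine, _COMP[alt_norm], alt_norm)
        for ci, pos0, cent, alt in zip(cis, poss, cents, alts):
            records.append(
                VariantRecord(
                    sample_id=sample_id,
                    chrom=idx.contig_names[ci],
                    pos=int(pos0) + 1,
                    ref_base=BASES[cent],
                    alt_base=BASES[alt],
                )
            )
    return records


def sample_tca_variants(
    reference: SyntheticReference,
    n: int,
    flavor: str = "ytca",
    seed: int = 0,
    sample_id: str = "S1",
    ct_fraction: float = 0.7,
) -> list[VariantRecord]:
    """Plant an APOBEC process with a fixed tetranucleotide preference.

    ``flavor`` selects mutated-cytosine positions whose normalized 4-mer
    context is YTCA (A3A-like generator), RTCA (A3B-like), or any TCA
    (``uniform_tca``, sampling positions uniformly so the YTCA:RTCA split
    follows the genome's own content). Substitutions are C>T with
    probability ``ct_fraction``, else C>G, mirroring SBS2/13 composition.
    """
    if flavor not in ("ytca", "rtca", "uniform_tca"):
        raise ValueError(f"unknown flavor {flavor!r}")
    if n < 1:
        raise ValueError("n must be a positive integer")
    rng = np.random.default_rng(seed)
    names, codes = [], []
    for name, seq in reference.contigs.items():
        names.append(name)
        codes.append(encode_sequence(seq))
    pool_ci, pool_pos, pool_cent = [], [], []
    for ci, code in enumerate(codes):
        if len(code) < 5:
            continue
        pos = np.arange(2, len(code) - 2)
        c = code[pos]
        l1, r1 = code[pos - 1], code[pos + 1]
        # plus-strand C in T-C-A, or plus-strand G in T-G-A (revcomp T-C-A)
        is_c = (c == 1) & (l1 == 3) & (r1 == 0)
        is_g = (c == 2) & (l1 == 3) & (r1 == 0)
        five = np.full(len(pos), -1, dtype=np.int8)
        five[is_c] = code[pos - 2][is_c]
        five[is_g] = _COMP[code[pos + 2][is_g]]
        if flavor == "ytca":
            sel = (is_c | is_g) & ((five == 1) | (five == 3))
        elif flavor == "rtca":
            sel = (is_c | is_g) & ((five == 0) | (five == 2))
        else:
            sel = is_c | is_g
        if sel.any():
            pool_ci.append(np.full(int(sel.sum()), ci, dtype=np.int32))
            pool_pos.append(pos[sel])
            pool_cent.append(c[sel])
    if not pool_ci:
        raise RuntimeError(f"reference has no {flavor} positions")
    pool_ci = np.concatenate(pool_ci)
    pool_pos = np.concatenate(pool_pos)
    pool_cent = np.concatenate(pool_cent)
    pick = rng.integers(0, len(pool_pos), size=n)
    is_ct = rng.random(n) < ct_fraction
    records = []
    for j, i in enumerate(pick):
        cent = pool_cent[i]
        alt_norm = 3 if is_ct[j] else 2  # T or G on the normalized strand
        alt = _COMP[alt_norm] if cent == 2 else alt_norm
        records.append(
            VariantRecord(
                sample_id=sample_id,
                chrom=names[pool_ci[i]],
                pos=int(pool_pos[i]) + 1,
                ref_base=BASES[cent],
                alt_base=BASES[alt],
            )
        )
    return records


def example_signatures(floor: float = 0.04) -> SignatureMatrix:
    """A synthetic stand-in reference signature set.

    Five COSMIC-shaped but synthetic channel distributions: an
    APOBEC-like pair (SBS2-like C>T at TpC, SBS13-like C>G at TpC), a
    clock-like CpG deamination profile (SBS1-like), a flat background
    (SBS5-like), and an oxidative C>A profile (SBS18-like). The names
    follow the signatures they emulate; the distributions are synthetic
    and mutually well separated, not the COSMIC v3.2 vectors.
    """

    def channel(sub: int, f5: int, f3: int) -> int:
        return sub * 16 + f5 * 4 + f3

    base = floor / 96 * np.ones(96)
    sigs = {}
    v = base.copy()
    for f3, w in zip(range(4), (0.38, 0.12, 0.15, 0.31)):  # T[C>T]N
        v[channel(2, 3, f3)] += (1 - floor) * w
    sigs["SBS2"] = v
    v = base.copy()
    for f3, w in zip(range(4), (0.35, 0.12, 0.12, 0.35)):  # T[C>G]N
        v[channel(1, 3, f3)] += (1 - floor) * 0.94 * w
    for f3 in range(4):  # minor T[C>A]N component
        v[channel(0, 3, f3)] += (1 - floor) * 0.06 * 0.25
    sigs["SBS13"] = v
    v = base.copy()
    for f5 in range(4):  # N[C>T]G, CpG deamination
        v[channel(2, f5, 2)] += (1 - floor) * 0.25
    sigs["SBS1"] = v
    tilt = 1 + 0.3 * np.sin(np.arange(96) * 0.7)  # flat-ish, deterministic
    sigs["SBS5"] = tilt / tilt.sum()
    v = base.copy()
    for f5 in range(4):
        for f3, w in zip(range(4), (0.4, 0.15, 0.15, 0.3)):  # N[C>A]N
            v[channel(0, f5, f3)] += (1 - floor) * 0.25 * w
    sigs["SBS18"] = v
    frame = pd.DataFrame(sigs, index=list(CHANNELS_96))
    frame = frame / frame.sum(axis=0)
    return SignatureMatrix(frame)


@dataclass
class MixtureTruth:
    """Known signature weights behind a set of simulated samples."""

    signature_names: list
    weights: pd.DataFrame  # samples x signatures, rows sum to 1
    n_mutations: pd.Series

    def __post_init__(self) -> None:
        w = self.weights.to_numpy(dtype=float)
        if (w < -1e-12).any() or not np.allclose(w.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("weights must be non-negative and sum to 1 per sample")
        if (self.n_mutations < 1).any():
            raise ValueError("n_mutations must be >= 1")


def mixture_distribution(signatures: SignatureMatrix, weights: Mapping[str, float]) -> np.ndarray:
    """The 96-channel distribution of a signature mixture."""
    S = signatures.profiles[list(weights)].to_numpy(dtype=float)
    w = np.array(list(weights.values()), dtype=float)
    return S @ w


@dataclass
class SimulatedCohort:
    """A paired primary/metastatic cohort with full generating truth."""

    reference: SyntheticReference
    variants: list  # VariantRecord for every sample
    truth: pd.DataFrame  # one row per patient
    samples: pd.DataFrame  # one row per sample: sample/patient/site/survival
    signatures: SignatureMatrix
    apobec_names: tuple
    threshold: float


def simulate_cohort(
    n_patients: int,
    base_apobec,
    met_fold: float,
    background_signatures: SignatureMatrix | None = None,
    n_mutations: int = 5000,
    survival_model: Mapping[str, float] | None = None,
    threshold: float = cohort_mod.DEFAULT_THRESHOLD,
    seed: int = 0,
    reference: SyntheticReference | None = None,
    apobec_names: Sequence[str] = APOBEC_SIGNATURES,
) -> SimulatedCohort:
    """Simulate a paired cohort with a planted metastatic APOBEC fold.

    Each patient gets a primary and a metastatic variant set of
    ``n_mutations`` SNVs. The primary APOBEC weight is ``base_apobec``
    (scalar, or one value per patient); the metastatic weight is
    ``min(1, primary * met_fold)`` with the clamp recorded. The APOBEC
    weight is split evenly over the designated APOBEC-like pair and the
    remainder evenly over the other signatures. Survival is drawn from a
    normal model conditioned on the truth label (metastatic APOBEC weight
    strictly above ``threshold``), floored at 1 day.
    """
    if met_fold <= 0:
        raise ValueError("met_fold must be positive")
    if n_patients < 1:
        raise ValueError("n_patients must be positive")
    sigs = background_signatures if background_signatures is not None else example_signatures()
    names = sigs.names
    missing = set(apobec_names) - set(names)
    if missing:
        raise ValueError(f"APOBEC signatures absent from reference set: {sorted(missing)}")
    others = [s for s in names if s not in apobec_names]
    if not others:
        raise ValueError("need at least one non-APOBEC background signature")
    model = dict(survival_model or {"mean_days_high": 816.7, "mean_days_low": 1655.3, "sd": 200.0})
    base = np.broadcast_to(np.asarray(base_apobec, dtype=float), (n_patients,)).copy()
    if ((base < 0) | (base > 1)).any():
        raise ValueError("base_apobec weights must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if reference is None:
        reference = make_reference(100_000, 0.45, 1, seed=int(rng.integers(2**31 - 1)))
    index = ContextIndex(reference)

    variants: list[VariantRecord] = []
    truth_rows, sample_rows = [], []
    for p in range(n_patients):
        patient = f"PT{p + 1:03d}"
        w_primary = float(base[p])
        w_met_raw = w_primary * met_fold
        clamped = w_met_raw > 1
        w_met = min(1.0, w_met_raw)
        site_weights = {"primary": w_primary, "metastatic": w_met}
        label = "high" if w_met > threshold else "low"
        mean = model["mean_days_high"] if label == "high" else model["mean_days_low"]
        survival = max(1.0, float(rng.normal(mean, model["sd"])))
        for site, w in site_weights.items():
            weights = {s: 0.0 for s in names}
            for a in apobec_names:
                weights[a] = w / len(apobec_names)
            for o in others:
                weights[o] = (1 - w) / len(others)
            mix = mixture_distribution(sigs, weights)
            sid = f"{patient}_{'P' if site == 'primary' else 'M'}"
            variants.extend(
                sample_variants(
                    reference,
                    mix,
                    n_mutations,
                    seed=int(rng.integers(2**31 - 1)),
                    sample_id=sid,
                    index=index,
                )
            )
            sample_rows.append(
                {
                    "sample_id": sid,
                    "patient_id": patient,
                    "site": site,
                    "survival_days": survival,
                    "true_apobec_weight": w,
                    "true_weights": weights,
                }
            )
        truth_rows.append(
            {
                "patient_id": patient,
                "primary_apobec": w_primary,
                "metastatic_apobec": w_met,
                "met_fold": met_fold,
                "clamped": clamped,
                "survival_days": survival,
                "apobec_truth_label": label,
                "survivor_class_truth": cohort_mod.survivor_class(survival),
            }
        )
    return SimulatedCohort(
        reference=reference,
        variants=variants,
        truth=pd.DataFrame(truth_rows),
        samples=pd.DataFrame(sample_rows),
        signatures=sigs,
        apobec_names=tuple(apobec_names),
        threshold=threshold,
    )


@dataclass
class PlantedExpression:
    """Count-like expression with known multiplicative gene-set shifts."""

    matrix: pd.DataFrame  # genes x samples
    group_labels: pd.Series  # sample -> {case, control}
    effect_table: dict  # gene-set name -> fold applied in the case group
    dispersion: float
    gene_sets: list = field(default_factory=list)

    @property
    def case_samples(self) -> list:
        return list(self.group_labels[self.group_labels == "case"].index)

    @property
    def control_samples(self) -> list:
        return list(self.group_labels[self.group_labels == "control"].index)


def assign_gene_sets(
    genes: Sequence[str],
    sizes: Mapping[str, int],
    seed: int = 0,
    categories: Mapping[str, str] | None = None,
) -> list[GeneSet]:
    """Carve disjoint random gene sets of the requested sizes out of a
    gene universe (a synthetic stand-in for curated program lists)."""
    total = sum(sizes.values())
    if total > len(genes):
        raise ValueError("gene universe too small for requested set sizes")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(genes), size=total, replace=False)
    out, at = [], 0
    for name, size in sizes.items():
        members = tuple(genes[i] for i in chosen[at : at + size])
        at += size
        out.append(
            GeneSet(name=name, genes=members, category=(categories or {}).get(name, name))
        )
    return out


def simulate_expression(
    n_genes: int,
    n_case: int,
    n_control: int,
    gene_sets: Sequence[GeneSet] = (),
    effects: Mapping[str, float] | None = None,
    base_mean: float = 100.0,
    dispersion: float = 0.1,
    seed: int = 0,
) -> PlantedExpression:
    """Gamma-Poisson (negative binomial) expression with planted shifts.

    Every gene has mean ``base_mean`` in controls; genes belonging to a
    set named in ``effects`` have their case-group mean multiplied by the
    set's fold. ``dispersion`` is the NB overdispersion (variance =
    mean + dispersion * mean^2); zero gives pure Poisson noise.
    """
    if base_mean <= 0 or dispersion < 0:
        raise ValueError("base_mean must be positive and dispersion non-negative")
    effects = dict(effects or {})
    genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    by_name = {gs.name: gs for gs in gene_sets}
    unknown_sets = set(effects) - set(by_name)
    if unknown_sets:
        raise ValueError(f"effects name unknown gene sets: {sorted(unknown_sets)}")
    universe = set(genes)
    for gs in gene_sets:
        stray = set(gs.genes) - universe
        if stray:
            raise ValueError(f"gene set {gs.name!r} has genes outside the universe: {sorted(stray)[:5]}")
    rng = np.random.default_rng(seed)
    samples = [f"case_{i + 1}" for i in range(n_case)] + [
        f"control_{i + 1}" for i in range(n_control)
    ]
    labels = pd.Series(["case"] * n_case + ["control"] * n_control, index=samples)
    mean = np.full((n_genes, n_case + n_control), float(base_mean))
    gene_pos = {g: i for i, g in enumerate(genes)}
    for set_name, fold in effects.items():
        rows = [gene_pos[g] for g in by_name[set_name].genes]
        mean[np.ix_(rows, range(n_case))] *= fold
    if dispersion > 0:
        lam = rng.gamma(shape=1.0 / dispersion, scale=mean * dispersion)
    else:
        lam = mean
    counts = rng.poisson(lam)
    matrix = pd.DataFrame(counts, index=genes, columns=samples)
    return PlantedExpression(
        matrix=matrix,
        group_labels=labels,
        effect_table=effects,
        dispersion=dispersion,
        gene_sets=list(gene_sets),
    )
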