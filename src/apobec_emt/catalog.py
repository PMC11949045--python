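"""Pyrimidine-normalized 96-channel trinucleotide mutation catalogs.

Somatic single-nucleotide variants are classified into the standard 96
single-base-substitution channels: six pyrimidine substitution classes
(C>A, C>G, C>T, T>A, T>C, T>G) crossed with the 16 combinations of 5'
and 3' flanking bases. Variants whose reference base is a purine are
mapped to the reverse-complement strand first, so every channel is
reported with a C or T at the mutated position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: substitution classes in the conventional catalog order
SUBSTITUTION_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: the 96 channel labels, e.g. "A[C>A]A": substitution class major,
#: then 5' flank, then 3' flank, each in A,C,G,T order
CHANNELS_96 = tuple(
    f"{f5}[{sub}]{f3}"
    for sub in SUBSTITUTION_CLASSES
    for f5 in BASES
    for f3 in BASES
)

CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}

# encoded complement: A<->T, C<->G under the 0..3 encoding
_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.int8)

# substitution-class index for (pyrimidine ref code, alt code); -1 invalid
_SUB_OF = -np.ones((4, 4), dtype=np.int8)
for _alt, _cls in ((0, 0), (2, 1), (3, 2)):  # C>A, C>G, C>T
    _SUB_OF[1, _alt] = _cls
for _alt, _cls in ((0, 3), (1, 4), (2, 5)):  # T>A, T>C, T>G
    _SUB_OF[3, _alt] = _cls


class VariantRecord(NamedTuple):
    """A single-sample somatic SNV in 1-based VCF-style coordinates."""

    sample_id: str
    chrom: str
    pos: int
    ref_base: str
    alt_base: str


@dataclass
class SkipReport:
    """Per-reason tally of variants excluded during catalog construction."""

    ref_mismatch: int = 0
    out_of_bounds: int = 0
    not_snv: int = 0
    ambiguous_context: int = 0
    records: list = field(default_factory=list)

    @property
    def total(self) -> int:
        return (
            self.ref_mismatch
            + self.out_of_bounds
            + self.not_snv
            + self.ambiguous_context
        )


@dataclass
class MutationCatalog:
    """Per-sample counts over the 96 substitution channels.

    ``counts`` is a 96 x n_samples DataFrame indexed by :data:`CHANNELS_96`.
    """

    counts: pd.DataFrame
    skipped: SkipReport | None = None

    def __post_init__(self) -> None:
        if list(self.counts.index) != list(CHANNELS_96):
            raise ValueError("catalog rows must be the 96 channels in standard order")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy(dtype=float)

    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def frequencies(self) -> pd.DataFrame:
        """Per-sample channel counts renormalized to sum to 1."""
        tot = self.counts.sum(axis=0)
        if (tot == 0).any():
            raise ValueError("cannot normalize an all-zero sample")
        return self.counts / tot


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a contig as int8 codes A=0,C=1,G=2,T=3; other bases -> -1."""
    table = np.full(256, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        table[ord(b)] = i
        table[ord(b.lower())] = i
    return table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def as_contig_map(reference) -> Mapping[str, str]:
    """Accept a plain ``{name: sequence}`` mapping, a SyntheticReference,
    or a pyfaidx.Fasta, and return a ``{name: str}`` view."""
    contigs = getattr(reference, "contigs", None)
    if isinstance(contigs, Mapping):
        return contigs
    if isinstance(reference, Mapping):
        first = next(iter(reference.values()), "")
        if isinstance(first, str):
            return reference
    # pyfaidx.Fasta and similar: keyed access to sequence-like records
    return {name: str(reference[name][:]) for name in reference.keys()}


def extract_context(reference, chrom: str, pos: int, flank5: int = 1, flank3: int = 1) -> str:
    """Return the uppercase sequence window of ``flank5 + 1 + flank3`` bases
    centered on the 1-based position ``pos``.

    Raises IndexError when the window runs off either contig end.
    """
    seq = as_contig_map(reference)[chrom]
    start = pos - 1 - flank5
    end = pos + flank3
    if start < 0 or end > len(seq):
        raise IndexError(
            f"context window [{start + 1}, {end}] off contig {chrom!r} (length {len(seq)})"
        )
    return seq[start:end].upper()


def pyrimidine_normalize(ref_base: str, alt_base: str, context: str) -> tuple[str, str]:
    """Map a substitution and its context onto the pyrimidine strand.

    Returns ``(substitution_class, normalized_context)`` where the class is
    one of C>A,...,T>G and the context is reverse-complemented whenever the
    reference base is a purine.
    """
    ref_base, alt_base, context = ref_base.upper(), alt_base.upper(), context.upper()
    if len(context) % 2 == 0:
        raise ValueError("context must have odd length")
    mid = len(context) // 2
    if context[mid] != ref_base:
        raise ValueError(
            f"context center {context[mid]!r} does not match ref base {ref_base!r}"
        )
    if ref_base == alt_base:
        raise ValueError("ref and alt bases must differ")
    if ref_base in "AG":
        ref_base = _COMPLEMENT[ref_base]
        alt_base = _COMPLEMENT[alt_base]
        context = reverse_complement(context)
    return f"{ref_base}>{alt_base}", context


def channel_of(ref_base: str, alt_base: str, context: str) -> str:
    """The 96-channel label of a variant given its trinucleotide context."""
    sub, ctx = pyrimidine_normalize(ref_base, alt_base, context)
    return f"{ctx[0]}[{sub}]{ctx[2]}"


def _variants_frame(variants) -> pd.DataFrame:
    if isinstance(variants, pd.DataFrame):
        df = variants
        missing = {"sample_id", "chrom", "pos", "ref_base", "alt_base"} - set(df.columns)
        if missing:
            raise ValueError(f"variant table missing columns: {sorted(missing)}")
        return df
    rows = list(variants)
    return pd.DataFrame(rows, columns=["sample_id", "chrom", "pos", "ref_base", "alt_base"])


def build_catalog(variants, reference, samples: Sequence[str] | None = None) -> MutationCatalog:
    """Build the 96-channel catalog for a set of SNVs against a reference.

    Variants may be an iterable of :class:`VariantRecord` or a DataFrame with
    the same columns. Variants with a reference mismatch, a context window
    off the contig end, a non-ACGT base, or identical ref/alt are skipped and
    tallied in the returned catalog's :class:`SkipReport`.
    """
    df = _variants_frame(variants)
    contigs = as_contig_map(reference)
    skip = SkipReport()

    if samples is None:
        samples = list(pd.unique(df["sample_id"])) if len(df) else []
    counts = np.zeros((96, len(samples)), dtype=np.int64)
    sample_pos = {s: j for j, s in enumerate(samples)}

    for chrom, sub in df.groupby("chrom", sort=False) if len(df) else []:
        if chrom not in contigs:
            raise KeyError(f"variant contig {chrom!r} absent from reference")
        code = encode_sequence(contigs[chrom])
        n = len(code)
        pos = sub["pos"].to_numpy(dtype=np.int64)
        ref = _encode_bases(sub["ref_base"])
        alt = _encode_bases(sub["alt_base"])
        samp = sub["sample_id"].map(sample_pos).to_numpy()

        bad_base = (ref < 0) | (alt < 0) | (ref == alt)
        skip.not_snv += int(bad_base.sum())
        oob = (pos < 2) | (pos > n - 1)
        skip.out_of_bounds += int((oob & ~bad_base).sum())
        ok = ~bad_base & ~oob

        idx = pos[ok] - 1
        center = code[idx]
        mismatch = center != ref[ok]
        skip.ref_mismatch += int(mismatch.sum())
        keep = np.flatnonzero(ok)[~mismatch]

        idx = pos[keep] - 1
        f5, f3 = code[idx - 1], code[idx + 1]
        ambig = (f5 < 0) | (f3 < 0)
        skip.ambiguous_context += int(ambig.sum())
        keep = keep[~ambig]
        idx, f5, f3 = idx[~ambig], f5[~ambig], f3[~ambig]

        r, a = ref[keep], alt[keep]
        purine = (r == 0) | (r == 2)  # A or G on the plus strand
        r_n = np.where(purine, _COMP_CODE[r], r)
        a_n = np.where(purine, _COMP_CODE[a], a)
        f5_n = np.where(purine, _COMP_CODE[f3], f5)
        f3_n = np.where(purine, _COMP_CODE[f5], f3)
        chan = _SUB_OF[r_n, a_n] * 16 + f5_n * 4 + f3_n
        np.add.at(counts, (chan, samp[keep]), 1)

    cat = pd.DataFrame(counts, index=list(CHANNELS_96), columns=list(samples))
    return MutationCatalog(counts=cat, skipped=skip)


def _encode_bases(series: pd.Series) -> np.ndarray:
    s = series.astype(str).str.upper()
    return s.map(_BASE_INDEX).fillna(-1).to_numpy(dtype=np.int8)


def build_catalog_naive(variants: Iterable[VariantRecord], reference) -> MutationCatalog:
    """Reference implementation: one variant at a time through the scalar
    context/normalization path. Used as an oracle against :func:`build_catalog`."""
    contigs = as_contig_map(reference)
    counts: dict[str, np.ndarray] = {}
    skip = SkipReport()
    df = _variants_frame(variants)
    for rec in df.itertuples(index=False):
        vec = counts.setdefault(rec.sample_id, np.zeros(96, dtype=np.int64))
        ref = str(rec.ref_base).upper()
        alt = str(rec.alt_base).upper()
        if ref not in _BASE_INDEX or alt not in _BASE_INDEX or ref == alt:
            skip.not_snv += 1
            continue
        try:
            ctx = extract_context(contigs, rec.chrom, int(rec.pos), 1, 1)
        except IndexError:
            skip.out_of_bounds += 1
            continue
        if ctx[1] != ref:
            skip.ref_mismatch += 1
            continue
        if any(b not in _BASE_INDEX for b in ctx):
            skip.ambiguous_context += 1
            continue
        vec[CHANNEL_INDEX[channel_of(ref, alt, ctx)]] += 1
    frame = pd.DataFrame(
        {s: v for s, v in counts.items()}, index=list(CHANNELS_96), dtype=np.int64
    )
    if frame.empty:
        frame = pd.DataFrame(index=list(CHANNELS_96), dtype=np.int64)
    return MutationCatalog(counts=frame, skipped=skip)
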