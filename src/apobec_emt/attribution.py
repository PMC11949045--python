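"""APOBEC3A- vs APOBEC3B-like attribution from tetranucleotide context.

Both enzymes deaminate cytosine in a TpC dinucleotide, producing the C>T
and C>G substitutions of signatures SBS2/SBS13, but they prefer different
bases 5' of the TpC: A3A favors a pyrimidine (YTCA, Y = C or T) while A3B
favors a purine (RTCA, R = A or G). Counting qualifying mutations in each
tetranucleotide class, normalized by the genome's own YTCA/RTCA content,
gives a simple enzyme-attribution statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .catalog import (
    _COMP_CODE,
    _variants_frame,
    as_contig_map,
    encode_sequence,
)

# codes: A=0, C=1, G=2, T=3
_PYRIMIDINES = (1, 3)
_PURINES = (0, 2)


@dataclass
class TetraContextCounts:
    """Qualifying TpC mutations split by the base 5' of the T, plus the
    reference genome's own (double-strand-collapsed) 4-mer frequencies."""

    ytca: int
    rtca: int
    other_tca: int
    background_ytca_freq: float
    background_rtca_freq: float

    @property
    def n_informative(self) -> int:
        return self.ytca + self.rtca


@dataclass
class AttributionCall:
    ratio_raw: float
    ratio_normalized: float
    label: str  # {"A3A-like", "A3B-like", "indeterminate"}
    n_informative: int


def background_tetra_frequencies(reference) -> tuple[float, float]:
    """Frequencies of YTCA and RTCA among all 4-mers of both strands.

    Every 4-mer window is counted once per strand; a window whose plus
    strand reads YTCA and one whose minus strand does contribute equally.
    """
    total = 0
    ytca = 0
    rtca = 0
    for seq in as_contig_map(reference).values():
        code = encode_sequence(seq)
        if len(code) < 4:
            continue
        w0, w1, w2, w3 = code[:-3], code[1:-2], code[2:-1], code[3:]
        valid = (w0 >= 0) & (w1 >= 0) & (w2 >= 0) & (w3 >= 0)
        total += 2 * int(valid.sum())
        # plus strand: x T C A
        plus = valid & (w1 == 3) & (w2 == 1) & (w3 == 0)
        ytca += int((plus & np.isin(w0, _PYRIMIDINES)).sum())
        rtca += int((plus & np.isin(w0, _PURINES)).sum())
        # minus strand: plus-strand T G A x reads x' T C A in reverse complement
        minus = valid & (w0 == 3) & (w1 == 2) & (w2 == 0)
        comp5 = _COMP_CODE[np.clip(w3, 0, 3)]
        ytca += int((minus & np.isin(comp5, _PYRIMIDINES)).sum())
        rtca += int((minus & np.isin(comp5, _PURINES)).sum())
    if total == 0:
        raise ValueError("reference contains no 4-mer windows")
    return ytca / total, rtca / total


def count_tca_contexts(variants, reference) -> TetraContextCounts:
    """Count YTCA/RTCA mutations among SBS2/13-compatible SNVs.

    A mutation qualifies when, after pyrimidine normalization, it is a
    C>T or C>G substitution whose trinucleotide context is T-C-A. The base
    5' of that T decides YTCA vs RTCA; an edge or non-ACGT base there
    lands in ``other_tca``.
    """
    contigs = as_contig_map(reference)
    if not contigs or all(len(s) == 0 for s in contigs.values()):
        raise ValueError("empty reference")
    df = _variants_frame(variants)
    ytca = rtca = other = 0
    for rec in df.itertuples(index=False):
        seq = contigs[rec.chrom]
        i = int(rec.pos) - 1  # 0-based center
        if i < 1 or i > len(seq) - 2:
            continue
        code = encode_sequence(seq[max(0, i - 2) : i + 3].upper())
        center_off = min(i, 2)
        ref = "ACGT".find(str(rec.ref_base).upper())
        alt = "ACGT".find(str(rec.alt_base).upper())
        if ref < 0 or alt < 0 or code[center_off] != ref:
            continue
        if ref == 1:  # plus-strand C: context T C A, 5' base two left
            qualifies = alt in (3, 2)  # C>T or C>G
            tri_ok = (
                code[center_off - 1] == 3
                and center_off + 1 < len(code)
                and code[center_off + 1] == 0
            )
            five = code[center_off - 2] if center_off >= 2 else -1
        elif ref == 2:  # plus-strand G: minus-strand C; plus T-G-A revcomps to T-C-A
            qualifies = alt in (0, 1)  # G>A (=C>T) or G>C (=C>G)
            tri_ok = (
                code[center_off - 1] == 3
                and center_off + 1 < len(code)
                and code[center_off + 1] == 0
            )
            five = (
                _COMP_CODE[code[center_off + 2]]
                if center_off + 2 < len(code) and code[center_off + 2] >= 0
                else -1
            )
        else:
            continue
        if not (qualifies and tri_ok):
            continue
        if five in _PYRIMIDINES:
            ytca += 1
        elif five in _PURINES:
            rtca += 1
        else:
            other += 1
    bg_y, bg_r = background_tetra_frequencies(contigs)
    return TetraContextCounts(
        ytca=ytca,
        rtca=rtca,
        other_tca=other,
        background_ytca_freq=bg_y,
        background_rtca_freq=bg_r,
    )


def attribute_enzyme(
    counts: TetraContextCounts,
    min_support: int = 20,
    decision_margin: float = 0.10,
) -> AttributionCall:
    """Call A3A-like vs A3B-like from background-normalized YTCA:RTCA.

    The call is A3A-like when the normalized ratio exceeds ``1 + margin``,
    A3B-like below ``1/(1 + margin)``, indeterminate in between or when
    fewer than ``min_support`` informative mutations are available. A zero
    count on one side yields an infinite (or zero) ratio sentinel; the
    label is still assigned when support suffices.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    n = counts.n_informative
    if counts.rtca == 0:
        raw = math.inf if counts.ytca > 0 else math.nan
    else:
        raw = counts.ytca / counts.rtca
    bg_y = counts.background_ytca_freq
    bg_r = counts.background_rtca_freq
    if counts.rtca == 0 or bg_y == 0:
        norm = math.inf if counts.ytca > 0 and bg_r > 0 else math.nan
    else:
        norm = (counts.ytca / bg_y) / (counts.rtca / bg_r)
    if n < min_support or math.isnan(norm):
        label = "indeterminate"
    elif norm > 1 + decision_margin:
        label = "A3A-like"
    elif norm < 1 / (1 + decision_margin):
        label = "A3B-like"
    else:
        label = "indeterminate"
    return AttributionCall(
        ratio_raw=raw, ratio_normalized=norm, label=label, n_informative=n
    )
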