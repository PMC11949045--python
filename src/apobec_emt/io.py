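"""Readers and writers for the pipeline's on-disk formats.

FASTA references are read through pyfaidx, VCFs through pysam; catalogs,
signature matrices, exposures and cohort tables travel as TSV; gene sets
as GMT. VCF reading splits multi-allelic records and skips non-SNV ALTs
with a logged reason, mirroring catalog-construction policy.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam
from pyfaidx import Fasta

from .catalog import CHANNELS_96, MutationCatalog, VariantRecord
from .emt import GeneSet
from .signatures import ExposureResult, SignatureMatrix

log = logging.getLogger(__name__)

_VARIANT_COLUMNS = ["sample_id", "chrom", "pos", "ref_base", "alt_base"]


def read_fasta(path) -> dict:
    """Load a FASTA file into a {contig: sequence} map."""
    with Fasta(str(path), as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(contigs, path, width: int = 70) -> None:
    contig_map = contigs.contigs if hasattr(contigs, "contigs") else contigs
    with open(path, "w") as fh:
        for name, seq in contig_map.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_vcf(path, sample_id: str | None = None) -> list[VariantRecord]:
    """Read single-nucleotide variants from a VCF (v4.2, plain or bgzip).

    Multi-allelic records are split into one variant per ALT; ALTs that
    are not single-base substitutions are skipped and logged. The sample
    id comes from a per-record SAMPLE info tag when present (the
    convention :func:`write_vcf` uses for multi-sample variant sets),
    else from ``sample_id``, else from the file stem.
    """
    default_sid = sample_id if sample_id is not None else Path(path).stem.removesuffix(".vcf")
    records: list[VariantRecord] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            sid = rec.info.get("SAMPLE", default_sid) if sample_id is None else sample_id
            for alt in rec.alts or ():
                if len(rec.ref) == 1 and len(alt) == 1 and alt in "ACGT" and rec.ref in "ACGT":
                    records.append(
                        VariantRecord(sid, rec.chrom, rec.pos, rec.ref, alt)
                    )
                else:
                    skipped += 1
    if skipped:
        log.info("skipped %d non-SNV ALT alleles in %s", skipped, path)
    return records


def write_vcf(variants: Iterable[VariantRecord], path, contig_lengths=None) -> None:
    """Write SNVs as a minimal VCF v4.2 (1-based, single-ALT records)."""
    variants = list(variants)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("##INFO=<ID=SAMPLE,Number=1,Type=String,Description=\"Sample id\">\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(variants, key=lambda r: (r.chrom, r.pos)):
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref_base}\t{v.alt_base}\t.\t.\tSAMPLE={v.sample_id}\n"
            )


def read_variant_table(path) -> list[VariantRecord]:
    """Read a tab-delimited variant table (sample, chrom, pos, ref, alt)."""
    df = pd.read_csv(path, sep="\t")
    missing = set(_VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    return [
        VariantRecord(r.sample_id, r.chrom, int(r.pos), r.ref_base, r.alt_base)
        for r in df.itertuples(index=False)
    ]


def write_variant_table(variants: Iterable[VariantRecord], path) -> None:
    pd.DataFrame(list(variants), columns=_VARIANT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def write_catalog(catalog: MutationCatalog, path) -> None:
    catalog.counts.rename_axis("channel").to_csv(path, sep="\t")


def read_catalog(path) -> MutationCatalog:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    return MutationCatalog(counts=df.loc[list(CHANNELS_96)].astype(int))


def write_signatures(signatures: SignatureMatrix, path) -> None:
    signatures.profiles.rename_axis("channel").to_csv(path, sep="\t")


def read_signatures(path) -> SignatureMatrix:
    """Read a COSMIC-format signature TSV (channel labels x signatures).

    Accepts either the catalog's bracketed channel labels ("A[C>A]A") or
    the COSMIC website's identical convention; rows are reordered to the
    standard channel order.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = None
    missing = set(CHANNELS_96) - set(df.index)
    if missing:
        raise ValueError(f"signature file missing {len(missing)} channels")
    return SignatureMatrix(df.loc[list(CHANNELS_96)].astype(float))


def write_exposures(result: ExposureResult, path) -> None:
    abs_ = result.absolute.add_suffix(":absolute")
    rel = result.relative.add_suffix(":relative")
    table = pd.concat([abs_, rel], axis=1)
    table["reconstruction_residual"] = result.reconstruction_residual
    table["cosine_to_data"] = result.cosine_to_data
    table.rename_axis("sample_id").to_csv(path, sep="\t")


def read_cohort_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "patient_id", "site", "apobec_fraction"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return df


def write_cohort_table(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


def read_gmt(path, categories=None) -> list[GeneSet]:
    """Read gene sets from a GMT file (name, description, genes...)."""
    sets = []
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
            category = (categories or {}).get(name, desc or None)
            sets.append(GeneSet(name=name, genes=tuple(genes), category=category))
    return sets


def write_gmt(gene_sets: Sequence[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in gene_sets:
            desc = gs.category or gs.name
            fh.write("\t".join([gs.name, desc, *gs.genes]) + "\n")
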