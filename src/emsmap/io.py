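"""Readers and writers for the standard formats the pipeline touches.

FASTA is handled with Biopython, VCF with pysam, GFF3 parsing with
gffutils. Conversion between the 1-based inclusive coordinates of the
file formats and any internal arithmetic is confined to this layer, so
round trips are lossless for every field the pipeline uses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import gffutils
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import (
    EmsVariant,
    FormatError,
    GeneModel,
    GenomeFixture,
    PooledSiteCounts,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_gff3",
    "write_gff3",
    "read_variants_vcf",
    "write_variants_vcf",
    "VcfResult",
]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into an ordered name -> sequence map.

    Rejects duplicate record names and non-A/C/G/T characters (the fixture
    generator never emits N), naming the offending record.
    """
    chromosomes: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in chromosomes:
            raise FormatError(f"duplicate FASTA record {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - set("ACGT")
        if bad:
            raise FormatError(
                f"FASTA record {record.id!r}: non-ACGT characters {sorted(bad)}"
            )
        chromosomes[record.id] = seq
    return chromosomes


def write_fasta(chromosomes: dict[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in chromosomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(
    path: str | Path, chromosomes: Optional[dict[str, str]] = None
) -> list[GeneModel]:
    """Parse gene models from a GFF3 with gene/mRNA/CDS features.

    CDS segments are grouped per gene and stored in genomic order; a gene
    whose spliced CDS length is not a multiple of three is rejected by name.
    """
    try:
        db = gffutils.create_db(
            str(path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except (gffutils.exceptions.EmptyInputError, ValueError, OSError) as exc:
        raise FormatError(f"cannot parse GFF3 {path}: {exc}") from exc
    genes: list[GeneModel] = []
    for feature in db.features_of_type("gene", order_by=("seqid", "start")):
        segments = sorted(
            (cds.start, cds.end)
            for cds in db.children(feature, featuretype="CDS")
        )
        if not segments:
            raise FormatError(f"gene {feature.id}: no CDS features")
        gene = GeneModel(
            gene_id=feature.id,
            chrom=feature.seqid,
            strand=feature.strand,
            cds_segments=tuple(segments),
        )
        if chromosomes is not None:
            if gene.chrom not in chromosomes:
                raise FormatError(
                    f"gene {gene.gene_id}: unknown chromosome {gene.chrom!r}"
                )
            if gene.end > len(chromosomes[gene.chrom]):
                raise FormatError(
                    f"gene {gene.gene_id}: coordinates exceed {gene.chrom} length"
                )
        genes.append(gene)
    return genes


def write_gff3(genes: list[GeneModel], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for gene in genes:
        span = (gene.start, gene.end)
        mrna_id = f"{gene.gene_id}.t1"
        lines.append(
            "\t".join(
                [
                    gene.chrom, "emsmap", "gene", str(span[0]), str(span[1]),
                    ".", gene.strand, ".", f"ID={gene.gene_id}",
                ]
            )
        )
        lines.append(
            "\t".join(
                [
                    gene.chrom, "emsmap", "mRNA", str(span[0]), str(span[1]),
                    ".", gene.strand, ".",
                    f"ID={mrna_id};Parent={gene.gene_id}",
                ]
            )
        )
        # CDS phase: offset of the first complete codon within the segment,
        # accumulated along the coding strand.
        segs = (
            gene.cds_segments if gene.strand == "+" else gene.cds_segments[::-1]
        )
        consumed = 0
        phases: dict[tuple[int, int], int] = {}
        for s, e in segs:
            phases[(s, e)] = (3 - consumed % 3) % 3
            consumed += e - s + 1
        for i, (s, e) in enumerate(gene.cds_segments, 1):
            lines.append(
                "\t".join(
                    [
                        gene.chrom, "emsmap", "CDS", str(s), str(e), ".",
                        gene.strand, str(phases[(s, e)]),
                        f"ID={mrna_id}.cds{i};Parent={mrna_id}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# VCF

@dataclass
class VcfResult:
    """Variants parsed from a VCF plus any pooled depths found in AD."""

    variants: list[EmsVariant] = field(default_factory=list)
    counts: dict[tuple[str, int], PooledSiteCounts] = field(default_factory=dict)
    n_skipped: int = 0


def read_variants_vcf(
    path: str | Path, genome: Optional[GenomeFixture] = None
) -> VcfResult:
    """Read biallelic SNV records into EmsVariant records.

    Indels and multi-allelic records are skipped with a logged count, not
    fatally. Pooled allele depths are taken from the POOL sample's AD field
    when present. If ``genome`` is given, every variant's REF allele is
    checked against the reference base and mismatches are rejected.
    """
    result = VcfResult()
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise FormatError(f"cannot parse VCF {path}: {exc}") from exc
    with vcf:
        for rec in vcf:
            alts = rec.alts or ()
            if (
                len(alts) != 1
                or len(rec.ref) != 1
                or len(alts[0]) != 1
                or rec.ref not in "ACGT"
                or alts[0] not in "ACGT"
            ):
                result.n_skipped += 1
                continue
            variant = EmsVariant(rec.contig, rec.pos, rec.ref, alts[0])
            if genome is not None:
                variant.check_reference(genome)
            result.variants.append(variant)
            for sample in rec.samples.values():
                ad = sample.get("AD")
                if ad is not None and None not in ad and len(ad) == 2:
                    result.counts[variant.key] = PooledSiteCounts(
                        variant, int(ad[0]), int(ad[1])
                    )
                    break
    if result.n_skipped:
        logger.info("skipped %d non-SNV/multi-allelic VCF records", result.n_skipped)
    return result


def write_variants_vcf(
    variants: list[EmsVariant],
    path: str | Path,
    contigs: dict[str, int],
    counts: Optional[dict[tuple[str, int], PooledSiteCounts]] = None,
) -> None:
    """Write biallelic SNV records with pooled depths in a POOL sample."""
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.formats.add(
        "AD", "R", "Integer", "Read depths for the REF and ALT alleles in the pool"
    )
    header.add_sample("POOL")
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for variant in variants:
            rec = vcf.new_record(
                contig=variant.chrom,
                start=variant.pos - 1,
                stop=variant.pos,
                alleles=(variant.ref, variant.mut),
            )
            if counts is not None and variant.key in counts:
                site = counts[variant.key]
                rec.samples["POOL"]["AD"] = (site.ref_depth, site.mut_depth)
            vcf.write(rec)
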