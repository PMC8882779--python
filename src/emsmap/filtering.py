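"""Candidate-reduction cascade for mapping-by-sequencing.

Three monotone stages: keep the EMS transition signature (reference G->A
or C->T), keep sites near fixation for the mutant allele in the
phenotype-selected pool (mutant-allele frequency >= 90% by default), and
keep protein-changing variants (missense or nonsense) after codon-level
annotation against the gene models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio.Seq import Seq

from .genome import (
    EMS_TRANSITIONS,
    ConfigError,
    Effect,
    EmsVariant,
    GeneModel,
    GenomeFixture,
    IntegrityError,
    PooledSiteCounts,
    complement,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "EffectCall",
    "filter_transitions",
    "filter_allele_frequency",
    "annotate_effect",
    "select_candidates",
]


@dataclass(frozen=True)
class FilterConfig:
    """Thresholds of the candidate-reduction cascade."""

    allele_frequency_threshold: float = 0.90
    transition_set: frozenset[tuple[str, str]] = EMS_TRANSITIONS
    candidate_effects: frozenset[Effect] = frozenset(
        {Effect.MISSENSE, Effect.NONSENSE}
    )

    def __post_init__(self) -> None:
        if not 0.0 < self.allele_frequency_threshold <= 1.0:
            raise ConfigError(
                "allele_frequency_threshold must be in (0, 1], got "
                f"{self.allele_frequency_threshold}"
            )


@dataclass(frozen=True)
class EffectCall:
    """Codon-level annotation of one variant.

    ``codon_index`` and ``cds_position`` are 1-based within the spliced
    CDS on the coding strand; codon/amino-acid fields are None outside
    coding sequence.
    """

    variant: EmsVariant
    effect: Effect
    gene_id: Optional[str] = None
    cds_position: Optional[int] = None
    codon_index: Optional[int] = None
    ref_codon: Optional[str] = None
    mut_codon: Optional[str] = None
    ref_aa: Optional[str] = None
    mut_aa: Optional[str] = None


def filter_transitions(
    variants: Sequence[EmsVariant], config: Optional[FilterConfig] = None
) -> list[EmsVariant]:
    """Keep variants matching the configured transition signature.

    Order-preserving and idempotent. The default set is reference G->A and
    C->T only: alleles are reference-strand normalised and EMS alkylates
    G/C, so the other two transition orientations are not expected.
    """
    config = config or FilterConfig()
    return [v for v in variants if (v.ref, v.mut) in config.transition_set]


def filter_allele_frequency(
    counts: Sequence[PooledSiteCounts], config: Optional[FilterConfig] = None
) -> list[PooledSiteCounts]:
    """Keep sites whose pooled mutant-allele frequency meets the threshold.

    Zero-depth sites are dropped with a logged count (their frequency is
    undefined), never treated as passing or failing.
    """
    config = config or FilterConfig()
    n_zero = sum(1 for c in counts if c.total_depth == 0)
    if n_zero:
        logger.info("dropping %d zero-depth sites", n_zero)
    return [
        c
        for c in counts
        if c.total_depth > 0
        and c.mut_frequency >= config.allele_frequency_threshold
    ]


def _coding_gene(genome: GenomeFixture, variant: EmsVariant) -> tuple[
    Optional[GeneModel], Optional[GeneModel]
]:
    """(gene with the variant in its CDS, gene merely spanning it)."""
    spanning = None
    for gene in genome.genes_at(variant.chrom, variant.pos):
        if gene.in_cds(variant.pos):
            return gene, gene
        spanning = spanning or gene
    return None, spanning


def annotate_effect(variant: EmsVariant, genome: GenomeFixture) -> EffectCall:
    """Classify a variant as intergenic / intronic / synonymous / missense
    / nonsense by mutating its codon and translating both versions.

    Minus-strand genes: alleles are complemented onto the coding strand and
    the CDS coordinate counted from the coding-strand start. A base on a
    CDS/intron boundary belongs to the CDS (inclusive intervals). Start- or
    stop-codon loss is reported as missense; a gained stop is nonsense.
    """
    variant.check_reference(genome)
    coding, spanning = _coding_gene(genome, variant)
    if coding is None:
        if spanning is None:
            return EffectCall(variant, Effect.INTERGENIC)
        return EffectCall(variant, Effect.INTRONIC, gene_id=spanning.gene_id)

    cds_pos = coding.genomic_to_cds(variant.pos)
    assert cds_pos is not None
    if coding.strand == "+":
        ref_c, mut_c = variant.ref, variant.mut
    else:
        ref_c, mut_c = complement(variant.ref), complement(variant.mut)
    codon_index = (cds_pos - 1) // 3
    within = (cds_pos - 1) % 3
    spliced = coding.spliced_cds(genome.chromosomes)
    ref_codon = spliced[3 * codon_index : 3 * codon_index + 3]
    if ref_codon[within] != ref_c:
        raise IntegrityError(
            f"{variant.chrom}:{variant.pos}: CDS codon {ref_codon} of "
            f"{coding.gene_id} disagrees with reference allele {ref_c}"
        )
    mut_codon = ref_codon[:within] + mut_c + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    mut_aa = str(Seq(mut_codon).translate())
    if ref_aa == mut_aa:
        effect = Effect.SYNONYMOUS
    elif mut_aa == "*":
        effect = Effect.NONSENSE
    else:
        effect = Effect.MISSENSE  # includes start-loss and stop-loss
    return EffectCall(
        variant,
        effect,
        gene_id=coding.gene_id,
        cds_position=cds_pos,
        codon_index=codon_index + 1,
        ref_codon=ref_codon,
        mut_codon=mut_codon,
        ref_aa=ref_aa,
        mut_aa=mut_aa,
    )


def select_candidates(
    calls: Sequence[EffectCall],
    config: Optional[FilterConfig] = None,
    restrict_chromosome: Optional[str] = None,
) -> list[EffectCall]:
    """Keep protein-changing calls, optionally on one chromosome, in
    deterministic (chromosome, position) order. An empty result is a
    warning, not an error."""
    config = config or FilterConfig()
    kept = [
        c
        for c in calls
        if c.effect in config.candidate_effects
        and (restrict_chromosome is None or c.variant.chrom == restrict_chromosome)
    ]
    kept.sort(key=lambda c: (c.variant.chrom, c.variant.pos))
    if not kept:
        logger.warning("no candidate variants survive the cascade")
    return kept
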