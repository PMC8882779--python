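"""Shared test helpers: independent oracles and marker placement."""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

import emsmap as em

#: A 2-chromosome genome keeps the Monte-Carlo tests fast.
SMALL_CHROMS = {"chr1": 60_000, "chr3": 60_000}


def small_genome(seed: int = 13) -> em.GenomeFixture:
    return em.simulate_genome(
        seed=seed, chrom_lengths=SMALL_CHROMS, genes_per_chrom=2
    )


def marker_at_r(
    genome: em.GenomeFixture, config: em.CrossSimConfig, r: float
) -> em.EmsVariant:
    """An EMS-style marker whose recombination fraction from the causal
    locus is r: placed at the Haldane map distance on the causal
    chromosome, or on another chromosome for r = 0.5 (unlinked)."""
    causal = em.causal_variant(genome, config)
    if r == 0.5:
        chrom = next(c for c in genome.chromosomes if c != causal.chrom)
        pos = len(genome.chromosomes[chrom]) // 2
    elif r == 0.0:
        chrom, pos = causal.chrom, causal.pos
    else:
        chrom = causal.chrom
        length = len(genome.chromosomes[chrom])
        delta = em.haldane_d_from_r(r) / config.map_length_cM * length
        pos = causal.pos + int(round(delta))
        if pos > length:
            pos = causal.pos - int(round(delta))
        assert 1 <= pos <= length, "marker distance exceeds chromosome"
    ref = genome.base_at(chrom, pos)
    mut = {"G": "A", "C": "T", "A": "G", "T": "C"}[ref]
    return em.EmsVariant(chrom, pos, ref, mut)


def selected_pools(
    genome: em.GenomeFixture,
    n_reps: int,
    seed0: int,
    **config_kwargs,
):
    """Yield (pool, config) for n_reps seeded phenotype-selected pools."""
    for i in range(n_reps):
        config = em.CrossSimConfig(seed=seed0 + i, **config_kwargs)
        causal = em.causal_variant(genome, config)
        population = em.make_f2(genome, [causal], config)
        yield em.select_pool(population, config), config


def ref_allele_fraction(pool, site: em.EmsVariant) -> float:
    """True reference-allele frequency among the pool's homologs."""
    k_mut = sum(ind.n_mut_alleles(site.chrom, site.pos) for ind in pool)
    return 1.0 - k_mut / (2 * len(pool))


def oracle_effect(variant: em.EmsVariant, genome: em.GenomeFixture) -> em.Effect:
    """Brute-force effect call: rebuild the whole mutant CDS, translate
    both proteins and diff them. Independent of the codon-arithmetic path."""
    spanning = genome.genes_at(variant.chrom, variant.pos)
    coding = [g for g in spanning if g.in_cds(variant.pos)]
    if not spanning:
        return em.Effect.INTERGENIC
    if not coding:
        return em.Effect.INTRONIC
    gene = coding[0]
    mutated = dict(genome.chromosomes)
    seq = mutated[gene.chrom]
    assert seq[variant.pos - 1] == variant.ref
    mutated[gene.chrom] = (
        seq[: variant.pos - 1] + variant.mut + seq[variant.pos :]
    )
    ref_prot = str(Seq(gene.spliced_cds(genome.chromosomes)).translate())
    mut_prot = str(Seq(gene.spliced_cds(mutated)).translate())
    if ref_prot == mut_prot:
        return em.Effect.SYNONYMOUS
    i = next(k for k, (a, b) in enumerate(zip(ref_prot, mut_prot)) if a != b)
    if mut_prot[i] == "*" and ref_prot[i] != "*":
        return em.Effect.NONSENSE
    return em.Effect.MISSENSE


def random_snvs(
    genome: em.GenomeFixture, n: int, rng: np.random.Generator
) -> list[em.EmsVariant]:
    names = list(genome.chromosomes)
    out = []
    for _ in range(n):
        chrom = names[int(rng.integers(len(names)))]
        pos = int(rng.integers(1, len(genome.chromosomes[chrom]) + 1))
        ref = genome.base_at(chrom, pos)
        mut = rng.choice([b for b in "ACGT" if b != ref])
        out.append(em.EmsVariant(chrom, pos, ref, str(mut)))
    return out
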