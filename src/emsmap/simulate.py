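"""Simulation of the mapping experiment: EMS mutagenesis of an inbred line,
a mutant x reference cross, an F2 population with Haldane (no-interference)
recombination, recessive phenotype assignment, phenotype selection of a
40-plant pool, pooled sequencing counts and per-plant Sanger peak patterns.

All EMS mutations reside on the mutant-line haplotype (coupling phase),
which is what makes the crossover-rate statistic an unbiased estimator of
the recombination fraction in phenotype-selected progeny.

Randomness is controlled by a single integer seed; each stage of the
pipeline draws from an independent stream derived from it, so e.g. changing
the pool depth does not perturb meiosis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .genome import (
    ConfigError,
    EmsVariant,
    GeneModel,
    GenomeFixture,
    PooledSiteCounts,
    revcomp,
)

__all__ = [
    "MUT",
    "B73",
    "DWARF",
    "TALL",
    "PAIR",
    "SINGLE_REF",
    "SINGLE_MUT",
    "CrossSimConfig",
    "Haplotype",
    "F2Individual",
    "PeakPattern",
    "stage_rng",
    "simulate_genome",
    "mutagenize",
    "causal_variant",
    "make_f2",
    "haldane_r_from_d",
    "haldane_d_from_r",
    "select_pool",
    "simulate_pooled_counts",
    "simulate_peak_patterns",
]

#: Ancestry labels for haplotype segments.
MUT = "MUT"
B73 = "B73"

#: Phenotype labels (complete penetrance, single recessive locus).
DWARF = "dwarf"
TALL = "tall"

#: Sanger chromatogram peak classes at a biallelic site.
PAIR = "PAIR"              # double peak: heterozygote
SINGLE_REF = "SINGLE_REF"  # single reference peak: homozygous wild type
SINGLE_MUT = "SINGLE_MUT"  # single mutant peak: homozygous mutant

_PEAK_CLASSES = (PAIR, SINGLE_REF, SINGLE_MUT)

_STAGES = ("mutagenesis", "meiosis", "selection", "pooling", "genotyping")


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent generator for one pipeline stage, derived from the seed."""
    ss = np.random.SeedSequence(seed, spawn_key=(_STAGES.index(stage),))
    return np.random.default_rng(ss)


# ---------------------------------------------------------------------------
# Configuration

@dataclass
class CrossSimConfig:
    """Parameters of the simulated mutagenesis + cross + pooling experiment.

    ems_mutation_rate
        Expected induced mutations per reference bp (Poisson).
    transition_fraction
        Proportion of induced mutations that are reference G->A or C->T
        (the EMS signature); the remainder are random transversions.
    causal_gene / causal_cds_position
        The causal lesion: a C->T at this 1-based spliced-CDS position of
        this gene, always injected. The default position sits at codon
        position 1 of a glutamine codon, turning CAG into the TAG stop.
    n_f2 / n_selected
        F2 population size and the number of dwarf plants pooled.
    map_length_cM
        Genetic length of each chromosome; crossovers per gamete are
        Poisson(map_length_cM / 100) with uniform positions (Haldane).
    pool_depth / seq_error_rate
        Mean sequencing depth per site (Poisson) and per-base probability
        that a read reports the wrong allele.
    genotyping_error_rate
        Per-plant probability that a Sanger peak call is replaced by a
        uniformly chosen wrong class.
    backcross_first
        If True, the selfed parent is a BC1 (mutant x reference, then
        crossed to the reference again) carrying the causal allele, which
        halves background heterozygosity.
    """

    ems_mutation_rate: float = 1e-4
    transition_fraction: float = 0.9
    causal_gene: str = "zmte1"
    causal_cds_position: int = 547
    n_f2: int = 300
    n_selected: int = 40
    map_length_cM: float = 150.0
    pool_depth: float = 100.0
    seq_error_rate: float = 0.01
    genotyping_error_rate: float = 0.0
    backcross_first: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "transition_fraction",
            "seq_error_rate",
            "genotyping_error_rate",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {value}")
        if self.ems_mutation_rate < 0:
            raise ConfigError("ems_mutation_rate must be >= 0")
        if self.n_f2 < 1 or self.n_selected < 1:
            raise ConfigError("n_f2 and n_selected must be positive")
        if self.map_length_cM < 0:
            raise ConfigError("map_length_cM must be >= 0")
        if self.pool_depth <= 0:
            raise ConfigError("pool_depth must be > 0")
        if self.causal_cds_position < 1:
            raise ConfigError("causal_cds_position must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CrossSimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


# ---------------------------------------------------------------------------
# Haplotypes and individuals

@dataclass(frozen=True)
class Haplotype:
    """A gamete haplotype as an ancestry mosaic along one chromosome.

    ``breakpoints`` are sorted continuous positions in [0, L); ancestry
    starts as ``first`` and flips at each breakpoint. The 1-based base
    ``pos`` has ancestry ``first`` iff an even number of breakpoints lie
    at or before its 0-based index.
    """

    breakpoints: np.ndarray
    first: str

    def ancestry_at(self, pos: int) -> str:
        flips = int(np.searchsorted(self.breakpoints, pos - 1, side="right"))
        if flips % 2 == 0:
            return self.first
        return B73 if self.first == MUT else MUT

    def segments(self, chrom_length: int) -> list[tuple[int, int, str]]:
        """Tile the chromosome as (start, end, ancestry), 1-based inclusive.

        Breakpoint pairs that round to the same base boundary cancel.
        """
        switches = np.ceil(self.breakpoints).astype(int)
        switches = switches[(switches >= 1) & (switches < chrom_length)]
        boundaries: list[int] = []
        for b in switches:
            if boundaries and boundaries[-1] == b:
                boundaries.pop()  # even number of crossovers: no net switch
            else:
                boundaries.append(int(b))
        out = []
        ancestry = self.first
        start = 1
        for b in boundaries:
            out.append((start, b, ancestry))
            start = b + 1
            ancestry = B73 if ancestry == MUT else MUT
        out.append((start, chrom_length, ancestry))
        return out


@dataclass
class F2Individual:
    """Two haplotypes per chromosome plus the (fully penetrant) phenotype."""

    haplotypes: dict[str, tuple[Haplotype, Haplotype]]
    phenotype: str

    def ancestries_at(self, chrom: str, pos: int) -> tuple[str, str]:
        a, b = self.haplotypes[chrom]
        return (a.ancestry_at(pos), b.ancestry_at(pos))

    def n_mut_alleles(self, chrom: str, pos: int) -> int:
        """Mutant-allele dosage (0, 1 or 2) at a site, by ancestry."""
        return sum(anc == MUT for anc in self.ancestries_at(chrom, pos))


@dataclass(frozen=True)
class PeakPattern:
    """One plant's Sanger peak call at one site."""

    site: EmsVariant
    plant_id: int
    pattern: str

    def __post_init__(self) -> None:
        if self.pattern not in _PEAK_CLASSES:
            raise ConfigError(f"unknown peak pattern {self.pattern!r}")


# ---------------------------------------------------------------------------
# Fixture genome

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_STOPS = ("TAA", "TAG", "TGA")
_SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOPS
)


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + random stop-free codons + one stop codon."""
    body = rng.choice(len(_SENSE_CODONS), size=n_codons - 2)
    return (
        "ATG"
        + "".join(_SENSE_CODONS[i] for i in body)
        + _STOPS[rng.integers(len(_STOPS))]
    )


def simulate_genome(
    seed: int = 0,
    chrom_lengths: Optional[dict[str, int]] = None,
    genes_per_chrom: int = 3,
    causal_gene: str = "zmte1",
    causal_chrom: str = "chr3",
    causal_cds_length: int = 900,
    causal_gln_codon: int = 183,
) -> GenomeFixture:
    """Build a small multi-chromosome reference with valid gene models.

    One designated gene (the causal gene, plus strand, single exon) carries
    a CAG glutamine codon at ``causal_gln_codon`` so that a C->T at codon
    position 1 produces a TAG premature stop; its default spliced-CDS
    position is 3 * (183 - 1) + 1 = 547. Other genes vary in strand and
    exon count so effect annotation is exercised on both strands.
    """
    if chrom_lengths is None:
        chrom_lengths = {"chr1": 100_000, "chr2": 100_000, "chr3": 100_000}
    if causal_chrom not in chrom_lengths:
        raise ConfigError(f"causal chromosome {causal_chrom!r} not in genome")
    if causal_cds_length % 3 != 0 or causal_cds_length < 3 * causal_gln_codon + 3:
        raise ConfigError("causal CDS too short for the glutamine codon")
    rng = np.random.default_rng(seed)
    chromosomes: dict[str, np.ndarray] = {
        name: _BASES[rng.integers(0, 4, size=length)].copy()
        for name, length in chrom_lengths.items()
    }
    genes: list[GeneModel] = []
    for chrom, length in chrom_lengths.items():
        slot = length // genes_per_chrom
        for i in range(genes_per_chrom):
            is_causal = chrom == causal_chrom and i == genes_per_chrom // 2
            if is_causal:
                gene_id, strand, n_exons = causal_gene, "+", 1
                cds_len = causal_cds_length
            else:
                gene_id = f"gene_{chrom}_{i + 1}"
                strand = "+" if rng.integers(2) == 0 else "-"
                n_exons = 1 if rng.integers(2) == 0 else 2
                cds_len = 3 * int(rng.integers(100, 300))
            intron = int(rng.integers(100, 400)) if n_exons == 2 else 0
            span = cds_len + intron
            if span + 200 > slot:
                raise ConfigError(
                    f"chromosome {chrom} too short for {genes_per_chrom} genes"
                )
            start = i * slot + 100 + int(rng.integers(slot - span - 200))
            coding = _random_orf(rng, cds_len // 3)
            if is_causal:
                k = 3 * (causal_gln_codon - 1)
                coding = coding[:k] + "CAG" + coding[k + 3 :]
            text = coding if strand == "+" else revcomp(coding)
            if n_exons == 1:
                segments = ((start, start + cds_len - 1),)
            else:
                cut = 3 * int(rng.integers(1, cds_len // 3))
                segments = (
                    (start, start + cut - 1),
                    (start + cut + intron, start + cds_len + intron - 1),
                )
            pieces = [text[: segments[0][1] - segments[0][0] + 1]]
            if n_exons == 2:
                pieces.append(text[len(pieces[0]) :])
            for (s, e), piece in zip(segments, pieces):
                chromosomes[chrom][s - 1 : e] = np.frombuffer(
                    piece.encode(), dtype="S1"
                )
            genes.append(GeneModel(gene_id, chrom, strand, segments))
    return GenomeFixture(
        {name: arr.tobytes().decode() for name, arr in chromosomes.items()},
        genes,
    )


# ---------------------------------------------------------------------------
# Mutagenesis

_TRANSVERSIONS = {"A": ("C", "T"), "G": ("C", "T"), "C": ("A", "G"), "T": ("A", "G")}
_EMS_MUT = {"G": "A", "C": "T"}


def causal_variant(genome: GenomeFixture, config: CrossSimConfig) -> EmsVariant:
    """The injected causal lesion: coding-strand C->T at the configured
    spliced-CDS position of the causal gene, on reference-strand alleles."""
    gene = genome.gene_by_id(config.causal_gene)
    pos = gene.cds_to_genomic(config.causal_cds_position)
    ref = genome.base_at(gene.chrom, pos)
    expected_ref = "C" if gene.strand == "+" else "G"
    if ref != expected_ref:
        raise ConfigError(
            f"causal CDS position {config.causal_cds_position} of "
            f"{config.causal_gene} is not a coding-strand C (found "
            f"{'C' if gene.strand == '+' else revcomp(ref)})"
        )
    mut = "T" if gene.strand == "+" else "A"
    return EmsVariant(gene.chrom, pos, ref, mut)


def mutagenize(
    genome: GenomeFixture,
    config: CrossSimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[EmsVariant]:
    """Induce EMS mutations across the genome and inject the causal lesion.

    The mutation count is Poisson(rate x genome length); a Binomial
    ``transition_fraction`` share are reference G->A or C->T at G/C sites,
    the remainder random transversions. At most one mutation per position;
    the causal variant is always present.
    """
    if rng is None:
        rng = stage_rng(config.seed, "mutagenesis")
    causal = causal_variant(genome, config)

    names = list(genome.chromosomes)
    lengths = np.array([len(genome.chromosomes[n]) for n in names])
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    arr = np.frombuffer("".join(genome.chromosomes[n] for n in names).encode(), "S1")
    total = int(offsets[-1])

    n = int(rng.poisson(config.ems_mutation_rate * total))
    n_ts = int(rng.binomial(n, config.transition_fraction)) if n else 0
    gc_sites = np.flatnonzero((arr == b"G") | (arr == b"C"))
    ts_pos = rng.choice(gc_sites, size=min(n_ts, gc_sites.size), replace=False)
    tv_pos = rng.choice(total, size=n - n_ts, replace=False)

    causal_offset = (
        offsets[names.index(causal.chrom)] + causal.pos - 1
    )
    seen = {int(causal_offset)}
    variants = [causal]
    for flat_positions, is_transition in ((ts_pos, True), (tv_pos, False)):
        for flat in np.sort(flat_positions):
            flat = int(flat)
            if flat in seen:
                continue
            seen.add(flat)
            ci = int(np.searchsorted(offsets, flat, side="right")) - 1
            pos = flat - int(offsets[ci]) + 1
            ref = arr[flat].decode()
            if is_transition:
                mut = _EMS_MUT[ref]
            else:
                mut = _TRANSVERSIONS[ref][int(rng.integers(2))]
            variants.append(EmsVariant(names[ci], pos, ref, mut))
    variants.sort(key=lambda v: (v.chrom, v.pos))
    return variants


# ---------------------------------------------------------------------------
# Map functions

def haldane_r_from_d(d_cM: float) -> float:
    """Recombination fraction for a map distance in cM (no interference)."""
    if d_cM < 0:
        raise ConfigError("map distance must be >= 0")
    return 0.5 * (1.0 - math.exp(-2.0 * d_cM / 100.0))


def haldane_d_from_r(r: float) -> float:
    """Map distance in cM for a recombination fraction r in [0, 0.5)."""
    if not 0.0 <= r < 0.5:
        raise ConfigError("recombination fraction must be in [0, 0.5)")
    return -50.0 * math.log(1.0 - 2.0 * r)


# ---------------------------------------------------------------------------
# Meiosis

def _pure(ancestry: str) -> Haplotype:
    return Haplotype(np.empty(0), ancestry)


def _gamete_batch(
    rng: np.random.Generator, chrom_length: int, map_length_cM: float, n: int
) -> list[Haplotype]:
    """n independent F1 gametes for one chromosome (vectorised draws)."""
    counts = rng.poisson(map_length_cM / 100.0, size=n)
    positions = rng.uniform(0.0, chrom_length, counts.sum())
    firsts = rng.integers(0, 2, size=n)
    out: list[Haplotype] = []
    idx = 0
    for c, f in zip(counts, firsts):
        bps = np.sort(positions[idx : idx + c])
        idx += c
        out.append(Haplotype(bps, MUT if f == 0 else B73))
    return out


def _recombine(
    rng: np.random.Generator,
    hap_a: Haplotype,
    hap_b: Haplotype,
    chrom_length: int,
    map_length_cM: float,
) -> Haplotype:
    """One gamete of a parent with arbitrary (mosaic) haplotypes."""
    n_x = int(rng.poisson(map_length_cM / 100.0))
    child_bps = np.sort(rng.uniform(0.0, chrom_length, n_x))
    first_idx = int(rng.integers(0, 2))
    haps = (hap_a, hap_b)

    def anc(x: float, side: str) -> str:
        active = haps[(first_idx + int(np.searchsorted(child_bps, x, side=side))) % 2]
        flips = int(np.searchsorted(active.breakpoints, x, side=side))
        if flips % 2 == 0:
            return active.first
        return B73 if active.first == MUT else MUT

    candidates = np.sort(
        np.concatenate([child_bps, hap_a.breakpoints, hap_b.breakpoints])
    )
    merged = [
        float(p) for p in candidates if anc(p, "right") != anc(p, "left")
    ]
    return Haplotype(np.array(merged), anc(0.0, "left"))


def make_f2(
    genome: GenomeFixture,
    variants: Sequence[EmsVariant],
    config: CrossSimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[F2Individual]:
    """Self the heterozygous F1 (or BC1) and phenotype the progeny.

    Each F2 is formed from two independent gametes; each gamete carries
    Poisson(map_length_cM/100) crossovers at uniform positions. The
    phenotype is dwarf iff both haplotypes carry mutant-line ancestry at
    the causal site (single recessive locus, complete penetrance).
    """
    if rng is None:
        rng = stage_rng(config.seed, "meiosis")
    causal = causal_variant(genome, config)
    if not any(v.key == causal.key for v in variants):
        raise ConfigError(
            f"causal variant {causal.chrom}:{causal.pos} absent from the "
            "variant list; run mutagenize with the same config"
        )
    names = list(genome.chromosomes)
    lengths = {n: len(genome.chromosomes[n]) for n in names}

    if config.backcross_first:
        parents = {}
        for name in names:
            if name == causal.chrom:
                while True:  # BC1 must inherit the causal allele to segregate
                    gamete = _gamete_batch(rng, lengths[name], config.map_length_cM, 1)[0]
                    if gamete.ancestry_at(causal.pos) == MUT:
                        break
            else:
                gamete = _gamete_batch(rng, lengths[name], config.map_length_cM, 1)[0]
            parents[name] = (gamete, _pure(B73))
        gametes = {
            name: [
                _recombine(rng, *parents[name], lengths[name], config.map_length_cM)
                for _ in range(2 * config.n_f2)
            ]
            for name in names
        }
    else:
        gametes = {
            name: _gamete_batch(
                rng, lengths[name], config.map_length_cM, 2 * config.n_f2
            )
            for name in names
        }

    population = []
    for i in range(config.n_f2):
        haplotypes = {
            name: (gametes[name][2 * i], gametes[name][2 * i + 1]) for name in names
        }
        a, b = haplotypes[causal.chrom]
        dwarf = (
            a.ancestry_at(causal.pos) == MUT and b.ancestry_at(causal.pos) == MUT
        )
        population.append(F2Individual(haplotypes, DWARF if dwarf else TALL))
    return population


# ---------------------------------------------------------------------------
# Selection, pooling, genotyping

def select_pool(
    population: Sequence[F2Individual],
    config: CrossSimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[F2Individual]:
    """Uniform random subset of ``n_selected`` dwarf individuals."""
    if rng is None:
        rng = stage_rng(config.seed, "selection")
    dwarfs = [ind for ind in population if ind.phenotype == DWARF]
    if len(dwarfs) < config.n_selected:
        raise ConfigError(
            f"only {len(dwarfs)} dwarf individuals available, "
            f"{config.n_selected} requested"
        )
    chosen = rng.choice(len(dwarfs), size=config.n_selected, replace=False)
    return [dwarfs[i] for i in sorted(chosen)]


def simulate_pooled_counts(
    pool: Sequence[F2Individual],
    variants: Sequence[EmsVariant],
    config: CrossSimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[PooledSiteCounts]:
    """Equimolar pooled sequencing of the selected plants.

    Per site the total depth is Poisson(pool_depth); each read samples an
    allele at the pool's true frequency (each plant contributes two
    haplotypes with equal weight) and is mis-called with probability
    ``seq_error_rate``.
    """
    if rng is None:
        rng = stage_rng(config.seed, "pooling")
    e = config.seq_error_rate
    out = []
    for variant in variants:
        k_mut = sum(ind.n_mut_alleles(variant.chrom, variant.pos) for ind in pool)
        f_mut = k_mut / (2 * len(pool))
        p_mut_read = f_mut * (1 - e) + (1 - f_mut) * e
        depth = int(rng.poisson(config.pool_depth))
        mut_depth = int(rng.binomial(depth, p_mut_read)) if depth else 0
        out.append(PooledSiteCounts(variant, depth - mut_depth, mut_depth))
    return out


def simulate_peak_patterns(
    pool: Sequence[F2Individual],
    site: EmsVariant,
    config: CrossSimConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[PeakPattern]:
    """Per-plant Sanger amplicon genotypes at one site.

    A heterozygote shows a double peak, homozygous reference a single
    reference peak, homozygous mutant a single mutant peak; with
    probability ``genotyping_error_rate`` the call is replaced by a
    uniformly chosen wrong class.
    """
    if rng is None:
        rng = stage_rng(config.seed, "genotyping")
    true_pattern = {2: SINGLE_MUT, 1: PAIR, 0: SINGLE_REF}
    out = []
    for plant_id, ind in enumerate(pool):
        pattern = true_pattern[ind.n_mut_alleles(site.chrom, site.pos)]
        if config.genotyping_error_rate > 0 and (
            rng.random() < config.genotyping_error_rate
        ):
            wrong = [p for p in _PEAK_CLASSES if p != pattern]
            pattern = wrong[int(rng.integers(2))]
        out.append(PeakPattern(site, plant_id, pattern))
    return out
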