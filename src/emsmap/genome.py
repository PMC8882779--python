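"""Core domain types: reference genome, gene models, and EMS variant records.

Coordinates are 1-based inclusive at the API surface (matching VCF/GFF3);
any 0-based arithmetic is internal to individual methods. Variant alleles
are always expressed on the reference (+) strand; minus-strand genes are
handled by complementation inside effect annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional

__all__ = [
    "PipelineError",
    "ConfigError",
    "FormatError",
    "IntegrityError",
    "Effect",
    "GeneModel",
    "GenomeFixture",
    "EmsVariant",
    "PooledSiteCounts",
    "revcomp",
    "complement",
    "TRANSITIONS",
    "EMS_TRANSITIONS",
]


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(PipelineError):
    """Invalid or inconsistent configuration (CLI exit code 2)."""


class FormatError(PipelineError):
    """Malformed input file (CLI exit code 3)."""


class IntegrityError(PipelineError):
    """Data that is well-formed but internally inconsistent,
    e.g. a variant whose REF allele contradicts the reference genome."""


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

#: All transition substitutions (purine<->purine, pyrimidine<->pyrimidine).
TRANSITIONS = frozenset({("G", "A"), ("A", "G"), ("C", "T"), ("T", "C")})

#: The EMS mutagenesis signature on the reference strand: G:C -> A:T.
EMS_TRANSITIONS = frozenset({("G", "A"), ("C", "T")})


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class Effect(str, Enum):
    """Predicted consequence of a single-nucleotide substitution."""

    INTERGENIC = "intergenic"
    INTRONIC = "intronic"
    SYNONYMOUS = "synonymous"
    MISSENSE = "missense"
    NONSENSE = "nonsense"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene as an ordered set of CDS intervals.

    ``cds_segments`` are (start, end) pairs, 1-based inclusive, in genomic
    order and non-overlapping. The concatenated segments, read on the coding
    strand, form the spliced CDS: it must have length divisible by three.
    """

    gene_id: str
    chrom: str
    strand: str
    cds_segments: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ConfigError(f"gene {self.gene_id}: strand must be '+' or '-'")
        segs = tuple((int(s), int(e)) for s, e in self.cds_segments)
        if not segs:
            raise ConfigError(f"gene {self.gene_id}: no CDS segments")
        for s, e in segs:
            if s < 1 or e < s:
                raise ConfigError(f"gene {self.gene_id}: bad CDS interval ({s}, {e})")
        for (s1, e1), (s2, e2) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise ConfigError(
                    f"gene {self.gene_id}: CDS segments overlap or are unsorted"
                )
        object.__setattr__(self, "cds_segments", segs)
        if self.cds_length % 3 != 0:
            raise FormatError(
                f"gene {self.gene_id}: spliced CDS length {self.cds_length} "
                "is not a multiple of 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds_segments)

    @property
    def start(self) -> int:
        return self.cds_segments[0][0]

    @property
    def end(self) -> int:
        return self.cds_segments[-1][1]

    def contains(self, pos: int) -> bool:
        """Whether ``pos`` falls within the gene span (CDS plus introns)."""
        return self.start <= pos <= self.end

    def in_cds(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.cds_segments)

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """Map a genomic position to its 1-based spliced-CDS coordinate on
        the coding strand, or None if the position is not in the CDS."""
        offset = 0
        plus_offset = None
        for s, e in self.cds_segments:
            if s <= pos <= e:
                plus_offset = offset + (pos - s)
                break
            offset += e - s + 1
        if plus_offset is None:
            return None
        if self.strand == "+":
            return plus_offset + 1
        return self.cds_length - plus_offset

    def cds_to_genomic(self, cds_pos: int) -> int:
        """Inverse of :meth:`genomic_to_cds`."""
        if not 1 <= cds_pos <= self.cds_length:
            raise ConfigError(
                f"gene {self.gene_id}: CDS position {cds_pos} outside "
                f"1..{self.cds_length}"
            )
        plus_offset = cds_pos - 1 if self.strand == "+" else self.cds_length - cds_pos
        for s, e in self.cds_segments:
            seg_len = e - s + 1
            if plus_offset < seg_len:
                return s + plus_offset
            plus_offset -= seg_len
        raise AssertionError("unreachable")

    def spliced_cds(self, chromosomes: dict[str, str]) -> str:
        """Coding-strand spliced CDS sequence."""
        seq = "".join(
            chromosomes[self.chrom][s - 1 : e] for s, e in self.cds_segments
        )
        return seq if self.strand == "+" else revcomp(seq)


@dataclass
class GenomeFixture:
    """A small reference genome with gene models.

    ``chromosomes`` maps chromosome name to an uppercase A/C/G/T sequence
    and preserves insertion order; it is the coordinate frame for every
    downstream stage.
    """

    chromosomes: dict[str, str]
    genes: list[GeneModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, seq in self.chromosomes.items():
            if set(seq) - set("ACGT"):
                bad = sorted(set(seq) - set("ACGT"))
                raise FormatError(
                    f"chromosome {name!r}: non-ACGT characters {bad}"
                )
        for gene in self.genes:
            if gene.chrom not in self.chromosomes:
                raise ConfigError(
                    f"gene {gene.gene_id}: unknown chromosome {gene.chrom!r}"
                )
            if gene.end > len(self.chromosomes[gene.chrom]):
                raise ConfigError(
                    f"gene {gene.gene_id}: extends past end of {gene.chrom}"
                )

    def base_at(self, chrom: str, pos: int) -> str:
        """Reference base at a 1-based position."""
        return self.chromosomes[chrom][pos - 1]

    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def gene_by_id(self, gene_id: str) -> GeneModel:
        for gene in self.genes:
            if gene.gene_id == gene_id:
                return gene
        raise ConfigError(f"gene {gene_id!r} not found in genome")

    def genes_at(self, chrom: str, pos: int) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom == chrom and g.contains(pos)]


@dataclass(frozen=True)
class EmsVariant:
    """One induced single-nucleotide mutation, reference-strand alleles."""

    chrom: str
    pos: int
    ref: str
    mut: str
    effect: Optional[Effect] = None

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.mut) != 1:
            raise FormatError(
                f"{self.chrom}:{self.pos}: alleles must be single bases "
                f"({self.ref!r} -> {self.mut!r})"
            )
        if self.ref == self.mut:
            raise FormatError(
                f"{self.chrom}:{self.pos}: ref and mut alleles are identical"
            )

    @property
    def is_transition(self) -> bool:
        return (self.ref, self.mut) in TRANSITIONS

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)

    def check_reference(self, genome: GenomeFixture) -> None:
        actual = genome.base_at(self.chrom, self.pos)
        if actual != self.ref:
            raise IntegrityError(
                f"{self.chrom}:{self.pos}: REF allele {self.ref} does not "
                f"match reference base {actual}"
            )


@dataclass(frozen=True)
class PooledSiteCounts:
    """Reference/mutant read depths at one site in the selected pool."""

    variant: EmsVariant
    ref_depth: int
    mut_depth: int

    def __post_init__(self) -> None:
        if self.ref_depth < 0 or self.mut_depth < 0:
            raise FormatError(
                f"{self.variant.chrom}:{self.variant.pos}: negative depth"
            )

    @property
    def total_depth(self) -> int:
        return self.ref_depth + self.mut_depth

    @property
    def mut_frequency(self) -> float:
        if self.total_depth == 0:
            raise IntegrityError(
                f"{self.variant.chrom}:{self.variant.pos}: frequency "
                "undefined at zero depth"
            )
        return self.mut_depth / self.total_depth


def sort_variants(variants: Iterable[EmsVariant]) -> list[EmsVariant]:
    """Deterministic (chromosome, position) ordering."""
    return sorted(variants, key=lambda v: (v.chrom, v.pos))
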