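"""The crossover-rate linkage statistic and candidate ranking.

Among F2 plants selected for a fully recessive phenotype, both homologs
carry the causal mutant allele, so a reference allele at a nearby marker
requires one crossover on that homolog. The fraction of reference alleles
among the 2N genotyped homologs therefore estimates the recombination
fraction r between the marker and the causal locus (coupling phase):
fully linked markers do not segregate (rate 0), unlinked markers
segregate 1:1 (rate 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .genome import ConfigError, Effect, EmsVariant, IntegrityError
from .filtering import EffectCall
from .simulate import PAIR, SINGLE_MUT, SINGLE_REF, PeakPattern

__all__ = [
    "GenotypeTally",
    "LinkageResult",
    "CandidateReport",
    "classify_pattern",
    "tally_patterns",
    "crossover_rate",
    "pooled_crossover_rate",
    "expected_crossover_rate",
    "segregation_chi_square",
    "rank_candidates",
]

#: Crossovers implied by each peak class in a phenotype-selected plant:
#: a double peak means one homolog recombined, a single reference peak
#: means both did, a single mutant peak means neither.
_PATTERN_CROSSOVERS = {SINGLE_MUT: 0, PAIR: 1, SINGLE_REF: 2}


def classify_pattern(pattern: str) -> int:
    """Crossover count (0, 1 or 2) implied by one plant's peak pattern."""
    try:
        return _PATTERN_CROSSOVERS[pattern]
    except KeyError:
        raise ConfigError(f"unknown peak pattern {pattern!r}") from None


@dataclass(frozen=True)
class GenotypeTally:
    """Per-site peak-class counts over the genotyped plants."""

    site: EmsVariant
    n_single_mut: int
    n_pair: int
    n_single_ref: int

    def __post_init__(self) -> None:
        if min(self.n_single_mut, self.n_pair, self.n_single_ref) < 0:
            raise ConfigError("negative genotype tally")

    @property
    def n_plants(self) -> int:
        return self.n_single_mut + self.n_pair + self.n_single_ref

    @property
    def n_crossover_alleles(self) -> int:
        """Reference alleles among the genotyped homologs."""
        return self.n_pair + 2 * self.n_single_ref


def tally_patterns(patterns: Iterable[PeakPattern]) -> GenotypeTally:
    counts = {SINGLE_MUT: 0, PAIR: 0, SINGLE_REF: 0}
    site = None
    for p in patterns:
        if site is None:
            site = p.site
        elif p.site.key != site.key:
            raise ConfigError("patterns from multiple sites in one tally")
        counts[p.pattern] += 1
    if site is None:
        raise ConfigError("no peak patterns to tally")
    return GenotypeTally(site, counts[SINGLE_MUT], counts[PAIR], counts[SINGLE_REF])


@dataclass(frozen=True)
class LinkageResult:
    """Crossover rate at one site with an exact binomial CI."""

    site: EmsVariant
    tally: GenotypeTally
    crossover_rate: float
    n_crossover_alleles: int
    n_alleles: int
    ci_low: float
    ci_high: float


def crossover_rate(tally: GenotypeTally, ci_level: float = 0.95) -> LinkageResult:
    """Reference-allele fraction among 2 x n_plants homologs.

    rate = (n_pair + 2 * n_single_ref) / (2 * n_plants), with a
    Clopper-Pearson interval on the allele count. Zero is exact: it occurs
    iff every plant shows a single mutant peak.
    """
    if tally.n_plants == 0:
        raise IntegrityError(
            f"{tally.site.chrom}:{tally.site.pos}: crossover rate undefined "
            "with zero genotyped plants"
        )
    k = tally.n_crossover_alleles
    n = 2 * tally.n_plants
    alpha = 1.0 - ci_level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return LinkageResult(tally.site, tally, k / n, k, n, low, high)


def pooled_crossover_rate(ref_depth: int, mut_depth: int) -> float:
    """Alternative estimator from pooled read counts: one minus the pooled
    mutant-allele frequency. Sequencing error biases it upward at linked
    sites; the per-plant estimator is authoritative when amplicon genotypes
    exist."""
    total = ref_depth + mut_depth
    if total == 0:
        raise IntegrityError("pooled crossover rate undefined at zero depth")
    return ref_depth / total


def expected_crossover_rate(r: float) -> float:
    """Expected crossover rate at a marker with recombination fraction r.

    Selected plants are homozygous mutant at the causal locus; in coupling
    phase each homolog independently carries the marker's reference allele
    with probability r, so the expectation is r itself: 0 under full
    linkage (no segregation), 0.5 when unlinked (1:1 segregation).
    """
    if not 0.0 <= r <= 0.5:
        raise ConfigError(f"recombination fraction must be in [0, 0.5], got {r}")
    return r


def segregation_chi_square(
    observed: Sequence[int], expected_ratio: Sequence[float]
) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of observed category counts to a ratio.

    E.g. (75 tall, 25 short) against 3:1 gives statistic 0. No continuity
    correction (two-category counts here are large); df = k - 1.
    """
    observed = np.asarray(observed, dtype=float)
    expected_ratio = np.asarray(expected_ratio, dtype=float)
    if observed.size < 2 or observed.size != expected_ratio.size:
        raise ConfigError("need matching observed counts and ratio, >= 2 categories")
    if (expected_ratio <= 0).any():
        raise ConfigError("expected ratio terms must be positive")
    expected = expected_ratio / expected_ratio.sum() * observed.sum()
    statistic, p = stats.chisquare(observed, f_exp=expected)
    return float(statistic), observed.size - 1, float(p)


_SEVERITY = {Effect.NONSENSE: 0, Effect.MISSENSE: 1}


@dataclass(frozen=True)
class CandidateReport:
    """One ranked candidate: linkage plus predicted effect."""

    rank: int
    linkage: LinkageResult
    effect: EffectCall
    is_putative_causal: bool
    is_tied_top: bool

    @property
    def site(self) -> EmsVariant:
        return self.linkage.site


def rank_candidates(
    results: Sequence[LinkageResult], calls: Sequence[EffectCall]
) -> list[CandidateReport]:
    """Rank candidates by ascending crossover rate; ties break by effect
    severity (nonsense before missense), then (chromosome, position).

    The top-ranked candidate is flagged putative causal; if several share
    both the minimal rate and the top severity they are flagged as a tie
    set rather than silently resolved.
    """
    by_site = {c.variant.key: c for c in calls}
    missing = [r.site.key for r in results if r.site.key not in by_site]
    if missing:
        raise ConfigError(f"linkage results without effect calls: {missing}")
    if not results:
        return []

    def sort_key(r: LinkageResult):
        call = by_site[r.site.key]
        return (
            r.crossover_rate,
            _SEVERITY.get(call.effect, 2),
            r.site.chrom,
            r.site.pos,
        )

    ordered = sorted(results, key=sort_key)
    top_key = sort_key(ordered[0])[:2]
    n_tied = sum(1 for r in ordered if sort_key(r)[:2] == top_key)
    return [
        CandidateReport(
            rank=i + 1,
            linkage=r,
            effect=by_site[r.site.key],
            is_putative_causal=(i == 0),
            is_tied_top=(n_tied > 1 and sort_key(r)[:2] == top_key),
        )
        for i, r in enumerate(ordered)
    ]
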