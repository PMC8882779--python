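"""Orchestration: simulate -> filter -> annotate -> validate -> rank.

Every run writes a manifest (config snapshot, seed, per-stage counts,
artifact paths, top candidate) that fully determines it: replaying the
manifest's config and seed reproduces every artifact byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import pandas as pd

from . import io
from .filtering import (
    EffectCall,
    FilterConfig,
    annotate_effect,
    filter_allele_frequency,
    filter_transitions,
    select_candidates,
)
from .genome import (
    ConfigError,
    EmsVariant,
    GenomeFixture,
    PooledSiteCounts,
    sort_variants,
)
from .linkage import (
    CandidateReport,
    crossover_rate,
    rank_candidates,
    segregation_chi_square,
    tally_patterns,
)
from .simulate import (
    CrossSimConfig,
    PeakPattern,
    causal_variant,
    make_f2,
    mutagenize,
    select_pool,
    simulate_genome,
    simulate_peak_patterns,
    simulate_pooled_counts,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunManifest",
    "MapResult",
    "map_candidates",
    "run_simulate",
    "run_map",
    "run_segtest",
    "run_end_to_end",
    "write_peak_patterns",
    "read_peak_patterns",
]


# ---------------------------------------------------------------------------
# Peak-pattern TSV (plant id, site, pattern)

_PEAKS_COLUMNS = ["plant_id", "chrom", "pos", "ref", "mut", "pattern"]


def write_peak_patterns(patterns: Sequence[PeakPattern], path: str | Path) -> None:
    rows = [
        {
            "plant_id": p.plant_id,
            "chrom": p.site.chrom,
            "pos": p.site.pos,
            "ref": p.site.ref,
            "mut": p.site.mut,
            "pattern": p.pattern,
        }
        for p in patterns
    ]
    with open(path, "w") as fh:
        fh.write(
            "# per-plant Sanger peak calls: PAIR = double peak (het), "
            "SINGLE_REF = reference homozygote, SINGLE_MUT = mutant homozygote\n"
        )
        pd.DataFrame(rows, columns=_PEAKS_COLUMNS).to_csv(fh, sep="\t", index=False)


def read_peak_patterns(path: str | Path) -> list[PeakPattern]:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise io.FormatError(f"cannot parse peak TSV {path}: {exc}") from exc
    missing = set(_PEAKS_COLUMNS) - set(df.columns)
    if missing:
        raise io.FormatError(f"peak TSV {path} lacks columns {sorted(missing)}")
    return [
        PeakPattern(
            EmsVariant(str(r.chrom), int(r.pos), str(r.ref), str(r.mut)),
            int(r.plant_id),
            str(r.pattern),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# Manifest

@dataclass
class RunManifest:
    """Reproducibility record: what ran, on what, with what result."""

    command: str
    config: dict
    seed: int
    stage_counts: dict = field(default_factory=dict)
    artifacts: dict = field(default_factory=dict)
    top_candidate: Optional[dict] = None

    def validate_funnel(self) -> None:
        stages = ["input", "transitions", "af_pass", "candidates"]
        counts = [self.stage_counts.get(s) for s in stages]
        counts = [c for c in counts if c is not None]
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise ConfigError(f"filter funnel counts increased: {self.stage_counts}")

    def write(self, path: str | Path) -> None:
        self.validate_funnel()
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Mapping cascade (shared by the file-based and in-memory entry points)

@dataclass
class MapResult:
    reports: list[CandidateReport]
    funnel: dict
    candidates_without_genotypes: list[EmsVariant] = field(default_factory=list)


def map_candidates(
    genome: GenomeFixture,
    variants: Sequence[EmsVariant],
    counts: dict[tuple[str, int], PooledSiteCounts],
    get_patterns: Callable[[EmsVariant], Sequence[PeakPattern]],
    filter_config: Optional[FilterConfig] = None,
    restrict_chromosome: Optional[str] = None,
) -> MapResult:
    """Run the full candidate cascade and rank survivors by linkage."""
    fcfg = filter_config or FilterConfig()
    stage1 = filter_transitions(variants, fcfg)
    stage1_counts = [counts[v.key] for v in stage1 if v.key in counts]
    n_uncounted = len(stage1) - len(stage1_counts)
    if n_uncounted:
        logger.info("%d transition sites lack pooled depths", n_uncounted)
    stage2 = filter_allele_frequency(stage1_counts, fcfg)
    calls = [annotate_effect(c.variant, genome) for c in stage2]
    candidates = select_candidates(calls, fcfg, restrict_chromosome)

    results = []
    unmeasured = []
    for call in candidates:
        patterns = get_patterns(call.variant)
        if not patterns:
            unmeasured.append(call.variant)
            continue
        results.append(crossover_rate(tally_patterns(patterns)))
    if unmeasured:
        logger.warning(
            "%d candidates lack per-plant genotypes and are excluded from "
            "ranking", len(unmeasured),
        )
    measured_calls = [c for c in candidates if c.variant.key not in
                      {v.key for v in unmeasured}]
    reports = rank_candidates(results, measured_calls)
    funnel = {
        "input": len(variants),
        "transitions": len(stage1),
        "af_pass": len(stage2),
        "candidates": len(candidates),
    }
    return MapResult(reports, funnel, unmeasured)


def _report_rows(reports: Sequence[CandidateReport]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "rank": r.rank,
                "chrom": r.site.chrom,
                "pos": r.site.pos,
                "ref": r.site.ref,
                "mut": r.site.mut,
                "gene_id": r.effect.gene_id,
                "effect": r.effect.effect.value,
                "aa_change": (
                    f"{r.effect.ref_aa}{r.effect.codon_index}{r.effect.mut_aa}"
                    if r.effect.codon_index
                    else ""
                ),
                "n_single_mut": r.linkage.tally.n_single_mut,
                "n_pair": r.linkage.tally.n_pair,
                "n_single_ref": r.linkage.tally.n_single_ref,
                "crossover_alleles": r.linkage.n_crossover_alleles,
                "total_alleles": r.linkage.n_alleles,
                "crossover_rate": r.linkage.crossover_rate,
                "ci_low": r.linkage.ci_low,
                "ci_high": r.linkage.ci_high,
                "putative_causal": r.is_putative_causal,
                "tied_top": r.is_tied_top,
            }
            for r in reports
        ]
    )


def write_candidate_report(
    reports: Sequence[CandidateReport], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write(
            "# candidates ranked by ascending crossover rate "
            "(reference alleles / total genotyped alleles); ties broken by "
            "effect severity then position\n"
        )
        _report_rows(reports).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Entry points

def run_simulate(config: CrossSimConfig, out_dir: str | Path) -> RunManifest:
    """Simulate the full experiment and write all fixture artifacts.

    Writes reference.fasta, genes.gff3, variants.vcf (with pooled depths in
    the POOL sample), peaks.tsv (per-plant genotypes at every variant site)
    and manifest.json. Reruns with the same config and seed are
    byte-identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = simulate_genome(seed=config.seed)
    variants = mutagenize(genome, config)
    population = make_f2(genome, variants, config)
    pool = select_pool(population, config)
    counts = simulate_pooled_counts(pool, variants, config)
    patterns: list[PeakPattern] = []
    for variant in variants:
        patterns.extend(simulate_peak_patterns(pool, variant, config))

    paths = {
        "fasta": out / "reference.fasta",
        "gff3": out / "genes.gff3",
        "vcf": out / "variants.vcf",
        "peaks": out / "peaks.tsv",
        "manifest": out / "manifest.json",
    }
    io.write_fasta(genome.chromosomes, paths["fasta"])
    io.write_gff3(genome.genes, paths["gff3"])
    io.write_variants_vcf(
        variants,
        paths["vcf"],
        {name: len(seq) for name, seq in genome.chromosomes.items()},
        {c.variant.key: c for c in counts},
    )
    write_peak_patterns(patterns, paths["peaks"])

    causal = causal_variant(genome, config)
    n_dwarf = sum(ind.phenotype == "dwarf" for ind in population)
    manifest = RunManifest(
        command="simulate",
        config=config.to_dict(),
        seed=config.seed,
        stage_counts={
            "variants": len(variants),
            "f2": len(population),
            "dwarf_f2": n_dwarf,
            "pool": len(pool),
            "genotyped_sites": len(variants),
        },
        artifacts={k: str(v) for k, v in paths.items()},
        top_candidate=None,
    )
    manifest.config["true_causal_site"] = {
        "chrom": causal.chrom,
        "pos": causal.pos,
        "ref": causal.ref,
        "mut": causal.mut,
    }
    manifest.write(paths["manifest"])
    return manifest


def run_map(
    vcf: str | Path,
    fasta: str | Path,
    gff3: str | Path,
    peaks: str | Path,
    out_dir: str | Path,
    filter_config: Optional[FilterConfig] = None,
    restrict_chromosome: Optional[str] = None,
) -> tuple[MapResult, RunManifest]:
    """File-based mapping run: cascade + ranking + report artifacts.

    An empty candidate set is reported with a warning, not an error.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chromosomes = io.read_fasta(fasta)
    genes = io.read_gff3(gff3, chromosomes)
    genome = GenomeFixture(chromosomes, genes)
    vcf_result = io.read_variants_vcf(vcf, genome=genome)
    peak_list = read_peak_patterns(peaks)
    by_site: dict[tuple[str, int], list[PeakPattern]] = {}
    for p in peak_list:
        by_site.setdefault(p.site.key, []).append(p)

    result = map_candidates(
        genome,
        vcf_result.variants,
        vcf_result.counts,
        lambda v: by_site.get(v.key, []),
        filter_config,
        restrict_chromosome,
    )

    report_path = out / "candidates.tsv"
    funnel_path = out / "funnel.json"
    manifest_path = out / "map_manifest.json"
    write_candidate_report(result.reports, report_path)
    Path(funnel_path).write_text(json.dumps(result.funnel, indent=2) + "\n")

    top = None
    if result.reports:
        r = result.reports[0]
        top = {
            "chrom": r.site.chrom,
            "pos": r.site.pos,
            "gene_id": r.effect.gene_id,
            "effect": r.effect.effect.value,
            "crossover_rate": r.linkage.crossover_rate,
            "tied_top": r.is_tied_top,
        }
    fcfg = filter_config or FilterConfig()
    manifest = RunManifest(
        command="map",
        config={
            "allele_frequency_threshold": fcfg.allele_frequency_threshold,
            "transition_set": sorted(map(list, fcfg.transition_set)),
            "candidate_effects": sorted(e.value for e in fcfg.candidate_effects),
            "restrict_chromosome": restrict_chromosome,
        },
        seed=0,
        stage_counts=dict(result.funnel, skipped_vcf_records=vcf_result.n_skipped),
        artifacts={
            "vcf": str(vcf),
            "fasta": str(fasta),
            "gff3": str(gff3),
            "peaks": str(peaks),
            "report": str(report_path),
            "funnel": str(funnel_path),
        },
        top_candidate=top,
    )
    manifest.write(manifest_path)
    return result, manifest


def run_segtest(
    observed: Sequence[int], expected_ratio: Sequence[float]
) -> dict:
    """Chi-square goodness of fit of phenotype counts to a Mendelian ratio."""
    statistic, df, p = segregation_chi_square(observed, expected_ratio)
    return {
        "observed": list(map(int, observed)),
        "expected_ratio": list(map(float, expected_ratio)),
        "statistic": statistic,
        "df": df,
        "p_value": p,
    }


@dataclass
class EndToEndResult:
    map_result: MapResult
    true_causal: EmsVariant
    config: CrossSimConfig

    @property
    def top_is_causal(self) -> bool:
        reports = self.map_result.reports
        return bool(reports) and reports[0].site.key == self.true_causal.key


def run_end_to_end(
    config: CrossSimConfig,
    filter_config: Optional[FilterConfig] = None,
    genome: Optional[GenomeFixture] = None,
    restrict_chromosome: Optional[str] = None,
) -> EndToEndResult:
    """In-memory simulate-and-map round trip (no files).

    Per-plant genotypes are generated only at candidate sites, mirroring
    amplicon validation of the shortlisted SNPs.
    """
    if genome is None:
        genome = simulate_genome(seed=config.seed)
    variants = mutagenize(genome, config)
    population = make_f2(genome, variants, config)
    pool = select_pool(population, config)
    counts = simulate_pooled_counts(pool, variants, config)
    result = map_candidates(
        genome,
        variants,
        {c.variant.key: c for c in counts},
        lambda v: simulate_peak_patterns(pool, v, config),
        filter_config,
        restrict_chromosome,
    )
    return EndToEndResult(result, causal_variant(genome, config), config)
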