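"""Simulator behaviour: mutagenesis spectrum, meiosis, phenotype law,
selection, pooled sequencing and peak-pattern genotyping."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import emsmap as em
from emsmap.simulate import B73, DWARF, MUT, PAIR, SINGLE_MUT, SINGLE_REF

from ._util import marker_at_r, ref_allele_fraction, selected_pools


class TestMutagenize:
    def test_pure_transition_fraction_forces_ems_spectrum(self, genome):
        config = em.CrossSimConfig(seed=1, transition_fraction=1.0,
                                   ems_mutation_rate=3e-4)
        variants = em.mutagenize(genome, config)
        assert len(variants) > 10
        assert all((v.ref, v.mut) in {("G", "A"), ("C", "T")} for v in variants)

    def test_zero_rate_leaves_only_injected_causal(self, genome):
        config = em.CrossSimConfig(seed=1, ems_mutation_rate=0.0)
        variants = em.mutagenize(genome, config)
        assert variants == [em.causal_variant(genome, config)]

    def test_mutation_count_matches_poisson_mean(self):
        # 100 kb single-chromosome genome, rate 1e-3: expect 100 + 1 (causal)
        genome = em.simulate_genome(
            seed=2, chrom_lengths={"chr3": 100_000}, genes_per_chrom=1
        )
        rate = 1e-3
        counts = [
            len(em.mutagenize(genome, em.CrossSimConfig(seed=s, ems_mutation_rate=rate)))
            for s in range(200)
        ]
        se = math.sqrt(100 / 200)
        assert abs(np.mean(counts) - 101) < 3 * se

    def test_variants_match_reference_and_are_unique(self, genome, config):
        variants = em.mutagenize(genome, config)
        for v in variants:
            v.check_reference(genome)
        assert len({v.key for v in variants}) == len(variants)

    def test_missing_causal_gene_is_config_error(self, genome):
        config = em.CrossSimConfig(seed=1, causal_gene="no_such_gene")
        with pytest.raises(em.ConfigError, match="no_such_gene"):
            em.mutagenize(genome, config)


class TestHaldane:
    def test_closed_form_values(self):
        assert em.haldane_r_from_d(0.0) == 0.0
        assert em.haldane_r_from_d(50.0) == pytest.approx((1 - math.exp(-1)) / 2)
        assert em.haldane_r_from_d(10_000.0) == pytest.approx(0.5, abs=1e-6)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=0.0, max_value=0.499, allow_nan=False))
    def test_inverse_round_trips(self, r):
        assert em.haldane_r_from_d(em.haldane_d_from_r(r)) == pytest.approx(
            r, abs=1e-9
        )


class TestMakeF2:
    def test_zero_map_length_gives_whole_chromosome_haplotypes(self, genome):
        config = em.CrossSimConfig(seed=3, map_length_cM=0.0, n_f2=50)
        causal = em.causal_variant(genome, config)
        for ind in em.make_f2(genome, [causal], config):
            for chrom, (a, b) in ind.haplotypes.items():
                for hap in (a, b):
                    segs = hap.segments(len(genome.chromosomes[chrom]))
                    assert len(segs) == 1
                    assert segs[0][2] in (MUT, B73)

    def test_dwarf_fraction_near_one_quarter(self, genome):
        config = em.CrossSimConfig(seed=4, n_f2=2000)
        causal = em.causal_variant(genome, config)
        population = em.make_f2(genome, [causal], config)
        frac = np.mean([ind.phenotype == DWARF for ind in population])
        se = math.sqrt(0.25 * 0.75 / 2000)
        assert abs(frac - 0.25) < 3 * se

    def test_every_dwarf_is_homozygous_mutant_at_causal_site(self, genome, config):
        causal = em.causal_variant(genome, config)
        for ind in em.make_f2(genome, [causal], config):
            if ind.phenotype == DWARF:
                assert ind.n_mut_alleles(causal.chrom, causal.pos) == 2

    def test_haplotype_segments_tile_and_alternate(self, genome, config):
        causal = em.causal_variant(genome, config)
        ind = em.make_f2(genome, [causal], config)[0]
        for chrom, (a, b) in ind.haplotypes.items():
            length = len(genome.chromosomes[chrom])
            for hap in (a, b):
                segs = hap.segments(length)
                assert segs[0][0] == 1 and segs[-1][1] == length
                for (s1, e1, anc1), (s2, e2, anc2) in zip(segs, segs[1:]):
                    assert s2 == e1 + 1
                    assert anc1 != anc2

    def test_backcross_population_still_segregates_dwarfs(self, two_chrom_genome):
        config = em.CrossSimConfig(seed=5, n_f2=400, backcross_first=True)
        causal = em.causal_variant(two_chrom_genome, config)
        population = em.make_f2(two_chrom_genome, [causal], config)
        frac = np.mean([ind.phenotype == DWARF for ind in population])
        se = math.sqrt(0.25 * 0.75 / 400)
        assert abs(frac - 0.25) < 4 * se

    def test_same_seed_is_bit_reproducible(self, two_chrom_genome, config):
        causal = em.causal_variant(two_chrom_genome, config)
        runs = []
        for _ in range(2):
            pop = em.make_f2(two_chrom_genome, [causal], config)
            pool = em.select_pool(pop, config)
            counts = em.simulate_pooled_counts(pool, [causal], config)
            runs.append(
                (
                    [ind.phenotype for ind in pop],
                    [(c.ref_depth, c.mut_depth) for c in counts],
                )
            )
        assert runs[0] == runs[1]


class TestSelectPool:
    def test_shortage_reports_achievable_count(self, genome):
        config = em.CrossSimConfig(seed=6, n_f2=60, n_selected=40)
        causal = em.causal_variant(genome, config)
        population = em.make_f2(genome, [causal], config)
        n_dwarf = sum(ind.phenotype == DWARF for ind in population)
        assert n_dwarf < 40  # 60 plants cannot yield 40 dwarfs
        with pytest.raises(em.ConfigError, match=str(n_dwarf)):
            em.select_pool(population, config)

    def test_pool_is_all_dwarf_and_right_size(self, genome, config):
        causal = em.causal_variant(genome, config)
        pool = em.select_pool(em.make_f2(genome, [causal], config), config)
        assert len(pool) == config.n_selected
        assert all(ind.phenotype == DWARF for ind in pool)


class TestPooledCounts:
    def test_error_free_causal_site_is_pure_mutant(self, genome, config):
        causal = em.causal_variant(genome, config)
        cfg = em.CrossSimConfig(seed=config.seed, seq_error_rate=0.0)
        pool = em.select_pool(em.make_f2(genome, [causal], cfg), cfg)
        [counts] = em.simulate_pooled_counts(pool, [causal], cfg)
        assert counts.ref_depth == 0
        assert counts.mut_depth == counts.total_depth > 0

    def test_sequencing_error_shifts_fixed_site_frequency(self, genome):
        # at a fixed site, E[mutant read fraction] = 1 - e
        cfg = em.CrossSimConfig(seed=8, seq_error_rate=0.01, pool_depth=200_000)
        causal = em.causal_variant(genome, cfg)
        pool = em.select_pool(em.make_f2(genome, [causal], cfg), cfg)
        [counts] = em.simulate_pooled_counts(pool, [causal], cfg)
        se = math.sqrt(0.01 * 0.99 / 200_000)
        assert counts.mut_frequency == pytest.approx(0.99, abs=4 * se)


class TestSelectionAlleleFrequencyLaw:
    """At a marker with recombination fraction r from the causal locus
    (coupling phase), the expected reference-allele frequency among
    phenotype-selected F2 equals r."""

    @pytest.mark.parametrize("r", [0.0, 0.1, 0.25, 0.5])
    def test_mean_reference_frequency_equals_r(self, two_chrom_genome, r):
        n_reps = 50
        config0 = em.CrossSimConfig(seed=0)
        marker = marker_at_r(two_chrom_genome, config0, r)
        fractions = [
            ref_allele_fraction(pool, marker)
            for pool, _ in selected_pools(two_chrom_genome, n_reps, seed0=100)
        ]
        if r == 0.0:
            assert fractions == [0.0] * n_reps
        else:
            se = math.sqrt(r * (1 - r) / (2 * 40 * n_reps))
            assert abs(np.mean(fractions) - r) < 3 * se


class TestPeakPatterns:
    def test_causal_site_error_free_is_all_single_mutant_peaks(
        self, genome, config
    ):
        causal = em.causal_variant(genome, config)
        pool = em.select_pool(em.make_f2(genome, [causal], config), config)
        patterns = em.simulate_peak_patterns(pool, causal, config)
        assert len(patterns) == 40
        assert all(p.pattern == SINGLE_MUT for p in patterns)

    def test_pattern_maps_genotype_classes(self, two_chrom_genome):
        # an unlinked marker segregates all three genotypes in a big pool
        config = em.CrossSimConfig(seed=9, n_f2=600, n_selected=150)
        marker = marker_at_r(two_chrom_genome, config, 0.5)
        causal = em.causal_variant(two_chrom_genome, config)
        pool = em.select_pool(em.make_f2(two_chrom_genome, [causal], config), config)
        patterns = em.simulate_peak_patterns(pool, marker, config)
        expected = {2: SINGLE_MUT, 1: PAIR, 0: SINGLE_REF}
        for plant, pattern in zip(pool, patterns):
            dosage = plant.n_mut_alleles(marker.chrom, marker.pos)
            assert pattern.pattern == expected[dosage]
        assert {p.pattern for p in patterns} == {SINGLE_MUT, PAIR, SINGLE_REF}

    def test_total_genotyping_error_never_matches_truth(self, genome):
        config = em.CrossSimConfig(seed=10, genotyping_error_rate=1.0)
        causal = em.causal_variant(genome, config)
        pool = em.select_pool(em.make_f2(genome, [causal], config), config)
        patterns = em.simulate_peak_patterns(pool, causal, config)
        assert all(p.pattern != SINGLE_MUT for p in patterns)
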