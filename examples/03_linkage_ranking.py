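"""Rank candidate mutations by the crossover-rate statistic.

Each selected dwarf is Sanger-genotyped at every candidate site; a double
peak means one homolog recombined, a single reference peak both, a single
mutant peak neither. The fraction of reference alleles among the 80
homologs estimates the recombination fraction to the causal locus.
"""

import emsmap as em

genome = em.simulate_genome(seed=0)
config = em.CrossSimConfig(seed=0)
result = em.run_end_to_end(config, genome=genome)

print(f"{'rank':>4} {'site':>14} {'gene':>12} {'effect':>9} "
      f"{'rate':>6} {'95% CI':>15}")
for r in result.map_result.reports:
    ci = f"[{r.linkage.ci_low:.3f}, {r.linkage.ci_high:.3f}]"
    print(
        f"{r.rank:>4} {r.site.chrom}:{r.site.pos:>9} "
        f"{r.effect.gene_id:>12} {r.effect.effect.value:>9} "
        f"{r.linkage.crossover_rate:>6.3f} {ci:>15}"
    )
causal = result.true_causal
print(f"\ntrue causal site: {causal.chrom}:{causal.pos} "
      f"(recovered: {result.top_is_causal})")
print("Rate 0 means no selected plant carries a reference allele there:")
print("the site is fully linked to (here, identical to) the causal lesion.")
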