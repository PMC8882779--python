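# emsmap

Mapping-by-sequencing of EMS-induced recessive mutants (MutMap-style
bulked segregant analysis), built around a fully simulated experiment so
that every inference stage is testable without any sequencing download.

The workflow it implements is the classic forward-genetics route to a
causal gene in a crop like maize: an EMS-mutagenized line showing a
recessive phenotype (here, dwarfism) is crossed to the reference inbred,
the F1 is selfed, and DNA from ~40 phenotype-selected F2 plants is pooled
and sequenced. Because every selected plant is homozygous for the causal
allele, variants linked to the causal locus approach fixation in the
pool, while unlinked EMS markers segregate 1:1.

## Who it is for

Researchers and students who want a small, fully reproducible model of
pooled mutant mapping: to understand the statistics, to benchmark filter
thresholds, or to sanity-check an analysis plan before committing a real
F2 population to sequencing.

## The model and statistics

- **Cross simulation.** The mutant line is homozygous for all induced
  mutations (coupling phase). F2 gametes recombine with crossover count
  ~ Poisson(*L*/100) per chromosome of genetic length *L* cM and uniform
  breakpoints — the Haldane, no-interference model, so two loci *d* cM
  apart recombine with probability *r* = (1 − e^(−2d/100))/2. The dwarf
  phenotype appears iff both homologs carry mutant ancestry at the causal
  site (single recessive locus, complete penetrance), giving the 3:1 F2
  ratio.
- **Candidate cascade.** Variants are filtered to the EMS signature
  (reference G→A or C→T transitions), then to pooled mutant-allele
  frequency ≥ 90% in the selected pool, then annotated codon-by-codon
  against the gene models and restricted to protein-changing
  (missense/nonsense) calls.
- **Crossover-rate statistic.** Each selected plant is genotyped at a
  candidate site by its Sanger peak pattern: a double peak = one
  recombinant homolog, a single reference peak = two, a single mutant
  peak = none. The rate (n_pair + 2·n_single_ref)/(2·n_plants) is the
  reference-allele fraction among homologs and estimates *r* to the
  causal locus: 0 under full linkage, 0.5 when unlinked. Candidates are
  ranked by ascending rate (ties: nonsense before missense), with exact
  Clopper–Pearson binomial intervals.
- **Segregation tests.** Pearson chi-square goodness of fit of phenotype
  or allele counts to Mendelian ratios (3:1, 1:1).

## Worked example

`python examples/03_linkage_ranking.py` simulates the full experiment
(genome, mutagenesis, cross, 40-plant dwarf pool, per-plant genotypes at
the shortlisted candidates) and ranks the candidates:

```
rank           site         gene    effect   rate          95% CI
   1 chr3:    60094        zmte1  nonsense  0.000  [0.000, 0.045]

true causal site: chr3:60094 (recovered: True)
```

The single surviving candidate is the injected causal lesion — a C→T at
spliced-CDS position 547 turning a CAG glutamine codon into a TAG stop —
and its crossover rate is exactly 0: none of the 80 homologs of the 40
selected dwarfs carries a reference allele there. The funnel leading to
it (`python examples/02_filter_cascade.py`):

```
induced SNVs:            42
EMS transitions:         37
pool frequency >= 90%:   2
protein-changing:        1
```

## Command line

A thin CLI wraps the library: `emsmap simulate` writes a complete
synthetic experiment (FASTA, GFF3, VCF with pooled depths, peak-pattern
TSV, manifest), `emsmap map` runs the cascade and ranking on those files,
and `emsmap segtest --counts 75,25 --ratio 3,1` tests a segregation
ratio. Exit codes: 0 success, 2 configuration error, 3 input-format
error.

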