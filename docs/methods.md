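# Methods

## The procedure being modelled

A recessive mutant recovered from an EMS screen is crossed to the
reference inbred; the heterozygous F1 is selfed; F2 plants showing the
mutant phenotype are pooled and sequenced. Selection makes the pool
homozygous mutant at the causal locus, so the causal lesion and tightly
linked EMS markers approach 100% mutant-allele frequency in pooled reads,
while unlinked markers stay near 50%. Shortlisted candidates are then
genotyped plant-by-plant (Sanger amplicons), and the fraction of
reference alleles among the 2N homologs — the crossover rate — estimates
each candidate's recombination fraction to the causal locus.

## Genetic model and assumptions

- **Meiosis.** Crossovers per gamete and chromosome are
  Poisson(map_length_cM/100) with uniform breakpoint positions: the
  Haldane model, chosen because it is the minimal standard model without
  interference and yields the closed form r = (1 − e^(−2d/100))/2 used in
  the invariant checks. The bp→cM map is linear along each chromosome.
- **Coupling phase.** All induced mutations sit on the mutant-line
  haplotype, as is true of a mutagenized inbred. This is what makes the
  expected crossover rate at a marker equal its recombination fraction r
  in phenotype-selected F2: each homolog of a selected plant carries the
  marker's reference allele iff it recombined between marker and causal
  locus, independently with probability r.
- **Phenotype.** One fully recessive causal locus with complete
  penetrance and no phenotyping error (both configurable only through the
  genotype rule itself); unselected F2 therefore segregate 3:1.
- **Cross design.** The default is mutant × reference F1 selfed. A
  single backcross to the reference before selfing is supported
  (`backcross_first`), conditioned on the BC1 inheriting the causal
  allele; it halves background heterozygosity but changes none of the
  closed-form expectations, so it is off by default.

## Synthetic data generator

`simulate_genome` builds a 3 × 100 kb, 9-gene reference (uppercase
A/C/G/T only; genes are valid ORFs on both strands, one or two exons).
The causal gene is a plus-strand single-exon gene on chr3 whose codon 183
is forced to CAG, so the injected lesion — C→T at spliced-CDS position
547 = 3·182 + 1 — creates a TAG premature stop, the canonical
EMS-induced nonsense pattern (Gln→stop).

`mutagenize` draws Poisson(rate × genome length) mutations,
`transition_fraction` of them G→A/C→T at G/C sites and the rest random
transversions (present only to exercise the transition filter), at most
one per position, causal lesion always injected. Pooled sequencing draws
per-site depth ~ Poisson(pool_depth); each read samples an allele at the
pool's true frequency (equimolar plants, two homologs each) and flips to
the other allele with probability `seq_error_rate`. Peak-pattern calls
are the true genotype class, replaced by a uniformly chosen wrong class
with probability `genotyping_error_rate`.

What the generator does **not** emulate: read-level data (FASTQ,
mapping, base qualities), capture-efficiency variation across exome
baits, polygenic or environmental phenotype variance, segregation
distortion, and genotyping dropout. Passing tests therefore demonstrate
the correctness of the statistics and filters under the stated genetic
model, not robustness to real-data artefacts such as mapping bias or
uneven capture.

## Defaults and why

| parameter | default | rationale |
|---|---|---|
| n_selected | 40 plants | standard pool size for this design |
| n_f2 | 300 | keeps P(<40 dwarfs) negligible (~10⁻⁶) |
| map_length_cM | 150 per chromosome | typical cereal chromosome scale |
| ems_mutation_rate | 1e-4 /bp | gives a few dozen sites on 300 kb, a readable funnel |
| transition_fraction | 0.9 | EMS is strongly but not perfectly G:C→A:T biased |
| pool_depth | 100 (Poisson) | typical pooled exome depth; not a measured value |
| seq_error_rate | 0.01 | short-read scale error |
| allele_frequency_threshold | 0.90 | the cascade's retention cut |
| genotyping_error_rate | 0 | Sanger amplicon calls treated as clean |

The 90% cut is interpreted as **mutant-allele frequency in the selected
pool** ≥ 0.90; a "minor allele frequency ≥ 90%" is not otherwise
meaningful, and fixation of the mutant allele is what phenotype selection
predicts. The transition filter keeps only reference G→A and C→T (not
all four transition orientations) because alleles are reference-strand
normalised and EMS alkylates G; an all-transitions mode is configurable.

## Numerical and edge-case choices

- Coordinates are 1-based inclusive at every API surface (VCF/GFF3
  conventions); 0-based arithmetic is confined to method internals.
- Haplotypes are stored as breakpoint lists, not per-base arrays; a base
  belongs to the mutant-line segment iff an even number of breakpoints
  precede it. Breakpoint pairs falling within one base boundary cancel.
- Effect annotation mutates a single codon and translates with the
  standard nuclear code; a brute-force oracle (rebuild the whole mutant
  CDS, translate, diff) checks it in the tests. Start-loss and stop-loss
  are reported as missense; a gained stop is nonsense. A variant on a
  CDS/intron boundary base belongs to the CDS. Splice sites are not
  modelled.
- Zero-depth pooled sites are dropped (logged), never classified; a
  crossover rate over zero genotyped plants is an error, never a silent
  zero. Candidates without per-plant genotypes are excluded from ranking
  with a warning. The pooled-read estimator (1 − pooled mutant
  frequency) is exposed as a fallback, with the caveat that sequencing
  error biases it upward at linked sites; the per-plant estimator is
  authoritative.
- Chi-square uses no continuity correction; the two-category counts used
  here are large.
- Ranking ties at the same rate are broken by effect severity (nonsense
  before missense) and then by position; if several candidates share both
  the minimal rate and top severity, the whole set is flagged as tied
  rather than silently resolved.
- One integer seed drives everything; each stage (mutagenesis, meiosis,
  selection, pooling, genotyping) uses an independent child stream, so a
  run is bit-reproducible and changing one stage's parameters does not
  perturb the others' draws.

## Problem sizes used in the checks

The statistical checks run at desk scale, sized so that Monte-Carlo
standard errors are small relative to the effects tested: 10,000 F2 for
the 3:1 ratio; 20 seeded 40-plant pools for exact full linkage; 100
pools for the unlinked 1:1 expectation; 200 pools per recombination
fraction (r ∈ {0, 0.05, 0.1, 0.25, 0.5}) for estimator recovery; 1,000
random SNVs for the annotation oracle; 100 end-to-end runs for
causal-gene recovery. Acceptance bands are 3 SE throughout.

## Known limitations

- The linear bp→cM map and uniform gene placement are conveniences; real
  recombination landscapes are highly non-uniform.
- Genome-scale variant counts from a real exome-capture experiment
  (tens of thousands of SNVs) are mirrored only qualitatively by the
  funnel at the fixture's ~300 kb scale.
- The allele-frequency filter implements a frequency threshold only; no
  base- or mapping-quality model exists because reads are not simulated.
- Per-site genotyping denominators below the pool size (failed
  amplicons) are supported in the tallies but not generated by the
  simulator.
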