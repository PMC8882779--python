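"""Chi-square tests of Mendelian segregation ratios.

Phenotype counts against 3:1 (recessive F2 expectation) and marker allele
counts against 1:1 (unlinked-site expectation in a selected pool).
"""

import emsmap as em

for observed, ratio, label in [
    ([75, 25], [3, 1], "phenotypes 75 tall : 25 short vs 3:1"),
    ([90, 10], [3, 1], "phenotypes 90 tall : 10 short vs 3:1"),
    ([40, 40], [1, 1], "alleles 40 ref : 40 mut vs 1:1"),
]:
    stat, df, p = em.segregation_chi_square(observed, ratio)
    print(f"{label}:  chi2={stat:.2f}  df={df}  p={p:.4f}")
print("The first and third fit their expected ratios exactly (chi2 = 0);")
print("the second deviates strongly, rejecting a single recessive locus.")
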