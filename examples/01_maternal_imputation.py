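"""Maternal genotype posteriors from infant genotypes.

The mother of a genotyped infant passed it exactly one allele; under
random mating (HWE) that pins down a closed-form posterior over her
genotype.  This script prints the posterior for each infant genotype at
a desaturase-locus-like allele frequency, and shows how much genotype
information a single child actually carries (the IMPUTE-style info
score of the imputed cohort).
"""

import numpy as np

import milkgwas as mg

p = 0.17  # reference-allele frequency

print(f"reference-allele frequency p = {p}")
for c in (0, 1, 2):
    post = mg.maternal_posterior_given_child(c, p)
    print(f"  infant carries {c} ref alleles -> maternal posterior "
          f"(pi0, pi1, pi2) = ({post[0]:.3f}, {post[1]:.3f}, {post[2]:.3f})")

# an uncertain (imputed) infant call mixes the three closed forms
child = np.array([0.1, 0.8, 0.1])
post = mg.maternal_posterior_from_probabilistic(child, p)
print(f"uncertain infant {child.tolist()} -> maternal ({post[0]:.3f}, "
      f"{post[1]:.3f}, {post[2]:.3f})")

# info score: hard infant calls are fully informative about the infant,
# but the *maternal* posteriors retain only part of that information
rng = np.random.default_rng(1)
n = 5000
mother = rng.binomial(2, p, n)
father = rng.binomial(2, p, n)
infant = rng.binomial(1, mother / 2) + rng.binomial(1, father / 2)
maternal, p_hat = mg.impute_cohort(infant[None, :])
print(f"\ncohort of {n} dyads: estimated p = {p_hat[0]:.4f}")
print(f"infant info score   = {mg.info_score(mg.hard_to_triples(infant)):.3f}")
print(f"maternal info score = {mg.info_score(maternal[0]):.3f}  "
      "(one child tells you a lot, but not everything, about its mother)")
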