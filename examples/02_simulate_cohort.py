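"""Simulate a mother-father-infant cohort with compositional phenotypes.

Generates HWE parents, Mendelian infants and a 26-fraction breast-milk
fatty-acid profile per mother (log-normal with block correlation by
lipid class, closed to 100 %wt/wt), with a configured multiplicative
SNP effect on arachidonic acid (AA).
"""

import numpy as np

import milkgwas as mg
from milkgwas.fatty_acids import FA_NAMES
from milkgwas.simulate import GeneticEffect

cfg = mg.SimConfig(
    n_dyads=1000,
    variants=[mg.Variant("11", 61_580_635, "T", "C", raf=0.17, snp_id="rs_lead")],
    seed=7,
    genetic_effects=[GeneticEffect(0, "AA", 0.85)],  # x0.85 per ref allele
)
cohort, table = mg.simulate_study(cfg)

sums = table[list(FA_NAMES)].sum(axis=1)
print(f"{cfg.n_dyads} dyads; fractions sum to 100 per mother "
      f"(max deviation {np.abs(sums - 100).max():.2e})")
print(f"mean AA fraction = {table['AA'].mean():.3f} %wt/wt "
      f"(target {cfg.fa_means['AA']})")

for g in (0, 1, 2):
    sel = cohort.maternal[0] == g
    print(f"mothers with {g} ref alleles (n={sel.sum():4d}): "
          f"mean AA = {table.loc[sel, 'AA'].mean():.3f}")
print("each additional reference allele multiplies AA by ~0.85, "
      "as configured")
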