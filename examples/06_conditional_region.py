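"""Regional conditional scans: is there a second independent signal?

After a locus is found, two conditioning strategies probe its
structure: adding the associated phenotype (log AA) as a covariate
tests whether other phenotypes' signals are merely mediated by AA, and
adding the lead variant's posterior-mean maternal dosage tests for a
second independent variant.  Conditioning a variant on its own dosage
must annihilate its signal - a built-in self-check.
"""

import milkgwas as mg
from milkgwas.simulate import GeneticEffect

REGION = ("11", 61_547_000, 61_673_000)

variants = [
    mg.Variant("11", 61_580_635, "T", "C", raf=0.17, snp_id="rs_lead"),
    mg.Variant("11", 61_600_000, "A", "G", raf=0.30, snp_id="rs_other"),
]
studies = []
for name, n, seed in (("URBAN", 532, 5), ("RURAL", 610, 6)):
    cfg = mg.SimConfig(n_dyads=n, variants=variants, seed=seed,
                       genetic_effects=[GeneticEffect(0, "AA", 0.85)])
    cohort, table = mg.simulate_study(cfg)
    studies.append(mg.Study.from_simulation(name, cohort, table))

plain = mg.regional_conditional_scan(studies, REGION, None, phenotype_names=["AA"])
on_snp = mg.regional_conditional_scan(
    studies, REGION, ("variant", "rs_lead"), phenotype_names=["AA"]
)

for label, df in (("unconditioned", plain), ("conditioned on rs_lead", on_snp)):
    print(f"\n{label}:")
    print(df[["snp_id", "beta_reported", "p_meta"]].to_string(index=False))
print("\nconditioning on the causal variant's dosage removes its own "
      "association (p -> 1): no second independent signal remains")
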