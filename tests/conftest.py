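import numpy as np
import pytest
from hypothesis import settings

import milkgwas as mg
from milkgwas.simulate import GeneticEffect

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20231105)


@pytest.fixture
def lead_variant():
    """The prototypical desaturase-locus lead SNP scenario (raf 0.17)."""
    return mg.Variant("11", 61_580_635, "T", "C", raf=0.17, snp_id="rs_lead")


@pytest.fixture
def small_cohort(lead_variant):
    """A modest simulated study with one causal variant (factor 0.85 on AA)."""
    cfg = mg.SimConfig(
        n_dyads=500,
        variants=[lead_variant, mg.Variant("2", 10_000_000, "A", "G", raf=0.4, snp_id="rs_null")],
        seed=42,
        genetic_effects=[GeneticEffect(0, "AA", 0.85)],
    )
    cohort, table = mg.simulate_study(cfg)
    return cohort, table


def trio_posterior_oracle(c: int, p: float) -> np.ndarray:
    """Brute-force maternal posterior by enumerating all mother x father
    HWE genotype pairs, weighting by Mendelian transmission and
    conditioning on the child's reference-allele count."""
    q = 1 - p
    prior = np.array([q * q, 2 * p * q, p * p])
    post = np.zeros(3)
    for m in range(3):
        for f in range(3):
            for am in (0, 1):
                for af in (0, 1):
                    pa = (m / 2 if am else 1 - m / 2) * (f / 2 if af else 1 - f / 2)
                    if am + af == c:
                        post[m] += prior[m] * prior[f] * pa
    return post / post.sum()
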