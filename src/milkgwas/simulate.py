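"""Synthetic mother-father-infant dyads and compositional FA phenotypes.

The generator inverts the inference model of the pipeline so every
downstream stage can be validated against known truth without any real
data:

* Parents are independent draws from Hardy-Weinberg equilibrium at each
  variant's reference-allele frequency; the infant receives one allele
  drawn uniformly from each parent (obligate Mendelian transmission).
  Variants are simulated independently (no LD).
* Fatty-acid fractions are generated as a multivariate log-normal:
  latent log-scale values with moment-matched per-FA means/SDs
  (``sigma2_log = ln(1 + CV^2)``, ``mu_log = ln(mean) - sigma2_log/2``)
  and a block correlation structure by lipid class; configured genetic
  effects multiply a target FA by ``factor**m`` for maternal
  reference-allele count ``m``; covariate effects are additive on the
  log scale.  Finally the 26 fractions are renormalised (closure) to
  sum to 100 %wt/wt per mother, as the assay reports them.

Closure slightly attenuates effects on large fractions; for arachidonic
acid (~0.5% of total) the attenuation is negligible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fatty_acids import CLASS_OF, FA_NAMES, default_means, default_sds
from .formats import Variant, hard_to_triples
from .imputation import MonomorphicVariantError, hwe_prior

__all__ = [
    "GeneticEffect",
    "SimConfig",
    "DyadCohort",
    "default_correlation",
    "simulate_dyad_genotypes",
    "simulate_fa_profiles",
    "simulate_study",
    "degrade_to_probabilistic",
]


@dataclass(frozen=True)
class GeneticEffect:
    """A per-allele multiplicative effect of a variant on one fatty acid.

    ``factor`` multiplies the target FA once per maternal reference
    allele; e.g. factor 0.85 on AA at raf 0.17 emulates the lead
    desaturase-locus signal.
    """

    variant_index: int
    fa: str
    factor: float

    def __post_init__(self):
        if self.factor <= 0:
            raise ValueError("multiplicative factor must be > 0")
        if self.fa not in FA_NAMES:
            raise ValueError(f"unknown fatty acid {self.fa!r}")


def default_correlation(
    rho_within: float = 0.5,
    rho_between: dict[tuple[str, str], float] | None = None,
) -> np.ndarray:
    """Block correlation matrix over the 26 FAs by lipid class.

    Within-class correlation ``rho_within`` everywhere; between-class
    correlation from ``rho_between`` (unordered class pairs), default
    -0.3 between SFA and each PUFA class and 0 elsewhere — a
    qualitative stand-in for the empirical correlation structure, which
    shows positive within-class blocks and SFA/PUFA anticorrelation.
    """
    if rho_between is None:
        rho_between = {("SFA", "PUFA6"): -0.3, ("SFA", "PUFA3"): -0.3}
    lookup = {frozenset(k): v for k, v in rho_between.items()}
    k = len(FA_NAMES)
    corr = np.eye(k)
    for i, a in enumerate(FA_NAMES):
        for j, b in enumerate(FA_NAMES):
            if i == j:
                continue
            ca, cb = CLASS_OF[a], CLASS_OF[b]
            corr[i, j] = rho_within if ca == cb else lookup.get(frozenset((ca, cb)), 0.0)
    return corr


@dataclass
class SimConfig:
    """Study conditions for the synthetic generator.

    Defaults emulate the discovery-cohort conditions: 26 FA fractions
    with the published cohort means/SDs, within-class correlation 0.5
    and SFA-PUFA anticorrelation -0.3, and no genetic or covariate
    effects unless configured.
    """

    n_dyads: int = 1142
    variants: Sequence[Variant] = field(default_factory=list)
    seed: int = 0
    fa_means: dict[str, float] = field(default_factory=default_means)
    fa_sds: dict[str, float] = field(default_factory=default_sds)
    rho_within: float = 0.5
    rho_between: dict[tuple[str, str], float] | None = None
    correlation: np.ndarray | None = None  # overrides the block default
    genetic_effects: Sequence[GeneticEffect] = field(default_factory=list)
    #: fa -> {covariate -> additive log-scale coefficient}
    covariate_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    site: int = 0

    def correlation_matrix(self) -> np.ndarray:
        corr = (
            np.asarray(self.correlation, dtype=float)
            if self.correlation is not None
            else default_correlation(self.rho_within, self.rho_between)
        )
        lam = np.linalg.eigvalsh(corr)
        if lam.min() < -1e-8:
            raise ValueError(
                f"FA correlation matrix is not positive semi-definite "
                f"(min eigenvalue {lam.min():.3g})"
            )
        return corr


@dataclass
class DyadCohort:
    """True trio genotypes plus dyad covariates.

    Genotype matrices are ``(n_variants, n_dyads)`` reference-allele
    counts; ``infant_triples`` is set when the infant calls have been
    degraded to probabilistic form (the observation channel the real
    study has), otherwise the hard infant matrix applies.
    """

    variants: list[Variant]
    maternal: np.ndarray
    paternal: np.ndarray
    infant: np.ndarray
    covariates: pd.DataFrame
    infant_triples: np.ndarray | None = None

    @property
    def n_dyads(self) -> int:
        return self.maternal.shape[1] if self.maternal.ndim == 2 else len(self.covariates)

    def observed_infant_triples(self) -> np.ndarray:
        if self.infant_triples is not None:
            return self.infant_triples
        return hard_to_triples(self.infant)


def _simulate_covariates(n: int, rng: np.random.Generator, site: int) -> pd.DataFrame:
    # Young mothers sampled within 6 weeks postpartum: age ~ N(25, 5) clipped
    # to 15-45 y; infant age at milk sample 3-43 d, right-skewed around ~9 d.
    age = np.clip(rng.normal(25.0, 5.0, size=n), 15.0, 45.0)
    infant_age = np.clip(3.0 + rng.gamma(3.0, 2.0, size=n), 3.0, 43.0)
    sex = rng.integers(0, 2, size=n)
    return pd.DataFrame(
        {
            "maternal_age": age,
            "infant_age_days": infant_age,
            "infant_sex": sex,
            "site": np.full(n, site),
        },
        index=[f"S{i + 1}" for i in range(n)],
    )


def simulate_dyad_genotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> DyadCohort:
    """Draw HWE parents and Mendelian infants for every configured variant.

    Mothers and fathers are i.i.d. Binomial(2, p) per variant; the infant
    allele from each parent is transmitted with probability proportional
    to that parent's allele count.  Raises on monomorphic rafs.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = int(config.n_dyads)
    variants = list(config.variants)
    for v in variants:
        if not 0.0 < v.raf < 1.0:
            raise MonomorphicVariantError(
                f"monomorphic variant {v.snp_id}: raf {v.raf}"
            )
    n_var = len(variants)
    p = np.array([v.raf for v in variants])[:, None]
    maternal = rng.binomial(2, np.broadcast_to(p, (n_var, n)))
    paternal = rng.binomial(2, np.broadcast_to(p, (n_var, n)))
    from_mother = rng.binomial(1, maternal / 2.0)
    from_father = rng.binomial(1, paternal / 2.0)
    infant = from_mother + from_father
    cov = _simulate_covariates(n, rng, config.site)
    return DyadCohort(variants, maternal, paternal, infant, cov)


def simulate_fa_profiles(
    cohort: DyadCohort,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Generate the 26-fraction compositional phenotype table for a cohort.

    Latent log-scale values are multivariate normal with the configured
    correlation and moment-matched marginals; genetic effects act on the
    **maternal** genotype (the phenotype is maternal breast milk — the
    infant genotype is only the observation channel); covariate effects
    add on the log scale; closure renormalises to 100.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n = cohort.n_dyads
    means = np.array([config.fa_means[f] for f in FA_NAMES])
    sds = np.array([config.fa_sds[f] for f in FA_NAMES])
    if (means <= 0).any():
        raise ValueError("fraction means must be positive")
    corr = config.correlation_matrix()
    sigma2_log = np.log1p((sds / means) ** 2)
    sigma_log = np.sqrt(sigma2_log)
    mu_log = np.log(means) - sigma2_log / 2.0

    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(FA_NAMES)))
    z = rng.standard_normal((n, len(FA_NAMES))) @ chol.T
    logx = mu_log + sigma_log * z

    fa_index = {f: i for i, f in enumerate(FA_NAMES)}
    for eff in config.genetic_effects:
        if eff.variant_index >= len(cohort.variants):
            raise ValueError(f"no simulated variant at index {eff.variant_index}")
        m = cohort.maternal[eff.variant_index]
        logx[:, fa_index[eff.fa]] += np.log(eff.factor) * m
    for fa, coefs in config.covariate_effects.items():
        for cov_name, beta in coefs.items():
            logx[:, fa_index[fa]] += beta * cohort.covariates[cov_name].to_numpy()

    x = np.exp(logx)
    x *= 100.0 / x.sum(axis=1, keepdims=True)  # closure to %wt/wt
    table = pd.DataFrame(x, columns=list(FA_NAMES), index=cohort.covariates.index)
    return pd.concat([table, cohort.covariates], axis=1)


def degrade_to_probabilistic(
    hard: np.ndarray,
    certainty: float,
    raf: Sequence[float] | float | None = None,
    priors: np.ndarray | None = None,
) -> np.ndarray:
    """Blur hard genotype calls into probability triples.

    The true genotype keeps probability ``certainty``; the remaining
    mass is split between the other two genotype classes proportionally
    to their prior probabilities — the HWE prior at ``raf`` by default,
    or an explicit per-variant ``priors`` array ``(V, 3)``.
    ``certainty=1`` returns degenerate triples; with uniform priors
    ``certainty=1/3`` is fully uninformative.  Emulates imperfect SNP
    imputation of the infant genotypes.
    """
    c = float(certainty)
    if not 1.0 / 3.0 <= c <= 1.0:
        raise ValueError("certainty must lie in [1/3, 1]")
    if (raf is None) == (priors is None):
        raise ValueError("supply exactly one of raf or priors")
    hard = np.asarray(hard)
    single = hard.ndim == 1
    g = hard[None, :] if single else hard
    n_var = g.shape[0]
    if priors is not None:
        prior_rows = np.broadcast_to(np.asarray(priors, dtype=float), (n_var, 3))
    else:
        p = np.broadcast_to(np.asarray(raf, dtype=float), (n_var,))
    out = np.zeros(g.shape + (3,), dtype=float)
    for i in range(n_var):
        prior = prior_rows[i] if priors is not None else hwe_prior(p[i])
        for true_g in (0, 1, 2):
            others = [k for k in (0, 1, 2) if k != true_g]
            w = np.array([prior[k] for k in others])
            w = w / w.sum() if w.sum() > 0 else np.full(2, 0.5)
            triple = np.zeros(3)
            triple[true_g] = c
            triple[others[0]] = (1.0 - c) * w[0]
            triple[others[1]] = (1.0 - c) * w[1]
            out[i, g[i] == true_g] = triple
        out[i, g[i] < 0] = 0.0  # missing stays missing
    return out[0] if single else out


def simulate_study(
    config: SimConfig,
    certainty: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[DyadCohort, pd.DataFrame]:
    """Convenience wrapper: genotypes + phenotypes for one study.

    ``certainty < 1`` additionally degrades the infant hard calls to
    probabilistic triples, stored on the cohort.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    cohort = simulate_dyad_genotypes(config, rng)
    table = simulate_fa_profiles(cohort, config, rng)
    if certainty < 1.0:
        raf = np.array([v.raf for v in cohort.variants])
        cohort.infant_triples = degrade_to_probabilistic(cohort.infant, certainty, raf)
    return cohort, table
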