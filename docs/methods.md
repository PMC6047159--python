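# Methods

This note documents the statistical model behind `milkgwas`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not establish about real data.

## Maternal genotype imputation

At a biallelic variant with reference-allele frequency *p*, both parents
are modelled as independent Hardy–Weinberg draws; the infant receives one
allele from each. Bayes' rule over all nine mother × father genotype
pairs gives the maternal posterior conditional on the infant
reference-allele count (π₀, π₁, π₂ = P of 0/1/2 maternal reference
copies):

| infant count | π₀ | π₁ | π₂ |
|---|---|---|---|
| 0 | 1−p | p | 0 |
| 1 | (1−p)/2 | 1/2 | p/2 |
| 2 | 0 | 1−p | p |

Mendelian-impossible maternal genotypes carry zero mass; mixing the
three rows over the infant's Hardy–Weinberg marginal returns the
maternal prior, and the posterior-mean dosage averages to 2p —
conservation checks enforced by the unit tests against a brute-force
trio-enumeration oracle (to 1e-12).

When the infant genotype is itself uncertain (SNP imputation), the
maternal posterior is the convolution of the two sources: the mixture of
the three closed forms weighted by the infant triple. A missing infant
genotype yields the maternal Hardy–Weinberg prior. The unobserved father
is always a random population member at the same *p* (no assortative
mating); allele frequencies default to the infant-cohort estimate
p̂ = Σμᵢ/(2n) and are overridable per variant. Monomorphic variants
(p̂ ∈ {0,1}) are dropped with a warning rather than imputed.

How much is retained: with hard infant calls, the maternal IMPUTE-style
info score is ≈0.25 at p = 0.17 (one child pins down one maternal
allele), which is the fundamental power cost of the design.

## Association: the uncertainty-aware score test

The phenotype model is linear on the transformed scale,
y = Xα + gβ + ε, ε ~ N(0, σ²), with g the (latent) maternal
reference-allele count. With null-fit residuals r = My (M the residual
projector of X, applied through the thin QR basis, never as an n×n
matrix), ML variance σ̂² = r'r/n, posterior moments μᵢ = π₁+2π₂,
τᵢ = π₁+4π₂, vᵢ = τᵢ−μᵢ²:

    U          = Σ μᵢ rᵢ / σ̂²
    I_complete = ( μ'Mμ + Σ vᵢ (1−hᵢᵢ) ) / σ̂²
    I_missing  = Σ vᵢ E[rᵢ²] / σ̂⁴
    V          = I_complete − I_missing,   S = U²/V ~ χ²₁,   β̂ = U/V

Two evaluations of the missing information are provided:

* **expected** (default): E[rᵢ²] is evaluated at its null expectation
  σ̂²(1−hᵢᵢ); the vᵢ terms cancel exactly and V = μ'Mμ/σ̂², the exact
  conditional variance of the score. The statistic is then exactly the
  classical score test of y on the posterior-mean dosage, so its null
  law is known in finite samples and the test is calibrated at any n.
* **observed**: the realised rᵢ² is plugged in (the Louis/EM
  decomposition). At the low per-sample genotype information of
  single-child maternal imputation, the realised squared residuals
  correlate with the score, and a 200,000-variant null simulation at
  n = 1000 measured type-I error 0.053 at α = 0.05 (CDF deviation up to
  0.006). The variant is kept for sensitivity analysis, not as the
  default.

The two coincide whenever all genotypes are hard (every vᵢ = 0), and in
expectation they carry the same information, so the default sacrifices
no power. Because the maternal posterior is a genuine conditional
expectation (not a noisy measurement), regressing on it does **not**
attenuate the effect: β̂ = U/V is consistent for β, which the
parameter-recovery tests confirm (median exp(β̂) ≈ 0.85, 95% CI coverage
≈ 96% over 200 replicates of the lead-SNP scenario). σ̂² uses the ML
divisor n (score-test convention).

Results with V ≤ 0 (e.g. all-prior triples, or a variant conditioned on
its own dosage) are flagged untestable with p = NaN rather than raised.

## Phenotypes, transforms, multiplicity

The 26 assayed fractions are %wt/wt of total identified fatty acids,
closed to 100 per mother. Seven derived phenotypes are added: the five
class totals (SFA, MUFA, PUFA6, PUFA3, TFA), total PUFA = PUFA6+PUFA3,
and the PUFA6/PUFA3 ratio. All 33 are log transformed except the ratio
(square root, with effects reported back on the ratio scale at the
standardisation point s₀ = 12, near the cohort mean, via the chain rule
2√s₀·β̂). Zero fractions under a log transform are excluded per
phenotype (complete-case within phenotype), preserving sample size for
unaffected phenotypes.

Meff uses the Li–Ji summand Σ[𝟙(λᵢ≥1) + (λᵢ−⌊λᵢ⌋)] over the eigenvalues
of the Pearson correlation matrix of the transformed phenotypes, pooled
across studies (both choices exposed as arguments; eigenvalues are
rounded at 1e-10 so exact integer eigenvalues do not straddle the floor).
A simpler eigenvalue-variance formula (Nyholt) is available as
`method="nyholt"` for sensitivity analysis. The experiment-wise
threshold is α_gw/Meff; at the empirical Meff ≈ 12 of real milk panels,
5×10⁻⁸/12.0 ≈ 4.2×10⁻⁹.

## Meta-analysis, filters, scans

Fixed-effects inverse-variance combination on the transformed scale:
wₖ = SEₖ⁻², β_meta = Σwₖβₖ/Σwₖ, SE_meta = (Σwₖ)^−½, p from the normal
Z. Allele harmonisation is strict-match only — no strand flipping, the
classic silent meta-analysis bug — and mismatches raise.

Per-variant QC follows the two-tier rule: MAF > 0.05 when the variant is
present in two or more studies, MAF > 0.1 when present in only one;
imputation info = 1 (within 1e-6) in every present study, relaxed to
info > 0.9 and MAF > 0.05 in regional mode; exact infant
Hardy–Weinberg p > 10⁻⁵ (the heterozygote-count exact test, validated
against full enumeration for n ≤ 20). Conditional scans append either
the transformed conditioning phenotype or the conditioning variant's
posterior-mean maternal dosage as a covariate column (a covariate cannot
carry a probability triple; the dosage is the posterior mean, which is
sufficient for linear adjustment). Loci merge significant variants
transitively within a 500 kb window (configurable; no LD-based clumping
since the generator simulates variants independently), with counts at
both the experiment-wise and the genome-wide threshold. λ_GC is computed
and logged for diagnostics; no genomic-control correction is applied.

## Synthetic-data generator

The generator inverts the inference model, which is exactly what makes
it a valid oracle for the pipeline and also what it cannot test:

* Parents i.i.d. HWE(p) per variant, infants by uniform allele draws;
  variants independent (no LD), autosomal, one milk specimen per mother.
* Fractions are multivariate log-normal: per-fraction means/SDs default
  to values typical of a South-Asian discovery cohort (e.g. AA
  0.53 ± 0.15 %wt/wt; configurable), moment-matched on the log scale
  (σ²_log = ln(1+CV²), μ_log = ln(mean)−σ²_log/2). The correlation is a
  qualitative block structure — within-class ρ = 0.5, SFA↔PUFA −0.3,
  else 0 — because published milk profiles report the pattern
  (positive within-class blocks, saturated/polyunsaturated
  anticorrelation) but not magnitudes; the matrix is configurable and
  validated PSD before sampling. Consequently the synthetic Meff (~19)
  is larger than the ~12 of real, more strongly intercorrelated panels;
  tests of the Meff machinery use analytic matrices, not the generator.
* Genetic effects multiply the target fraction by factor^(maternal
  count): the phenotype is maternal breast milk, so effects act on the
  mother and the infant genotype is only the observation channel.
  Covariate effects (default none) add on the log scale. Closure then
  renormalises to 100, which slightly attenuates effects on large
  fractions; for AA (~0.5% of total) the attenuation is negligible, and
  the recovery tests on AA bear that out.
* Covariates: maternal age ~ N(25, 5²) years clipped to 15–45, infant
  age at sampling 3–43 days (right-skewed, mode ≈ 7–9 d), infant sex
  Bernoulli(½), constant site indicator per study.
* Infant calls can be degraded to probability triples (true class keeps
  probability c, remainder split by prior) to emulate imperfect SNP
  imputation; info decreases monotonically in c.

Passing tests on this generator establish the mathematics of the
pipeline (posterior correctness, calibration, effect recovery,
meta-analysis identities) — not robustness to LD, population structure,
assay batch effects, non-log-normal tails or longitudinal milk-stage
drift, none of which the generator emulates.

## Numerical choices and problem sizes

* GEN probability triples renormalised on read; raw row sums outside
  [0.98, 1.02] are treated as corrupt. Missing genotype is the all-zero
  triple (standard GEN convention) and is excluded from per-variant
  statistics; maternal imputation maps missing infants to the prior, so
  association never sees missing maternal rows.
* In-memory triples are ordered by reference-allele count; GEN columns
  follow the Oxford order (hom-ref, het, hom-alt) with the reference
  allele as allele A — the reader/writer reverse between the two. The
  orientation fixes every effect sign, so it is asserted by round-trip
  and hard-call tests.
* Exact-fit null models (σ̂² below 1e-14 of the phenotype's mean square)
  are flagged degenerate; score tests with V ≤ 1e-12 are untestable.
* Default test-suite problem sizes: calibration 20,000 null variants at
  n = 1000 (KS and 99% binomial bounds), recovery 200 replicates at
  n = 1142, scan checks on 2-cohort designs of a few hundred dyads;
  chosen to make the Monte-Carlo bounds sharp while the whole suite runs
  in well under a minute per heavy test.

## Known limitations

Single-child dyads only (no siblings or paternal data), autosomes only,
biallelic SNPs only, no mixed-model/kinship or principal-component
adjustment, no between-study heterogeneity statistics, no LD-aware locus
delimitation. The effective information about a mother from one child is
modest (info ≈ 0.25 at p = 0.17), so the design needs the large
per-variant effects that fatty-acid desaturase loci actually show.
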