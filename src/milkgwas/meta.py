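"""Fixed-effects meta-analysis and genome/regional scan orchestration.

Per-study score-test results are combined by inverse-variance weighting
on the transformed phenotype scale (the classical fixed-effects model):
``w_k = SE_k^-2``, ``beta_meta = sum w_k beta_k / sum w_k``,
``SE_meta = (sum w_k)^-1/2``, ``Z = beta_meta / SE_meta``.  Alleles are
matched strictly across studies — no strand flipping — because a silent
flip is the classic meta-analysis failure mode.

:func:`genome_scan` runs the full pipeline per study (allele-frequency
estimation, maternal imputation, phenotype transforms, per-variant QC
filters, score tests) and meta-analyses the per-study summaries;
:func:`regional_conditional_scan` repeats it within a physical region
with a conditioning covariate (a transformed phenotype, or the
posterior-mean maternal dosage of a lead variant) appended to the null
model.  :func:`group_loci` merges significant variants into loci by
physical proximity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    AssocResult,
    fit_null_model,
    hwe_exact_test,
    report_effect,
    score_test_batch,
    variant_filters,
)
from .formats import Variant, triples_to_dosage
from .imputation import estimate_allele_frequency, impute_cohort, info_score
from .phenotypes import (
    PhenotypeSpec,
    default_phenotype_specs,
    derive_summary_fractions,
    transform_phenotypes,
)

__all__ = [
    "Study",
    "MetaRecord",
    "Locus",
    "meta_fixed_effects",
    "genome_scan",
    "regional_conditional_scan",
    "group_loci",
    "lambda_gc",
]

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = ("maternal_age", "infant_age_days", "infant_sex")


@dataclass
class Study:
    """One cohort's inputs to the scan.

    ``infant_triples`` is the observed infant genotype-probability stack
    ``(V, n, 3)``; ``phenotypes`` is the raw fraction table (26 assayed
    columns) with covariate columns, row-aligned with the sample axis of
    the triples.
    """

    name: str
    variants: list[Variant]
    infant_triples: np.ndarray
    phenotypes: pd.DataFrame
    covariate_names: tuple[str, ...] = DEFAULT_COVARIATES

    @classmethod
    def from_simulation(cls, name, cohort, table, covariate_names=DEFAULT_COVARIATES):
        """Build a study from a simulated :class:`~milkgwas.simulate.DyadCohort`."""
        return cls(
            name, list(cohort.variants), cohort.observed_infant_triples(),
            table, covariate_names,
        )

    @property
    def n_samples(self) -> int:
        return self.infant_triples.shape[1]


def _variant_key(v: Variant) -> tuple[str, int]:
    return (str(v.chrom), int(v.pos))


@dataclass
class MetaRecord:
    """Combined association record for one variant-phenotype pair."""

    variant: Variant
    phenotype: str
    per_study: list[AssocResult]
    beta: float
    se: float
    z: float
    p: float
    direction: str
    n: int


def meta_fixed_effects(results: Sequence[AssocResult]) -> MetaRecord:
    """Inverse-variance fixed-effects combination of per-study results.

    A single study passes through unchanged (up to the Z-based p-value).
    Raises when the studies' variants carry mismatched alleles.
    """
    usable = [r for r in results if r.testable]
    if not usable:
        raise ValueError("no testable study result to combine")
    ref = next((r.variant for r in usable if r.variant is not None), None)
    for r in usable:
        if r.variant is not None and ref is not None and not r.variant.same_alleles(ref):
            raise ValueError(
                f"allele mismatch between studies at {ref.chrom}:{ref.pos}: "
                f"{ref.ref_allele}/{ref.alt_allele} vs "
                f"{r.variant.ref_allele}/{r.variant.alt_allele}"
            )
    w = np.array([r.se ** -2 for r in usable])
    b = np.array([r.beta for r in usable])
    beta = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = max(p, np.nextafter(0, 1))
    direction = "".join(r.direction for r in usable)
    n = sum(r.n for r in usable)
    return MetaRecord(ref, usable[0].phenotype, list(usable), beta, se, z, p, direction, n)


# ---------------------------------------------------------------------------
# scan orchestration
# ---------------------------------------------------------------------------

def _per_study_qc(study: Study) -> pd.DataFrame:
    """Per-variant QC statistics for one study: raf, maf, info, HWE p."""
    t = study.infant_triples
    p_hat = np.atleast_1d(estimate_allele_frequency(t))
    info = np.atleast_1d(info_score(t, p_hat))
    hwe = np.empty(len(study.variants))
    best = np.argmax(t, axis=-1)
    observed = t.sum(axis=-1) > 1e-12
    for i in range(len(study.variants)):
        g = best[i][observed[i]]
        counts = [(g == c).sum() for c in (0, 1, 2)]
        hwe[i] = hwe_exact_test(*counts) if sum(counts) else 1.0
    return pd.DataFrame(
        {
            "raf": p_hat,
            "maf": np.minimum(p_hat, 1.0 - p_hat),
            "info": info,
            "hwe_p": hwe,
        }
    )


def _in_region(v: Variant, region: tuple[str, int, int] | None) -> bool:
    if region is None:
        return True
    chrom, start, end = region
    return str(v.chrom) == str(chrom) and start <= v.pos <= end


def genome_scan(
    studies: Sequence[Study],
    phenotype_names: Sequence[str] | None = None,
    specs: dict[str, PhenotypeSpec] | None = None,
    filter_mode: str = "strict",
    region: tuple[str, int, int] | None = None,
    condition_on: tuple[str, str] | None = None,
    hwe_threshold: float = 1e-5,
) -> pd.DataFrame:
    """Run the full maternal GWAS across studies and meta-analyse.

    Per study: estimate allele frequencies from the infant triples,
    impute maternal posteriors, derive and transform the phenotypes,
    apply the cross-study variant filters, and score-test every
    surviving variant against every requested phenotype; then combine
    per-study summaries with :func:`meta_fixed_effects` and rank by
    meta p (ties by position).

    ``condition_on``: ``("phenotype", name)`` appends the transformed
    conditioning phenotype to the covariates; ``("variant", snp_id)``
    appends that variant's posterior-mean maternal dosage.

    Returns a tidy DataFrame, one row per variant-phenotype pair, with
    per-study and combined effects on the transformed scale plus
    reporting-scale effects, ranked by meta p.  An empty post-filter
    variant set returns an empty frame and logs an explicit report.
    """
    specs = specs or default_phenotype_specs()
    phenotype_names = list(phenotype_names or specs.keys())

    # --- cross-study variant harmonisation (strict allele match) ---
    keys: list[tuple[str, int]] = []
    registry: dict[tuple[str, int], Variant] = {}
    study_index: list[dict[tuple[str, int], int]] = []
    for st in studies:
        idx = {}
        for i, v in enumerate(st.variants):
            k = _variant_key(v)
            if k in registry and not registry[k].same_alleles(v):
                raise ValueError(
                    f"allele mismatch between studies at {k[0]}:{k[1]}"
                )
            if k not in registry:
                registry[k] = v
                keys.append(k)
            idx[k] = i
        study_index.append(idx)
    keys = [k for k in keys if _in_region(registry[k], region)]

    # --- per-study QC, imputation, transforms ---
    qc_tables = [_per_study_qc(st) for st in studies]
    maternal = []
    transformed = []
    for st, qc in zip(studies, qc_tables):
        mat, _ = impute_cohort(st.infant_triples, st.variants, raf=qc["raf"].to_numpy())
        maternal.append(mat)
        transformed.append(transform_phenotypes(derive_summary_fractions(st.phenotypes), specs))

    # --- filters ---
    kept: list[tuple[str, int]] = []
    for k in keys:
        mafs, infos, hwes = [], [], []
        for si in range(len(studies)):
            if k in study_index[si]:
                i = study_index[si][k]
                mafs.append(float(qc_tables[si].iloc[i]["maf"]))
                infos.append(float(qc_tables[si].iloc[i]["info"]))
                hwes.append(float(qc_tables[si].iloc[i]["hwe_p"]))
            else:
                mafs.append(None)
                infos.append(None)
                hwes.append(None)
        decision = variant_filters(mafs, infos, hwes, mode=filter_mode,
                                   hwe_threshold=hwe_threshold)
        if decision.keep:
            kept.append(k)
    if not kept:
        logger.warning("no variant passed the %s filters; empty scan result", filter_mode)
        return _empty_scan_frame(studies)

    cond_dosage = None
    if condition_on is not None and condition_on[0] == "variant":
        cond_key = _find_variant(registry, condition_on[1])
        if cond_key not in kept:
            raise ValueError(
                f"conditioning variant {condition_on[1]} fails the active filters"
            )
        cond_dosage = []
        for si in range(len(studies)):
            i = study_index[si].get(cond_key)
            if i is None:
                raise ValueError(
                    f"conditioning variant {condition_on[1]} absent from study "
                    f"{studies[si].name}"
                )
            cond_dosage.append(triples_to_dosage(maternal[si][i]))

    # --- score tests per study, then meta ---
    rows = []
    for pheno in phenotype_names:
        per_study_results: dict[tuple[str, int], list[AssocResult]] = {k: [] for k in kept}
        for si, st in enumerate(studies):
            y_all = transformed[si][pheno]
            cov = st.phenotypes[list(st.covariate_names)].astype(float)
            if condition_on is not None and condition_on[0] == "phenotype":
                cov = cov.copy()
                cov["_cond_" + condition_on[1]] = transformed[si][condition_on[1]]
            if cond_dosage is not None:
                cov = cov.copy()
                cov["_cond_dosage"] = cond_dosage[si]
            complete = y_all.notna() & cov.notna().all(axis=1)
            if complete.sum() <= cov.shape[1] + 1:
                continue
            rows_mask = complete.to_numpy()
            try:
                null = fit_null_model(y_all[complete].to_numpy(), cov[complete])
            except ValueError as exc:
                logger.warning("study %s phenotype %s: %s", st.name, pheno, exc)
                continue
            if null.degenerate:
                logger.warning(
                    "study %s phenotype %s: zero residual variance under "
                    "conditioning; flagged untestable", st.name, pheno,
                )
                continue
            local = [k for k in kept if k in study_index[si]]
            if not local:
                continue
            tri = np.stack(
                [maternal[si][study_index[si][k]][rows_mask] for k in local]
            )
            res = score_test_batch(
                null, tri, [registry[k] for k in local], phenotype=pheno
            )
            for k, r in zip(local, res):
                per_study_results[k].append((si, r))
        for k in kept:
            results = [r for _, r in per_study_results[k] if r.testable]
            if not results:
                continue
            rec = meta_fixed_effects(results)
            by_study = {si: r for si, r in per_study_results[k]}
            rows.append(_record_to_row(rec, studies, by_study, specs[pheno]))

    if not rows:
        logger.warning("no testable variant-phenotype pair; empty scan result")
        return _empty_scan_frame(studies)
    df = pd.DataFrame(rows)
    df = df.sort_values(["p_meta", "chrom", "pos"], kind="mergesort").reset_index(drop=True)
    logger.info("genomic-control lambda = %.3f", lambda_gc(df["p_meta"].to_numpy()))
    return df


def _find_variant(registry: dict, snp_id: str):
    for k, v in registry.items():
        if v.snp_id == snp_id:
            return k
    raise ValueError(f"unknown conditioning variant {snp_id!r}")


def _record_to_row(rec, studies, by_study, spec) -> dict:
    v = rec.variant
    reported = report_effect(rec.beta, rec.se, spec)
    row = {
        "phenotype": rec.phenotype,
        "snp_id": v.snp_id,
        "chrom": v.chrom,
        "pos": v.pos,
        "ref_allele": v.ref_allele,
        "alt_allele": v.alt_allele,
        "n": rec.n,
        "beta_meta": rec.beta,
        "se_meta": rec.se,
        "z_meta": rec.z,
        "p_meta": rec.p,
        "direction": rec.direction,
        "beta_reported": reported.value,
        "se_reported": reported.se,
    }
    for si, st in enumerate(studies):
        r = by_study.get(si)
        ok = r is not None and r.testable
        row[f"beta_{st.name}"] = r.beta if ok else math.nan
        row[f"se_{st.name}"] = r.se if ok else math.nan
        row[f"p_{st.name}"] = r.p if ok else math.nan
    return row


def _empty_scan_frame(studies) -> pd.DataFrame:
    cols = [
        "phenotype", "snp_id", "chrom", "pos", "ref_allele", "alt_allele", "n",
        "beta_meta", "se_meta", "z_meta", "p_meta", "direction",
        "beta_reported", "se_reported",
    ]
    for st in studies:
        cols += [f"beta_{st.name}", f"se_{st.name}", f"p_{st.name}"]
    return pd.DataFrame(columns=cols)


def regional_conditional_scan(
    studies: Sequence[Study],
    region: tuple[str, int, int],
    condition_on: tuple[str, str] | None,
    phenotype_names: Sequence[str] | None = None,
    specs: dict[str, PhenotypeSpec] | None = None,
    filter_mode: str = "regional",
    hwe_threshold: float = 1e-5,
) -> pd.DataFrame:
    """Scan one physical region, optionally conditioning on a phenotype or variant.

    Identical to :func:`genome_scan` restricted to ``region`` (1-based,
    closed bounds) with relaxed regional filters by default; the result
    frame is annotated with the conditioning used.
    """
    df = genome_scan(
        studies,
        phenotype_names=phenotype_names,
        specs=specs,
        filter_mode=filter_mode,
        region=region,
        condition_on=condition_on,
        hwe_threshold=hwe_threshold,
    )
    df = df.copy()
    df["conditioned_on"] = (
        "none" if condition_on is None else f"{condition_on[0]}:{condition_on[1]}"
    )
    return df


# ---------------------------------------------------------------------------
# locus grouping and diagnostics
# ---------------------------------------------------------------------------

@dataclass
class Locus:
    """A cluster of significant variants merged by physical proximity."""

    chrom: str
    start: int
    end: int
    phenotype: str
    members: list[str]
    lead_snp: str
    lead_p: float
    n_primary: int
    n_secondary: int


def group_loci(
    results: pd.DataFrame,
    threshold: float,
    merge_window: int = 500_000,
    secondary_threshold: float = 5e-8,
) -> list[Locus]:
    """Merge significant variants into loci per phenotype and chromosome.

    Variants with meta p below ``threshold`` that lie within
    ``merge_window`` bp of another member are merged transitively; the
    lead variant is the smallest p.  ``n_primary``/``n_secondary`` count
    members below ``threshold`` and below ``secondary_threshold``
    within the locus span.
    """
    sig = results[results["p_meta"] < threshold]
    loci: list[Locus] = []
    for (pheno, chrom), grp in sig.groupby(["phenotype", "chrom"], sort=False):
        grp = grp.sort_values("pos")
        cluster: list[pd.Series] = []
        for _, row in grp.iterrows():
            if cluster and row["pos"] - cluster[-1]["pos"] > merge_window:
                loci.append(_make_locus(cluster, results, pheno, chrom,
                                        threshold, secondary_threshold, merge_window))
                cluster = []
            cluster.append(row)
        if cluster:
            loci.append(_make_locus(cluster, results, pheno, chrom,
                                    threshold, secondary_threshold, merge_window))
    loci.sort(key=lambda l: l.lead_p)
    return loci


def _make_locus(cluster, results, pheno, chrom, threshold, secondary, window) -> Locus:
    pos = [int(r["pos"]) for r in cluster]
    lead = min(cluster, key=lambda r: r["p_meta"])
    span = (min(pos), max(pos))
    within = results[
        (results["phenotype"] == pheno)
        & (results["chrom"] == chrom)
        & (results["pos"] >= span[0] - window)
        & (results["pos"] <= span[1] + window)
    ]
    return Locus(
        chrom=str(chrom),
        start=span[0],
        end=span[1],
        phenotype=pheno,
        members=[str(r["snp_id"]) for r in cluster],
        lead_snp=str(lead["snp_id"]),
        lead_p=float(lead["p_meta"]),
        n_primary=int((within["p_meta"] < threshold).sum()),
        n_secondary=int((within["p_meta"] < secondary).sum()),
    )


def lambda_gc(p_values: np.ndarray) -> float:
    """Genomic-control inflation factor from a vector of p-values.

    Median of the implied 1-df chi-square statistics divided by the
    theoretical null median (~0.4549).  Computed for diagnostics only;
    no correction is applied.
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        return float("nan")
    chi = stats.chi2.isf(p, df=1)
    return float(np.median(chi) / stats.chi2.ppf(0.5, df=1))
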