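"""Compositional phenotype preparation and multiplicity correction.

Breast-milk fatty-acid (FA) fractions are compositional: the 26 assayed
fractions are %wt/wt of total identified FA and sum to 100 per mother.
Seven derived summary phenotypes (per-class totals, total PUFA and the
omega-6/omega-3 ratio) bring the phenotype panel to 33.  All phenotypes
are log transformed to stabilise variance except the PUFA6/PUFA3 ratio,
which is square-root transformed.

Because the 33 phenotypes are strongly intercorrelated, a Bonferroni
correction over 33 tests would be conservative; instead the effective
number of independent tests Meff is computed from the eigenvalues of the
phenotype correlation matrix (Li-Ji method) and divides the genome-wide
alpha to give the experiment-wise threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fatty_acids import DERIVED_NAMES, FA_NAMES, MEMBERS_OF

__all__ = [
    "PhenotypeSpec",
    "MeffResult",
    "default_phenotype_specs",
    "derive_summary_fractions",
    "transform_phenotypes",
    "inverse_transform",
    "phenotype_correlation",
    "effective_tests",
    "experiment_wise_threshold",
    "log_variance_explained",
]

logger = logging.getLogger(__name__)

RATIO_NAME = "PUFA6/PUFA3"


@dataclass(frozen=True)
class PhenotypeSpec:
    """How one phenotype enters the association model.

    transform: "log" (natural log of the %wt/wt fraction), "sqrt-ratio"
    (square root, for the PUFA6/PUFA3 ratio) or "none".  ``s0`` is the
    standardisation point at which sqrt-scale effects are reported back
    on the ratio scale (default ratio of 12, near the cohort mean).
    """

    name: str
    fa_class: str
    transform: str = "log"
    s0: float = 12.0

    def __post_init__(self):
        if self.transform not in ("log", "sqrt-ratio", "none"):
            raise ValueError(f"unknown transform {self.transform!r}")


def default_phenotype_specs() -> dict[str, PhenotypeSpec]:
    """The 33 analysis phenotypes: 26 assayed + 7 derived.

    Everything is log transformed except the PUFA6/PUFA3 ratio.
    """
    from .fatty_acids import CLASS_OF

    specs: dict[str, PhenotypeSpec] = {}
    for name in FA_NAMES:
        specs[name] = PhenotypeSpec(name, CLASS_OF[name], "log")
    for name in DERIVED_NAMES:
        tf = "sqrt-ratio" if name == RATIO_NAME else "log"
        specs[name] = PhenotypeSpec(name, "derived", tf)
    assert len(specs) == 33
    return specs


def derive_summary_fractions(table: pd.DataFrame) -> pd.DataFrame:
    """Add the seven derived summary phenotypes to a fraction table.

    SFA/MUFA/PUFA6/PUFA3/TFA are simple sums of their member fractions,
    PUFA = PUFA6 + PUFA3, and PUFA6/PUFA3 is their ratio.  Rows with
    PUFA3 = 0 get a NaN ratio (flagged for exclusion from ratio
    analyses).  Idempotent: existing derived columns are recomputed.
    """
    missing = [c for c in FA_NAMES if c not in table.columns]
    if missing:
        raise ValueError(f"fraction table lacks assayed columns {missing}")
    out = table.copy()
    for cls, members in MEMBERS_OF.items():
        out[cls] = out[list(members)].sum(axis=1)
    out["PUFA"] = out["PUFA6"] + out["PUFA3"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["PUFA6"] / out["PUFA3"]
    undefined = out["PUFA3"] <= 0
    if undefined.any():
        logger.warning(
            "%d mother(s) with PUFA3 = 0: PUFA6/PUFA3 ratio undefined", undefined.sum()
        )
    out[RATIO_NAME] = ratio.where(~undefined)
    return out


def transform_phenotypes(
    table: pd.DataFrame, specs: dict[str, PhenotypeSpec] | None = None
) -> pd.DataFrame:
    """Apply per-phenotype variance-stabilising transforms.

    Returns a table of transformed phenotype columns only.  Zero or
    negative values under a log (or sqrt) transform are excluded for
    that phenotype (set NaN) with a logged count — complete-case within
    phenotype, so unaffected phenotypes keep their full sample.
    """
    specs = specs or default_phenotype_specs()
    out = pd.DataFrame(index=table.index)
    for name, spec in specs.items():
        if name not in table.columns:
            raise ValueError(f"phenotype {name!r} absent from table")
        x = table[name].astype(float)
        if spec.transform == "log":
            bad = x <= 0
            if bad.any():
                logger.info("%s: %d zero/negative value(s) excluded from log", name, bad.sum())
            out[name] = np.log(x.where(~bad))
        elif spec.transform == "sqrt-ratio":
            bad = x < 0
            out[name] = np.sqrt(x.where(~bad))
        else:
            out[name] = x
    return out


def inverse_transform(value: float, spec: PhenotypeSpec) -> float:
    """Map a transformed phenotype value back to the raw fraction scale."""
    if spec.transform == "log":
        return math.exp(value)
    if spec.transform == "sqrt-ratio":
        return value * value
    return value


def phenotype_correlation(transformed: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of transformed phenotypes.

    Uses pairwise-complete observations; requires at least 3 complete
    rows per pair and a non-constant column (raises naming the column).
    """
    if len(transformed) < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    sds = transformed.std(ddof=0)
    constant = sds[sds == 0].index.tolist()
    if constant:
        raise ValueError(f"constant phenotype column(s): {constant}")
    corr = transformed.corr(method="pearson", min_periods=3)
    return corr


@dataclass
class MeffResult:
    """Effective number of independent tests and the resulting threshold."""

    eigenvalues: np.ndarray
    meff: float
    alpha_genomewide: float = 5e-8
    method: str = "li_ji"

    @property
    def alpha_experiment_wise(self) -> float:
        return self.alpha_genomewide / self.meff


def effective_tests(
    corr: pd.DataFrame | np.ndarray,
    alpha_genomewide: float = 5e-8,
    method: str = "li_ji",
) -> MeffResult:
    """Effective number of independent tests from correlation eigenvalues.

    Li-Ji (default): ``Meff = sum_i [ I(lam_i >= 1) + (lam_i - floor(lam_i)) ]``
    over the eigenvalues of the correlation matrix, which equals K for the
    identity and 1 for a rank-one (perfectly correlated) matrix.  Tiny
    negative eigenvalues from near-singular matrices are clamped to 0.

    ``method="nyholt"`` gives the older variance-of-eigenvalues formula
    ``Meff = 1 + (K-1) (1 - var(lam)/K)`` for sensitivity analysis.
    """
    c = np.asarray(corr, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("correlation matrix must be square")
    if not np.allclose(c, c.T, atol=1e-8):
        raise ValueError("correlation matrix must be symmetric")
    lam = np.linalg.eigvalsh(c)
    # round off eigen-solver noise so the floor term in the Li-Ji summand
    # does not jump at integer eigenvalues (e.g. rank-1 gives K - 1e-15)
    lam = np.clip(np.round(lam, 10), 0.0, None)
    k = c.shape[0]
    if method == "li_ji":
        meff = float(np.sum((lam >= 1.0).astype(float) + (lam - np.floor(lam))))
    elif method == "nyholt":
        meff = float(1.0 + (k - 1) * (1.0 - np.var(lam) / k))
    else:
        raise ValueError(f"unknown method {method!r}")
    meff = min(max(meff, 1.0), float(k))
    return MeffResult(lam[::-1], meff, alpha_genomewide, method)


def experiment_wise_threshold(alpha_genomewide: float, meff: float) -> float:
    """Bonferroni-style experiment-wise alpha: genome-wide alpha / Meff."""
    if not 0.0 < alpha_genomewide < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if meff < 1.0:
        raise ValueError("Meff must be >= 1")
    return alpha_genomewide / meff


def log_variance_explained(
    mean: float, sd: float, raf: float, factor: float
) -> float:
    """Fraction of log-phenotype variance explained by a multiplicative SNP effect.

    Moment-matches a log-normal to the observed raw-scale mean/SD
    (``sigma2_log = ln(1 + CV^2)``), takes the additive log-scale effect
    ``beta = ln(factor)`` per reference allele with HWE genotype variance
    ``2 p (1-p)``, and returns ``beta^2 * 2p(1-p) / sigma2_log``.
    """
    if mean <= 0 or sd < 0:
        raise ValueError("mean must be positive and sd non-negative")
    if not 0.0 < raf < 1.0:
        raise ValueError("raf must be in (0, 1)")
    if factor <= 0:
        raise ValueError("multiplicative factor must be positive")
    sigma2_log = math.log1p((sd / mean) ** 2)
    beta = math.log(factor)
    return beta * beta * 2.0 * raf * (1.0 - raf) / sigma2_log
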