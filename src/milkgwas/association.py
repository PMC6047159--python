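"""Uncertainty-aware score test of phenotypes on maternal genotype posteriors.

The association model is an ordinary linear regression of a transformed
phenotype on the maternal reference-allele count plus covariates, but
the maternal genotype is only known as a posterior probability triple.
Rather than collapsing the triple to an expected dosage, the test is a
missing-data score test: the score and Fisher information are averaged
over the genotype posterior and the information lost to genotype
uncertainty is subtracted (observed information = complete-data
information - missing information).  With hard genotypes it reduces
exactly to the classical score test of the regression slope.

Notation: for sample ``i`` with posterior ``(pi0, pi1, pi2)``,

    mu_i  = pi1 + 2 pi2          expected allele count
    tau_i = pi1 + 4 pi2          expected squared count
    v_i   = tau_i - mu_i^2       per-sample genotype variance

and with null-model residuals ``r_i``, ML variance ``sigma2 = r'r / n``,
leverages ``h_ii`` and residual projector ``M = I - H``:

    U          = sum_i mu_i r_i / sigma2
    I_complete = ( mu' M mu + sum_i v_i (1 - h_ii) ) / sigma2
    I_missing  = sum_i v_i E[r_i^2] / sigma2^2
    V          = I_complete - I_missing

The statistic ``S = U^2 / V`` is chi-square(1) under the null; the
one-step effect estimate is ``beta = U / V`` with ``SE = V**-0.5``
(equal to the OLS slope when genotypes are hard).

Two information variants are offered.  The default (``"expected"``)
evaluates the missing information at its null expectation
``E[r_i^2] = sigma2 (1 - h_ii)``, under which the ``v_i`` terms cancel
and ``V = mu' M mu / sigma2`` — the exact conditional variance of the
score, so the test is exactly calibrated at any sample size.  The
``"observed"`` (Louis) variant plugs the realised ``r_i^2`` into the
missing information; it is the textbook EM decomposition but, at the
modest per-sample genotype information a single child provides about
its mother, the realised squared residuals couple to the score and
make the statistic measurably anticonservative in finite samples, so
it is kept for sensitivity analysis rather than as the default.  The
two coincide whenever all genotypes are hard (every ``v_i = 0``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .formats import Variant
from .phenotypes import PhenotypeSpec

__all__ = [
    "NullFit",
    "AssocResult",
    "fit_null_model",
    "score_test",
    "score_test_batch",
    "hwe_exact_test",
    "variant_filters",
    "report_effect",
    "ReportedEffect",
]


@dataclass
class NullFit:
    """Least-squares fit of the phenotype on covariates only.

    ``sigma2`` uses the maximum-likelihood divisor ``n`` (score-test
    convention).  ``q`` is the thin orthonormal basis of the column
    space of X, from which leverages and residual projections derive
    without materialising the n-by-n hat matrix.
    """

    X: np.ndarray
    coef: np.ndarray
    residuals: np.ndarray
    sigma2: float
    leverages: np.ndarray
    q: np.ndarray
    column_names: list[str]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def degenerate(self) -> bool:
        """True when the covariates fit the phenotype exactly."""
        return self.sigma2 <= 0.0


def fit_null_model(
    y: np.ndarray | pd.Series,
    X: np.ndarray | pd.DataFrame | None = None,
    add_intercept: bool = True,
) -> NullFit:
    """Fit the covariate-only null model by least squares.

    Parameters
    ----------
    y : phenotype vector (transformed scale), no NaN.
    X : covariate matrix or DataFrame; an intercept column is prepended
        unless ``add_intercept=False``.

    Raises on rank-deficient design, naming the collinear columns.
    """
    y = np.asarray(y, dtype=float).ravel()
    if np.isnan(y).any():
        raise ValueError("phenotype vector contains NaN; drop incomplete rows first")
    names: list[str] = []
    if X is None:
        mat = np.empty((y.size, 0))
    elif isinstance(X, pd.DataFrame):
        names = [str(c) for c in X.columns]
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        if mat.ndim == 1:
            mat = mat[:, None]
        names = [f"x{i}" for i in range(mat.shape[1])]
    if add_intercept:
        mat = np.column_stack([np.ones(y.size), mat])
        names = ["intercept"] + names
    if mat.shape[0] <= mat.shape[1]:
        raise ValueError(
            f"need n > {mat.shape[1]} covariate columns, got n = {mat.shape[0]}"
        )
    q, r = np.linalg.qr(mat)
    diag = np.abs(np.diag(r))
    scale = diag.max() if diag.size else 1.0
    bad = [names[j] for j in range(len(names)) if diag[j] < 1e-10 * max(scale, 1.0)]
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")
    coef = np.linalg.solve(r, q.T @ y)
    fitted = mat @ coef
    resid = y - fitted
    sigma2 = float(resid @ resid) / y.size
    # an exact fit leaves only rounding noise; flag it as degenerate
    if sigma2 < 1e-14 * max(float(y @ y) / y.size, 1e-300):
        sigma2 = 0.0
    leverages = np.einsum("ij,ij->i", q, q)
    return NullFit(mat, coef, resid, sigma2, leverages, q, names)


@dataclass
class AssocResult:
    """Score-test result for one variant-phenotype pair.

    ``beta`` and ``se`` are on the transformed phenotype scale; use
    :func:`report_effect` to express them on the reporting scale.
    ``testable`` is False when the genotype information V is not
    positive (extreme uncertainty) — then p is NaN.
    """

    variant: Variant | None
    phenotype: str
    n: int
    score: float
    information: float
    beta: float
    se: float
    statistic: float
    p: float
    direction: str
    testable: bool = True


def _score_components(
    null: NullFit, mu: np.ndarray, v: np.ndarray, information: str = "expected"
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised (U, V) for rows of mu/v with shape (..., n)."""
    if information not in ("expected", "observed"):
        raise ValueError(f"unknown information variant {information!r}")
    s2 = null.sigma2
    r = null.residuals
    u = (mu @ r) / s2
    proj = mu @ null.q  # (..., k)
    mu_m_mu = np.einsum("...i,...i->...", mu, mu) - np.einsum(
        "...k,...k->...", proj, proj
    )
    i_complete = (mu_m_mu + v @ (1.0 - null.leverages)) / s2
    if information == "observed":
        i_missing = (v @ (r * r)) / (s2 * s2)
    else:
        # E[r_i^2] = sigma2 (1 - h_ii) under the null: the v-terms cancel
        # and V reduces to the exact conditional score variance.
        i_missing = (v @ (1.0 - null.leverages)) / s2
    return u, i_complete - i_missing


def score_test(
    null: NullFit,
    triples: np.ndarray,
    variant: Variant | None = None,
    phenotype: str = "",
    information: str = "expected",
) -> AssocResult:
    """Missing-data score test of one variant against a fitted null model.

    ``triples`` is the ``(n, 3)`` maternal posterior matrix aligned with
    the null-fit rows (no missing rows — impute missing infants to the
    HWE prior upstream).  ``information`` selects the missing-information
    evaluation, ``"expected"`` (default, exactly calibrated) or
    ``"observed"`` (Louis decomposition); see the module docstring.
    """
    if null.degenerate:
        raise ValueError("null model has zero residual variance; phenotype degenerate")
    t = np.asarray(triples, dtype=float)
    if t.shape != (null.n, 3):
        raise ValueError(f"triples shape {t.shape} does not match n = {null.n}")
    mu = t[:, 1] + 2.0 * t[:, 2]
    tau = t[:, 1] + 4.0 * t[:, 2]
    v = tau - mu * mu
    u, info = _score_components(null, mu, v, information)
    return _package_result(float(u), float(info), null.n, variant, phenotype)


def _package_result(
    u: float, info: float, n: int, variant: Variant | None, phenotype: str
) -> AssocResult:
    if not info > 1e-12:
        return AssocResult(
            variant, phenotype, n, u, info, math.nan, math.nan, math.nan,
            math.nan, "?", testable=False,
        )
    s = u * u / info
    p = float(stats.chi2.sf(s, df=1))
    p = max(p, np.nextafter(0, 1))  # keep p in (0, 1]
    beta = u / info
    return AssocResult(
        variant, phenotype, n, u, info, beta, info ** -0.5, s, p,
        "+" if beta >= 0 else "-",
    )


def score_test_batch(
    null: NullFit,
    triples: np.ndarray,
    variants: list[Variant] | None = None,
    phenotype: str = "",
    information: str = "expected",
) -> list[AssocResult]:
    """Vectorised score tests for a ``(V, n, 3)`` stack of posterior matrices."""
    if null.degenerate:
        raise ValueError("null model has zero residual variance; phenotype degenerate")
    t = np.asarray(triples, dtype=float)
    mu = t[..., 1] + 2.0 * t[..., 2]
    tau = t[..., 1] + 4.0 * t[..., 2]
    v = tau - mu * mu
    u, info = _score_components(null, mu, v, information)
    out = []
    for i in range(t.shape[0]):
        var = variants[i] if variants is not None else None
        out.append(_package_result(float(u[i]), float(info[i]), null.n, var, phenotype))
    return out


# ---------------------------------------------------------------------------
# variant-level QC
# ---------------------------------------------------------------------------

def hwe_exact_test(n0: int, n1: int, n2: int) -> float:
    """Exact Hardy-Weinberg test on genotype counts (0/1/2 reference copies).

    Conditional on the observed allele counts, the heterozygote count
    follows a known distribution under HWE; the p-value sums the
    probabilities of all heterozygote counts no more probable than the
    observed one (the standard exact formulation).
    """
    n0, n1, n2 = int(n0), int(n1), int(n2)
    if min(n0, n1, n2) < 0 or n0 + n1 + n2 == 0:
        raise ValueError("genotype counts must be non-negative with n > 0")
    n = n0 + n1 + n2
    n_rare = min(2 * n0 + n1, 2 * n2 + n1)
    # P(het = h | n, n_rare) via the standard recurrence; h has the parity
    # of n_rare and ranges 0..n_rare.
    hs = list(range(n_rare % 2, n_rare + 1, 2))
    probs = {}
    h_mid = hs[len(hs) // 2]
    probs[h_mid] = 1.0
    # upward recurrence: P(h+2)/P(h) = 4*hom_r*hom_c / ((h+2)*(h+1))
    idx = hs.index(h_mid)
    for h in hs[idx:-1]:
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h + 2] = probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
    # downward recurrence: P(h-2)/P(h) = h*(h-1) / (4*(hom_r+1)*(hom_c+1))
    for h in reversed(hs[1 : idx + 1]):
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[h - 2] = probs[h] * h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
    total = sum(probs.values())
    obs = n1
    if obs not in probs:
        raise ValueError(
            f"heterozygote count {obs} inconsistent with allele counts (parity)"
        )
    p_obs = probs[obs]
    p = sum(pr for pr in probs.values() if pr <= p_obs * (1.0 + 1e-12)) / total
    return min(p, 1.0)


@dataclass(frozen=True)
class FilterDecision:
    keep: bool
    reason: str


def variant_filters(
    maf: "tuple[float | None, ...] | list[float | None]",
    info: "tuple[float | None, ...] | list[float | None]",
    hwe_p: "tuple[float | None, ...] | list[float | None]",
    mode: str = "strict",
    hwe_threshold: float = 1e-5,
) -> FilterDecision:
    """Apply the per-variant inclusion rule across studies.

    Per-study values are None where the variant is absent from that
    study.  The strict (genome-scan) rule requires info = 1 in every
    study where the variant is present, MAF > 0.05 when present in two
    or more studies or MAF > 0.1 when present in only one, and an exact
    infant HWE p > 1e-5 in every present study.  The relaxed regional
    mode requires info > 0.9 and MAF > 0.05.
    """
    present = [i for i, m in enumerate(maf) if m is not None]
    if not present:
        return FilterDecision(False, "absent from all studies")
    mafs = [maf[i] for i in present]
    infos = [info[i] for i in present if info[i] is not None]
    hwes = [hwe_p[i] for i in present if hwe_p[i] is not None]
    if mode == "strict":
        if any(i < 1.0 - 1e-6 for i in infos):
            return FilterDecision(False, "info < 1 in a present study")
        maf_cut = 0.05 if len(present) >= 2 else 0.1
        if any(m <= maf_cut for m in mafs):
            return FilterDecision(False, f"MAF <= {maf_cut} (present in {len(present)} study/ies)")
    elif mode == "regional":
        if any(i <= 0.9 for i in infos):
            return FilterDecision(False, "info <= 0.9 in a present study")
        if any(m <= 0.05 for m in mafs):
            return FilterDecision(False, "MAF <= 0.05")
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    if any(h <= hwe_threshold for h in hwes):
        return FilterDecision(False, f"infant HWE p <= {hwe_threshold}")
    return FilterDecision(True, "pass")


# ---------------------------------------------------------------------------
# effect reporting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReportedEffect:
    """Effect on the reporting scale of the phenotype's transform.

    For log phenotypes, ``value``/``se`` are the exponentiated effect
    and SE: the multiplicative change in the FA fraction per reference
    allele.  For the sqrt-transformed ratio, ``value`` is the change in
    the ratio per allele at the standardisation point s0 (chain rule:
    ``2 sqrt(s0) * beta``).  When the multiplicative effect is below 1,
    ``percent_per_major_allele`` gives the equivalent percent increase
    per copy of the other (major) allele, ``(1/value - 1) * 100``.
    """

    value: float
    se: float
    percent_per_major_allele: float | None


def report_effect(beta: float, se: float, spec: PhenotypeSpec) -> ReportedEffect:
    """Express a transformed-scale effect estimate on the reporting scale."""
    if spec.transform == "log":
        # exp saturates to inf instead of raising on extreme SEs from
        # near-untestable results
        with np.errstate(over="ignore"):
            value = float(np.exp(beta))
            se_rep = float(np.exp(se))
        pct = (1.0 / value - 1.0) * 100.0 if 0.0 < value < 1.0 else None
        return ReportedEffect(value, se_rep, pct)
    if spec.transform == "sqrt-ratio":
        scale = 2.0 * math.sqrt(spec.s0)
        return ReportedEffect(scale * beta, scale * se, None)
    return ReportedEffect(beta, se, None)
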