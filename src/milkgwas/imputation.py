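"""Posterior imputation of maternal genotypes from infant genotypes.

In a mother-infant dyad study where only the infant is genotyped, the
maternal genotype at a biallelic variant is a latent variable.  The
infant received exactly one allele from its mother; under random mating
the other parental allele is an independent draw from the population, and
both parents' genotypes follow Hardy-Weinberg equilibrium (HWE) at the
cohort reference-allele frequency ``p``.  Bayes' rule then gives a closed
form for the posterior distribution of the maternal reference-allele
count ``M`` given the infant count ``C`` (triples ordered ``(pi0, pi1,
pi2)`` = P(M = 0, 1, 2)):

    C = 2  ->  (0,        1 - p,  p)
    C = 1  ->  ((1-p)/2,  1/2,    p/2)
    C = 0  ->  (1 - p,    p,      0)

When the infant genotype is itself uncertain (a probability triple from
SNP imputation), the maternal posterior is the mixture of the three
closed forms weighted by the infant triple — the convolution of the two
sources of uncertainty.  A missing infant genotype carries no information
and yields the HWE prior ``((1-p)^2, 2p(1-p), p^2)``.

The module also provides the cohort-level helpers used to filter and
annotate variants: posterior-mean allele-frequency estimation and the
IMPUTE-style information score.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .formats import Variant, hard_to_triples, missing_mask, triples_to_dosage

__all__ = [
    "MonomorphicVariantError",
    "hwe_prior",
    "maternal_posterior_given_child",
    "maternal_posterior_from_probabilistic",
    "impute_cohort",
    "estimate_allele_frequency",
    "info_score",
]

logger = logging.getLogger(__name__)


class MonomorphicVariantError(ValueError):
    """Raised when p is 0 or 1: the maternal posterior is degenerate."""


def _check_p(p: float) -> float:
    p = float(p)
    if not 0.0 < p < 1.0:
        raise MonomorphicVariantError(
            f"monomorphic variant: reference-allele frequency {p} not in (0, 1)"
        )
    return p


def hwe_prior(p: float) -> np.ndarray:
    """HWE genotype distribution ((1-p)^2, 2p(1-p), p^2) over 0/1/2 copies."""
    p = _check_p(p)
    q = 1.0 - p
    return np.array([q * q, 2.0 * p * q, p * p])


def _posterior_table(p: float) -> np.ndarray:
    """3x3 table: row c = maternal posterior triple given infant count c."""
    p = _check_p(p)
    q = 1.0 - p
    return np.array(
        [
            [q, p, 0.0],            # c = 0
            [q / 2, 0.5, p / 2],    # c = 1
            [0.0, q, p],            # c = 2
        ]
    )


def maternal_posterior_given_child(c: int, p: float) -> np.ndarray:
    """Maternal genotype posterior (pi0, pi1, pi2) given a hard infant call.

    Parameters
    ----------
    c : infant reference-allele count, 0, 1 or 2.
    p : cohort reference-allele frequency in (0, 1).
    """
    if c not in (0, 1, 2):
        raise ValueError(f"infant reference-allele count must be 0, 1 or 2, got {c}")
    return _posterior_table(p)[c]


def maternal_posterior_from_probabilistic(
    child: Sequence[float] | np.ndarray, p: float
) -> np.ndarray:
    """Maternal posterior given an uncertain infant genotype triple.

    Mixes the three hard-call posteriors with the infant's genotype
    probabilities: ``sum_c child[c] * P(M | C = c)``.  The all-zero
    missing triple returns the HWE prior.
    """
    child = np.asarray(child, dtype=float)
    if child.shape != (3,):
        raise ValueError("child triple must have shape (3,)")
    s = child.sum()
    if s < 1e-12:
        return hwe_prior(p)
    return (child / s) @ _posterior_table(p)


def estimate_allele_frequency(triples: np.ndarray) -> float | np.ndarray:
    """Reference-allele frequency from posterior-mean dosages.

    ``p_hat = sum_i mu_i / (2 n)`` over non-missing samples, where
    ``mu_i`` is the triple's expected reference-allele count.  Accepts a
    single-variant ``(n, 3)`` matrix or a ``(V, n, 3)`` stack (returns a
    vector).  Raises if every sample is missing.
    """
    t = np.asarray(triples, dtype=float)
    single = t.ndim == 2
    if single:
        t = t[None]
    miss = missing_mask(t)
    n_obs = (~miss).sum(axis=1)
    if (n_obs == 0).any():
        raise ValueError("all genotypes missing; allele frequency undefined")
    mu = triples_to_dosage(t)
    p_hat = np.where(miss, 0.0, mu).sum(axis=1) / (2.0 * n_obs)
    return float(p_hat[0]) if single else p_hat


def info_score(triples: np.ndarray, p_hat: float | np.ndarray | None = None):
    """IMPUTE-style information score of a genotype-probability matrix.

    With per-sample expected dosage ``mu_i = pi1 + 2 pi2`` and second
    moment ``tau_i = pi1 + 4 pi2``, the per-sample dosage variance is
    ``v_i = tau_i - mu_i**2`` and

        info = 1 - sum_i v_i / (2 n p(1-p))

    evaluated at the estimated frequency (or ``p_hat`` if given), over
    non-missing samples.  Hard calls give info = 1; a matrix of HWE
    priors gives info = 0.  Defined as 1 when ``p_hat`` is 0 or 1.
    Accepts ``(n, 3)`` or ``(V, n, 3)`` input.
    """
    t = np.asarray(triples, dtype=float)
    single = t.ndim == 2
    if single:
        t = t[None]
    miss = missing_mask(t)
    n_obs = (~miss).sum(axis=1)
    if (n_obs == 0).any():
        raise ValueError("all genotypes missing; info score undefined")
    mu = triples_to_dosage(t)
    tau = t[..., 1] + 4.0 * t[..., 2]
    v = np.where(miss, 0.0, tau - mu * mu)
    if p_hat is None:
        p_hat = np.where(miss, 0.0, mu).sum(axis=1) / (2.0 * n_obs)
    else:
        p_hat = np.broadcast_to(np.asarray(p_hat, dtype=float), (t.shape[0],))
    denom = 2.0 * n_obs * p_hat * (1.0 - p_hat)
    with np.errstate(divide="ignore", invalid="ignore"):
        info = 1.0 - v.sum(axis=1) / denom
    info = np.where(denom <= 0, 1.0, info)
    info = np.clip(info, 0.0, 1.0)
    return float(info[0]) if single else info


def impute_cohort(
    infant: np.ndarray,
    variants: Sequence[Variant] | None = None,
    raf: Sequence[float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Impute maternal posterior triples for a whole cohort.

    Parameters
    ----------
    infant : infant genotypes, either hard calls ``(V, n)`` (ints 0/1/2,
        -1 missing) or probability triples ``(V, n, 3)``.
    variants : optional variant metadata; used for warnings and, when a
        variant carries a finite ``raf``, as the frequency source.
    raf : optional per-variant reference-allele frequencies overriding
        both the estimate and the variant metadata.

    Returns
    -------
    maternal : ``(V, n, 3)`` posterior triples.  Monomorphic variants
        (estimated p of 0 or 1) are returned as all-missing rows and a
        warning is logged.
    p_used : the per-variant frequency actually applied (NaN where
        monomorphic).
    """
    infant = np.asarray(infant)
    if infant.ndim == 2 and infant.shape[-1] != 3:
        triples = hard_to_triples(infant)
    elif infant.ndim == 3 and infant.shape[-1] == 3:
        triples = np.asarray(infant, dtype=float)
    else:
        raise ValueError(f"unrecognised infant genotype shape {infant.shape}")
    n_var, n_samp = triples.shape[:2]

    p_used = np.full(n_var, np.nan)
    if raf is not None:
        p_used[:] = np.asarray(raf, dtype=float)
    else:
        if variants is not None:
            for i, v in enumerate(variants):
                if np.isfinite(v.raf):
                    p_used[i] = v.raf
        est = estimate_allele_frequency(triples)
        fill = ~np.isfinite(p_used)
        p_used[fill] = np.atleast_1d(est)[fill]

    maternal = np.zeros_like(triples)
    miss = missing_mask(triples)
    poly = (p_used > 0.0) & (p_used < 1.0)
    if (~poly).any():
        bad = np.flatnonzero(~poly)
        names = (
            [variants[i].snp_id for i in bad] if variants is not None else list(bad)
        )
        logger.warning("dropping %d monomorphic variant(s): %s", len(bad), names)
        p_used[~poly] = np.nan
    for i in np.flatnonzero(poly):
        table = _posterior_table(p_used[i])  # rows: child c -> maternal triple
        child = triples[i]
        s = child.sum(axis=1, keepdims=True)
        norm = np.where(s < 1e-12, 1.0, s)
        maternal[i] = (child / norm) @ table
        maternal[i, miss[i]] = hwe_prior(p_used[i])
    return maternal, p_used
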