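"""Genotype and phenotype file I/O.

Genotypes move through the pipeline as *probability triples*: for each
sample and variant, a distribution ``(pi0, pi1, pi2)`` over carrying
0/1/2 copies of the **reference** allele.  In memory a cohort is a
``(n_variants, n_samples, 3)`` float array; a hard call is a degenerate
triple and a missing genotype is all-zero.

Allele-orientation convention (this determines every effect sign
downstream, so it is stated once, here):

* In memory, triples are indexed by reference-allele count:
  ``pi0 = P(hom-alt)``, ``pi1 = P(het)``, ``pi2 = P(hom-ref)``.
* In Oxford GEN files the three probability columns follow the Oxford
  ordering ``P(hom-ref) P(het) P(hom-alt)`` with the reference allele
  written in the fourth leading column (allele A).  The reader/writer
  reverse the ordering accordingly.
* In VCF, a ``GT`` of ``0/1`` (one REF copy) maps to ``(0, 1, 0)``;
  ``GP`` fields (ordered hom-ref, het, hom-alt) are reversed like GEN.

Coordinates are 1-based and fully closed (hg19 convention); no liftover.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .fatty_acids import FA_NAMES

__all__ = [
    "Variant",
    "GenParseError",
    "TripleValidationError",
    "hard_to_triples",
    "triples_to_dosage",
    "missing_mask",
    "validate_triples",
    "read_genotype_file",
    "write_genotype_file",
    "read_sample_file",
    "write_sample_file",
    "read_phenotype_table",
    "write_phenotype_table",
]

#: Raw per-sample probability rows may deviate from unit sum by storage
#: rounding; anything outside this band is treated as a corrupt record.
_SUM_BAND = (0.98, 1.02)


class GenParseError(ValueError):
    """A genotype file could not be parsed; the message names the line."""


class TripleValidationError(ValueError):
    """A probability triple violated the distribution constraints."""


@dataclass
class Variant:
    """A biallelic variant with its locus metadata.

    Attributes
    ----------
    chrom, pos : locus (1-based physical position, hg19).
    ref_allele, alt_allele : allele strings; effects are reported per
        reference allele.
    raf : reference-allele frequency in the cohort, NaN until estimated.
    info : imputation information score in [0, 1], NaN until computed.
    snp_id : rs identifier or ".".
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    raf: float = float("nan")
    info: float = float("nan")
    snp_id: str = "."

    def __post_init__(self) -> None:
        self.chrom = str(self.chrom)
        self.pos = int(self.pos)
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(
                f"reference and alternative allele are identical ({self.ref_allele})"
            )
        for name in ("raf", "info"):
            val = getattr(self, name)
            if not np.isnan(val) and not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {val}")

    @property
    def maf(self) -> float:
        """Minor-allele frequency, min(raf, 1-raf)."""
        return min(self.raf, 1.0 - self.raf)

    def same_alleles(self, other: "Variant") -> bool:
        """Strict allele-orientation match (no strand flipping)."""
        return (
            self.ref_allele == other.ref_allele
            and self.alt_allele == other.alt_allele
        )


# ---------------------------------------------------------------------------
# triple helpers
# ---------------------------------------------------------------------------

def hard_to_triples(genotypes: np.ndarray) -> np.ndarray:
    """Convert hard reference-allele counts to degenerate triples.

    ``genotypes`` is an integer array with values in {0, 1, 2}; -1 marks a
    missing call and becomes the all-zero (missing) triple.
    """
    g = np.asarray(genotypes)
    out = np.zeros(g.shape + (3,), dtype=float)
    for c in (0, 1, 2):
        out[..., c] = g == c
    return out


def triples_to_dosage(triples: np.ndarray) -> np.ndarray:
    """Posterior-mean reference-allele count, pi1 + 2*pi2."""
    t = np.asarray(triples, dtype=float)
    return t[..., 1] + 2.0 * t[..., 2]


def missing_mask(triples: np.ndarray) -> np.ndarray:
    """True where a triple is the all-zero missing encoding."""
    return np.asarray(triples).sum(axis=-1) < 1e-12


def validate_triples(triples: np.ndarray, where: str = "genotype data") -> np.ndarray:
    """Renormalise probability triples to unit sum and validate them.

    Missing (all-zero) triples pass through untouched.  Raises
    :class:`TripleValidationError` if a non-missing row sums outside
    [0.98, 1.02] before renormalisation, or has a negative entry.
    """
    t = np.array(triples, dtype=float)
    if t.shape[-1] != 3:
        raise TripleValidationError(f"{where}: last axis must have length 3")
    if (t < -1e-12).any():
        raise TripleValidationError(f"{where}: negative probability entry")
    s = t.sum(axis=-1)
    miss = s < 1e-12
    bad = ~miss & ((s < _SUM_BAND[0]) | (s > _SUM_BAND[1]))
    if bad.any():
        idx = np.argwhere(bad)[0]
        raise TripleValidationError(
            f"{where}: probability triple at index {tuple(idx)} sums to "
            f"{s[tuple(idx)]:.4f}, outside [{_SUM_BAND[0]}, {_SUM_BAND[1]}]"
        )
    s_safe = np.where(miss, 1.0, s)
    t = t / s_safe[..., None]
    t[miss] = 0.0
    return np.clip(t, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Oxford GEN / SAMPLE
# ---------------------------------------------------------------------------

def write_genotype_file(
    variants: Sequence[Variant],
    triples: np.ndarray,
    path: str | os.PathLike,
    sample_ids: Sequence[str] | None = None,
    covariates: pd.DataFrame | None = None,
    fmt: str = "gen",
) -> None:
    """Write variants and triples as an Oxford GEN file plus SAMPLE file.

    Leading columns are ``chrom snp_id pos refA altA``; probabilities are
    serialised with 6 significant digits in Oxford order
    (hom-ref, het, hom-alt), i.e. reversed relative to the in-memory
    reference-count order.  The companion SAMPLE file is written next to
    the GEN file with extension ``.sample``.
    """
    if fmt != "gen":
        raise ValueError(f"unsupported output format: {fmt!r}")
    triples = np.asarray(triples, dtype=float)
    n_var = len(variants)
    if triples.shape[:1] != (n_var,) or (n_var and triples.shape[-1] != 3):
        if n_var or triples.size:
            raise ValueError(
                f"triples shape {triples.shape} does not match {n_var} variants"
            )
    n_samples = triples.shape[1] if n_var else 0
    if sample_ids is None:
        sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    path = os.fspath(path)
    with open(path, "w") as fh:
        for vi, v in enumerate(variants):
            lead = f"{v.chrom} {v.snp_id} {v.pos} {v.ref_allele} {v.alt_allele}"
            probs = triples[vi][:, ::-1].ravel()  # reverse to Oxford order
            fh.write(lead + " " + " ".join(f"{p:.6g}" for p in probs) + "\n")
    write_sample_file(_sample_path(path), sample_ids, covariates)


def _sample_path(gen_path: str) -> str:
    stem, _ = os.path.splitext(gen_path)
    return stem + ".sample"


def write_sample_file(
    path: str | os.PathLike,
    sample_ids: Sequence[str],
    covariates: pd.DataFrame | None = None,
) -> None:
    """Write an Oxford SAMPLE file (two header rows, then one row/sample).

    Covariate columns are typed ``C`` (continuous) unless the column is
    binary 0/1, which is typed ``B``.
    """
    cols = list(covariates.columns) if covariates is not None else []
    with open(os.fspath(path), "w") as fh:
        fh.write(" ".join(["ID_1", "ID_2", "missing"] + cols) + "\n")
        types = []
        for c in cols:
            vals = covariates[c].dropna().unique()
            types.append("B" if set(np.asarray(vals).tolist()) <= {0, 1} else "C")
        fh.write(" ".join(["0", "0", "0"] + types) + "\n")
        for i, sid in enumerate(sample_ids):
            row = [str(sid), str(sid), "0"]
            if covariates is not None:
                row += [f"{covariates.iloc[i][c]:g}" for c in cols]
            fh.write(" ".join(row) + "\n")


def read_sample_file(path: str | os.PathLike) -> pd.DataFrame:
    """Read an Oxford SAMPLE file into a DataFrame indexed by sample id."""
    df = pd.read_csv(path, sep=r"\s+", skiprows=[1])
    df = df.set_index("ID_1")
    df.index.name = "sample_id"
    return df.drop(columns=["ID_2", "missing"], errors="ignore")


def _read_gen(path: str) -> tuple[list[Variant], np.ndarray, list[str]]:
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    n_samples = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) < 5 or (len(fields) - 5) % 3 != 0:
                raise GenParseError(
                    f"{path}:{lineno}: expected 5 leading fields plus "
                    f"3 probabilities per sample, got {len(fields)} fields"
                )
            chrom, snp_id, pos, ref, alt = fields[:5]
            try:
                v = Variant(chrom, int(pos), ref, alt, snp_id=snp_id)
                probs = np.array(fields[5:], dtype=float)
            except ValueError as exc:
                raise GenParseError(f"{path}:{lineno}: {exc}") from exc
            ns = probs.size // 3
            if n_samples is None:
                n_samples = ns
            elif ns != n_samples:
                raise GenParseError(
                    f"{path}:{lineno}: {ns} samples, expected {n_samples}"
                )
            variants.append(v)
            rows.append(probs.reshape(ns, 3)[:, ::-1])  # Oxford -> ref-count order
    if n_samples is None:
        n_samples = 0
    triples = (
        np.stack(rows) if rows else np.zeros((0, n_samples, 3))
    )
    triples = validate_triples(triples, where=path)
    sample_ids = [f"S{i + 1}" for i in range(n_samples)]
    spath = _sample_path(path)
    if os.path.exists(spath):
        sample_ids = list(read_sample_file(spath).index.astype(str))
        if len(sample_ids) != n_samples:
            raise GenParseError(
                f"{spath}: {len(sample_ids)} samples, GEN file has {n_samples}"
            )
    return variants, triples, sample_ids


def _read_vcf(path: str) -> tuple[list[Variant], np.ndarray, list[str]]:
    # cyvcf2 handles the VCF grammar; only biallelic GT/GP records are used.
    from cyvcf2 import VCF

    vcf = VCF(os.fspath(path))
    sample_ids = list(vcf.samples)
    variants: list[Variant] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise GenParseError(
                f"{path}: multi-allelic record at {rec.CHROM}:{rec.POS} unsupported"
            )
        variants.append(
            Variant(rec.CHROM, rec.POS, rec.REF, rec.ALT[0], snp_id=rec.ID or ".")
        )
        gp = None
        try:
            gp = rec.format("GP")
        except KeyError:
            gp = None
        if gp is not None:
            rows.append(np.asarray(gp, dtype=float)[:, ::-1])
        else:
            # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
            ref_count = np.choose(rec.gt_types, [2, 1, -1, 0])
            rows.append(hard_to_triples(ref_count))
    triples = (
        np.stack(rows) if rows else np.zeros((0, len(sample_ids), 3))
    )
    return variants, validate_triples(triples, where=path), sample_ids


def read_genotype_file(
    path: str | os.PathLike, fmt: str = "gen"
) -> tuple[list[Variant], np.ndarray, list[str]]:
    """Read a genotype file into (variants, triples, sample ids).

    Parameters
    ----------
    path : GEN or VCF file.  For GEN, a companion ``.sample`` file next to
        it supplies sample ids when present.
    fmt : ``"gen"`` or ``"vcf"``.

    Returns
    -------
    variants : list of :class:`Variant`
    triples : ``(n_variants, n_samples, 3)`` array in reference-count order,
        renormalised to unit sum; missing genotypes are all-zero.
    sample_ids : list of str
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt == "gen":
        return _read_gen(path)
    if fmt == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unsupported format: {fmt!r}")


# ---------------------------------------------------------------------------
# phenotype tables
# ---------------------------------------------------------------------------

#: Covariates of the screening model.
COVARIATE_NAMES = ("maternal_age", "infant_age_days", "infant_sex", "site")


def read_phenotype_table(path: str | os.PathLike, strict: bool = True) -> pd.DataFrame:
    """Read a tab-delimited fatty-acid phenotype/covariate table.

    The table must contain the 26 assayed fraction columns named by their
    standard abbreviations (CAP ... LLA) and may carry covariate and
    derived-fraction columns.  Fractions are %wt/wt; negative values are
    rejected; missing values stay NaN.  With ``strict=True`` any
    unrecognised column raises, listing the expected names.
    """
    df = pd.read_csv(path, sep="\t")
    if "sample_id" in df.columns:
        df = df.set_index("sample_id")
    missing = [c for c in FA_NAMES if c not in df.columns]
    if missing:
        raise ValueError(
            f"phenotype table lacks fatty-acid columns {missing}; "
            f"expected the 26 abbreviations {list(FA_NAMES)}"
        )
    from .fatty_acids import DERIVED_NAMES

    known = set(FA_NAMES) | set(DERIVED_NAMES) | set(COVARIATE_NAMES)
    unknown = [c for c in df.columns if c not in known]
    if unknown and strict:
        raise ValueError(
            f"unknown columns {unknown}; expected fatty acids {list(FA_NAMES)}, "
            f"derived fractions {list(DERIVED_NAMES)} or covariates "
            f"{list(COVARIATE_NAMES)}"
        )
    frac = df[list(FA_NAMES)].astype(float)
    if (frac < 0).any().any():
        col = frac.columns[(frac < 0).any()][0]
        raise ValueError(f"negative fraction in column {col}")
    df[list(FA_NAMES)] = frac
    return df


def write_phenotype_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a phenotype table as tab-delimited text (lossless re-read)."""
    out = df.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t", index=True)
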