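"""Reference table of the 26 assayed breast-milk fatty acids.

Each fatty acid (FA) is identified by the short abbreviation used throughout
the package (column names of phenotype tables) and carries its lipid class,
its chemical formula shorthand, and a default mean/SD of the fractional
composition (%wt/wt of total identified FA) typical of a South-Asian birth
cohort.  The defaults parameterise the synthetic-data generator
and are overridable per :class:`milkgwas.simulate.SimConfig`.

Classes
-------
SFA    saturated
MUFA   cis-monounsaturated
PUFA6  cis-polyunsaturated omega-6
PUFA3  cis-polyunsaturated omega-3
TFA    trans
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FattyAcid:
    abbrev: str
    formula: str
    fa_class: str
    mean: float  # %wt/wt
    sd: float


#: The 26 assayed fatty acids, in reporting order.
FATTY_ACIDS: tuple[FattyAcid, ...] = (
    # saturated
    FattyAcid("CAP", "C10:0", "SFA", 1.15, 0.52),
    FattyAcid("LAU", "C12:0", "SFA", 8.18, 2.99),
    FattyAcid("MYR", "C14:0", "SFA", 8.01, 3.04),
    FattyAcid("PAL", "C16:0", "SFA", 26.64, 3.76),
    FattyAcid("STE", "C18:0", "SFA", 3.89, 0.77),
    FattyAcid("ARA", "C20:0", "SFA", 0.14, 0.03),
    FattyAcid("BEH", "C22:0", "SFA", 0.07, 0.02),
    FattyAcid("LIG", "C24:0", "SFA", 0.08, 0.03),
    # cis-monounsaturated
    FattyAcid("PLE", "C16:1n7", "MUFA", 2.96, 1.10),
    FattyAcid("OLE", "C18:1n9", "MUFA", 33.24, 4.67),
    FattyAcid("EIC", "C20:1n9", "MUFA", 0.41, 0.16),
    FattyAcid("NER", "C24:1n9", "MUFA", 0.15, 0.11),
    # cis-polyunsaturated omega-6
    FattyAcid("LA", "C18:2n6", "PUFA6", 11.29, 5.09),
    FattyAcid("GLA", "C18:3n6", "PUFA6", 0.16, 0.11),
    FattyAcid("EDA", "C20:2n6", "PUFA6", 0.41, 0.18),
    FattyAcid("DGLA", "C20:3n6", "PUFA6", 0.55, 0.17),
    FattyAcid("AA", "C20:4n6", "PUFA6", 0.53, 0.15),
    FattyAcid("DTA", "C22:4n6", "PUFA6", 0.18, 0.10),
    FattyAcid("DPA6", "C22:5n6", "PUFA6", 0.12, 0.05),
    # cis-polyunsaturated omega-3
    FattyAcid("ALA", "C18:3n3", "PUFA3", 0.54, 0.40),
    FattyAcid("EPA", "C20:5n3", "PUFA3", 0.06, 0.07),
    FattyAcid("DPA", "C22:5n3", "PUFA3", 0.14, 0.08),
    FattyAcid("DHA", "C22:6n3", "PUFA3", 0.39, 0.14),
    # trans
    FattyAcid("PLA", "C16:1n7t", "TFA", 0.06, 0.03),
    FattyAcid("ELA", "C18:1t", "TFA", 0.35, 0.24),
    FattyAcid("LLA", "C18:2n6t", "TFA", 0.32, 0.16),
)

#: Abbreviations of the 26 assayed fractions, in order.
FA_NAMES: tuple[str, ...] = tuple(fa.abbrev for fa in FATTY_ACIDS)

#: Lipid classes in reporting order.
FA_CLASSES: tuple[str, ...] = ("SFA", "MUFA", "PUFA6", "PUFA3", "TFA")

#: abbreviation -> class lookup.
CLASS_OF: dict[str, str] = {fa.abbrev: fa.fa_class for fa in FATTY_ACIDS}

#: class -> member abbreviations, in order.
MEMBERS_OF: dict[str, tuple[str, ...]] = {
    c: tuple(fa.abbrev for fa in FATTY_ACIDS if fa.fa_class == c) for c in FA_CLASSES
}

#: Derived summary phenotypes added on top of the 26 assayed fractions:
#: per-class totals, total PUFA, and the omega-6/omega-3 ratio.
DERIVED_NAMES: tuple[str, ...] = (
    "SFA",
    "MUFA",
    "PUFA6",
    "PUFA3",
    "PUFA",
    "TFA",
    "PUFA6/PUFA3",
)

#: All 33 phenotype names (26 assayed + 7 derived).
ALL_PHENOTYPES: tuple[str, ...] = FA_NAMES + DERIVED_NAMES


def default_means() -> dict[str, float]:
    return {fa.abbrev: fa.mean for fa in FATTY_ACIDS}


def default_sds() -> dict[str, float]:
    return {fa.abbrev: fa.sd for fa in FATTY_ACIDS}
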