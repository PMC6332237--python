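"""Built-in compound library and reference MS/HRMS data for the
rugulovasine alkaloid series.

Rugulovasines are clavine-type ergot alkaloids (C16H16N2O2 core with a
spirolactone) produced by *Talaromyces wortmannii* as interconverting
A/B epimer pairs, together with mono- and dichlorinated congeners;
brominated congeners appear when the growth medium is supplemented with
a bromide source.  The library carries the eight series members with
published ion formulas; the reference spectra carry their literature-
reported [M+H]+ accurate masses and product-ion tables (25 eV,
positive electrospray), which double as templates for the synthetic
data generator.

Other confirmed co-metabolites of the producer strain (mitorubrins,
skyrin, rugulosin, multicolanic acid) are reported without printed
formulas and are therefore loadable from user CSV only, never embedded
as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .formula import Formula, parse_formula

__all__ = ["LibraryEntry", "ReferenceIon", "ReferenceSpectrum", "RUGULOVASINE_LIBRARY", "REFERENCE_SPECTRA", "default_library"]


@dataclass(frozen=True)
class LibraryEntry:
    """One dereplication-library compound."""

    name: str
    formula: Formula  # neutral molecule
    compound_class: str = "clavine alkaloid"
    #: shared id of an A/B epimer pair (empty when unpaired)
    epimer_group: str = ""
    #: "A" or "B" within the pair, empty when unpaired
    epimer_label: str = ""
    #: UV absorption maxima in nm, metadata only
    uv_maxima_nm: Tuple[int, ...] = ()

    @property
    def mz_protonated(self) -> float:
        return self.formula.protonated().mz()


@dataclass(frozen=True)
class ReferenceIon:
    """One reported accurate mass: observed m/z, intensity, composition.

    ``printed_formula_typo`` records a literature composition that is
    inconsistent with its own printed mass; annotation always follows
    the mass (see the class II ions of the monochloro epimers, whose
    printed composition belongs to the chlorine-radical-loss ion while
    the mass fits the HCl-loss ion).
    """

    mz: float
    rel_intensity_pct: float
    ion_formula: Formula  # mass-consistent composition, charge +1
    species_class: str  # "precursor", "I".."V"
    printed_formula_typo: Optional[str] = None


@dataclass(frozen=True)
class ReferenceSpectrum:
    """Reported precursor + product-ion table of one library compound."""

    compound: str
    precursor: ReferenceIon
    products: Tuple[ReferenceIon, ...] = ()

    @property
    def all_ions(self) -> Tuple[ReferenceIon, ...]:
        return (self.precursor,) + self.products


def _entry(name: str, formula: str, group: str, label: str) -> LibraryEntry:
    return LibraryEntry(
        name=name,
        formula=parse_formula(formula),
        epimer_group=group,
        epimer_label=label,
        uv_maxima_nm=(225, 295),
    )


#: The eight rugulovasine-series compounds with published compositions.
RUGULOVASINE_LIBRARY: Tuple[LibraryEntry, ...] = (
    _entry("rugulovasine A", "C16H16N2O2", "rugulovasine", "A"),
    _entry("rugulovasine B", "C16H16N2O2", "rugulovasine", "B"),
    _entry("8-chlororugulovasine A", "C16H15ClN2O2", "8-chlororugulovasine", "A"),
    _entry("8-chlororugulovasine B", "C16H15ClN2O2", "8-chlororugulovasine", "B"),
    _entry("2,8-dichlororugulovasine A", "C16H14Cl2N2O2", "2,8-dichlororugulovasine", "A"),
    _entry("2,8-dichlororugulovasine B", "C16H14Cl2N2O2", "2,8-dichlororugulovasine", "B"),
    _entry("2-bromorugulovasine A", "C16H15BrN2O2", "2-bromorugulovasine", "A"),
    _entry("2-bromorugulovasine B", "C16H15BrN2O2", "2-bromorugulovasine", "B"),
)


def _ion(
    mz: float,
    pct: float,
    formula: str,
    cls: str,
    typo: Optional[str] = None,
) -> ReferenceIon:
    return ReferenceIon(mz, pct, parse_formula(formula, 1), cls, typo)


#: Reported MS/HRMS reference data, one spectrum per library compound.
REFERENCE_SPECTRA: Tuple[ReferenceSpectrum, ...] = (
    ReferenceSpectrum(
        "rugulovasine A",
        _ion(269.1284, 72, "C16H17O2N2", "precursor"),
    ),
    ReferenceSpectrum(
        "rugulovasine B",
        _ion(269.1284, 37, "C16H17O2N2", "precursor"),
        (_ion(140.0705, 8, "C7H10O2N", "V"),),
    ),
    ReferenceSpectrum(
        "8-chlororugulovasine A",
        _ion(303.0894, 55, "C16H16O2N2Cl", "precursor"),
        (
            _ion(268.1208, 5, "C16H16O2N2", "I"),
            _ion(267.1127, 3, "C16H15O2N2", "II", typo="C16H15O2N2Cl"),
            _ion(249.1022, 8, "C16H13ON2", "III"),
        ),
    ),
    ReferenceSpectrum(
        "8-chlororugulovasine B",
        _ion(303.0894, 17, "C16H16O2N2Cl", "precursor"),
        (
            _ion(268.1205, 3, "C16H16O2N2", "I"),
            _ion(267.1122, 3, "C16H15O2N2", "II", typo="C16H15O2N2Cl"),
            _ion(249.1021, 12, "C16H13ON2", "III"),
            _ion(140.0705, 17, "C7H10O2N", "V"),
        ),
    ),
    ReferenceSpectrum(
        "2,8-dichlororugulovasine A",
        _ion(337.0503, 73, "C16H15O2N2Cl2", "precursor"),
        (
            _ion(302.0814, 16, "C16H15O2N2Cl", "I"),
            _ion(301.0736, 68, "C16H14O2N2Cl", "II"),
            _ion(283.0631, 75, "C16H12ON2Cl", "III"),
            _ion(255.0679, 5, "C15H12N2Cl", "IV"),
        ),
    ),
    ReferenceSpectrum(
        "2,8-dichlororugulovasine B",
        _ion(337.0501, 35, "C16H15O2N2Cl2", "precursor"),
        (
            _ion(302.0812, 5, "C16H15O2N2Cl", "I"),
            _ion(301.0734, 27, "C16H14O2N2Cl", "II"),
            _ion(283.0628, 33, "C16H12ON2Cl", "III"),
            _ion(255.0677, 6, "C15H12N2Cl", "IV"),
            _ion(140.0703, 18, "C7H10O2N", "V"),
        ),
    ),
    ReferenceSpectrum(
        "2-bromorugulovasine A",
        _ion(347.0388, 37, "C16H16O2N2Br", "precursor"),
        (
            _ion(268.1205, 13, "C16H16O2N2", "I"),
            _ion(267.1128, 21, "C16H15O2N2", "II"),
            _ion(249.1021, 11, "C16H13ON2", "III"),
            _ion(221.1072, 5, "C15H13N2", "IV"),
        ),
    ),
    ReferenceSpectrum(
        "2-bromorugulovasine B",
        _ion(347.0387, 13, "C16H16O2N2Br", "precursor"),
        (
            _ion(268.1206, 14, "C16H16O2N2", "I"),
            _ion(267.1128, 31, "C16H15O2N2", "II"),
            _ion(249.1021, 14, "C16H13ON2", "III"),
            _ion(221.1072, 4, "C15H13N2", "IV"),
            _ion(140.0705, 13, "C7H10O2N", "V"),
        ),
    ),
)

#: Preset chromatographic retention times (min), reversed phase.  The
#: dichloro pair elutes at 3.7/3.9 min; other compounds are placed in
#: the 3–8 min window with each A epimer 0.2 min before its B epimer.
PRESET_RT_MIN: Dict[str, float] = {
    "rugulovasine A": 4.5,
    "rugulovasine B": 4.7,
    "8-chlororugulovasine A": 5.3,
    "8-chlororugulovasine B": 5.5,
    "2,8-dichlororugulovasine A": 3.7,
    "2,8-dichlororugulovasine B": 3.9,
    "2-bromorugulovasine A": 6.1,
    "2-bromorugulovasine B": 6.3,
}


def default_library() -> List[LibraryEntry]:
    """A fresh mutable copy of the built-in eight-compound library."""
    return list(RUGULOVASINE_LIBRARY)


def reference_spectrum(compound: str) -> ReferenceSpectrum:
    for s in REFERENCE_SPECTRA:
        if s.compound == compound:
            return s
    raise KeyError(f"no reference spectrum for {compound!r}")
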