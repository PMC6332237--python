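"""Static isotope table for the supported element alphabet.

The table covers the ten elements relevant to halogenated alkaloid
screening (C, H, N, O, S, P, Cl, Br, Na, K).  Masses are in daltons,
abundances are natural-abundance fractions from the standard atomic-mass
evaluations.  The table is versioned with the package and never fetched
at runtime; :mod:`haloscreen.formula` and :mod:`haloscreen.isotopes`
build every mass and envelope from it, so there is exactly one source of
truth for mass arithmetic.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

#: Rest mass of the electron in Da; subtracted once per positive charge
#: when converting a composition mass to an observed m/z.
ELECTRON_MASS: float = 0.000548579909

#: symbol -> list of (nominal mass number, exact mass / Da, abundance fraction),
#: sorted by increasing mass.
ISOTOPES: Dict[str, List[Tuple[int, float, float]]] = {
    "H": [(1, 1.0078250319, 0.999885), (2, 2.0141017779, 0.000115)],
    "C": [(12, 12.0, 0.9893), (13, 13.0033548352, 0.0107)],
    "N": [(14, 14.0030740052, 0.99636), (15, 15.0001088984, 0.00364)],
    "O": [
        (16, 15.9949146221, 0.99757),
        (17, 16.9991315, 0.00038),
        (18, 17.9991604, 0.00205),
    ],
    "P": [(31, 30.97376151, 1.0)],
    "S": [
        (32, 31.97207069, 0.9499),
        (33, 32.9714585, 0.0075),
        (34, 33.96786683, 0.0425),
        (36, 35.96708088, 0.0001),
    ],
    "Cl": [(35, 34.96885271, 0.7576), (37, 36.9659026, 0.2424)],
    "Br": [(79, 78.9183376, 0.5069), (81, 80.9162906, 0.4931)],
    "Na": [(23, 22.98976928, 1.0)],
    "K": [
        (39, 38.9637069, 0.932581),
        (40, 39.96399867, 0.000117),
        (41, 40.96182597, 0.067302),
    ],
}

#: Elements accepted anywhere in the package.  Anything else is rejected
#: loudly rather than silently dropped.
SUPPORTED_ELEMENTS = frozenset(ISOTOPES)


class UnknownElementError(ValueError):
    """Raised when a formula names an element outside the supported alphabet."""


def monoisotopic_mass_of(symbol: str) -> float:
    """Exact mass of the lightest (here also most abundant) isotope."""
    try:
        return ISOTOPES[symbol][0][1]
    except KeyError:
        raise UnknownElementError(
            f"unsupported element {symbol!r}; supported: "
            f"{', '.join(sorted(SUPPORTED_ELEMENTS))}"
        ) from None


def isotope_distribution_of(symbol: str) -> List[Tuple[float, float]]:
    """(mass, abundance) pairs for one atom of ``symbol``."""
    if symbol not in ISOTOPES:
        raise UnknownElementError(
            f"unsupported element {symbol!r}; supported: "
            f"{', '.join(sorted(SUPPORTED_ELEMENTS))}"
        )
    return [(m, a) for (_, m, a) in ISOTOPES[symbol]]
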