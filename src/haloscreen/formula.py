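"""Elemental formulas and exact-mass arithmetic.

A :class:`Formula` is a multiset of element counts plus an integer
charge; throughout the package the only charge states are 0 (neutral
molecules) and +1 (protonated cations, the [M+H]+ species of positive
electrospray).  Cation m/z values are electron-mass corrected by
default: the observed ion is a composition that has *lost* one
electron, so its m/z is the summed atomic mass minus one electron mass.
At sub-ppm mass accuracy this 0.55 mDa correction is decisive — at
m/z 140 it amounts to ~3.9 ppm, larger than the instrument error.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping

from .elements import (
    ELECTRON_MASS,
    SUPPORTED_ELEMENTS,
    UnknownElementError,
    monoisotopic_mass_of,
)

__all__ = [
    "Formula",
    "FormulaParseError",
    "parse_formula",
    "monoisotopic_mz",
    "ppm_error",
    "rdbe",
    "formula_difference",
    "nominal_mass",
]

#: Hill-order element listing: carbon, hydrogen, then the rest alphabetically.
_HILL_ORDER = ("C", "H") + tuple(sorted(SUPPORTED_ELEMENTS - {"C", "H"}))

_TOKEN_RE = re.compile(r"([A-Z][a-z]?)(\d*)")


class FormulaParseError(ValueError):
    """Malformed composition string; the message names the offending token."""


@dataclass(frozen=True)
class Formula:
    """Immutable element->count multiset with an integer charge.

    ``counts`` only stores strictly positive entries; the empty formula
    is represented by an empty mapping and is permitted only at
    charge 0 (it is the additive identity of composition algebra).
    """

    counts: Mapping[str, int] = field(default_factory=dict)
    charge: int = 0

    def __post_init__(self) -> None:
        clean: Dict[str, int] = {}
        for el, n in self.counts.items():
            if el not in SUPPORTED_ELEMENTS:
                raise UnknownElementError(
                    f"unsupported element {el!r} in formula"
                )
            if not isinstance(n, int) or n < 0:
                raise ValueError(f"count for {el} must be a non-negative int, got {n!r}")
            if n > 0:
                clean[el] = n
        object.__setattr__(self, "counts", clean)

    # -- container protocol -------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self.counts.get(el, 0)

    def __iter__(self) -> Iterator[str]:
        return iter(self.counts)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __hash__(self) -> int:
        return hash((tuple(sorted(self.counts.items())), self.charge))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Formula):
            return NotImplemented
        return self.counts == other.counts and self.charge == other.charge

    @property
    def atom_count(self) -> int:
        return sum(self.counts.values())

    # -- algebra ------------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        merged = dict(self.counts)
        for el, n in other.counts.items():
            merged[el] = merged.get(el, 0) + n
        return Formula(merged, self.charge + other.charge)

    def __sub__(self, other: "Formula") -> "Formula":
        """Element-wise subtraction; negative counts are an error.

        Use :func:`formula_difference` for a signed delta.
        """
        out = dict(self.counts)
        for el, n in other.counts.items():
            rem = out.get(el, 0) - n
            if rem < 0:
                raise ValueError(
                    f"cannot subtract {other.to_string()} from {self.to_string()}: "
                    f"negative {el} count"
                )
            out[el] = rem
        return Formula(out, self.charge - other.charge)

    def contains(self, other: "Formula") -> bool:
        return all(self[el] >= n for el, n in other.counts.items())

    def replace_charge(self, charge: int) -> "Formula":
        return Formula(dict(self.counts), charge)

    def protonated(self) -> "Formula":
        """The [M+H]+ ion composition of this neutral molecule."""
        return Formula({**self.counts, "H": self["H"] + 1}, self.charge + 1)

    def deprotonated_neutral(self) -> "Formula":
        """Remove one H and the charge: inverse of :meth:`protonated`."""
        if self["H"] < 1:
            raise ValueError("cannot remove H from an H-free formula")
        return Formula({**self.counts, "H": self["H"] - 1}, 0)

    # -- masses -------------------------------------------------------------
    @property
    def monoisotopic_mass(self) -> float:
        """Sum of lightest-isotope masses (no electron correction)."""
        return sum(monoisotopic_mass_of(el) * n for el, n in self.counts.items())

    def mz(self, charge: int | None = None, electron_corrected: bool = True) -> float:
        return monoisotopic_mz(self, charge=charge, electron_corrected=electron_corrected)

    # -- serialization ------------------------------------------------------
    def to_string(self) -> str:
        """Hill-notation string (C, H, then alphabetical)."""
        parts = []
        for el in _HILL_ORDER:
            n = self[el]
            if n == 1:
                parts.append(el)
            elif n > 1:
                parts.append(f"{el}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()

    def __repr__(self) -> str:
        q = {0: "", 1: "+", -1: "-"}.get(self.charge, f"{self.charge:+d}")
        return f"Formula({self.to_string()}{q})"

    @classmethod
    def parse(cls, text: str, charge: int = 0) -> "Formula":
        return parse_formula(text, charge=charge)


def parse_formula(text: str, charge: int = 0) -> Formula:
    """Parse a Hill-style composition string such as ``"C16H15O2N2Cl2"``.

    A missing count means 1.  Element order is free; unknown element
    symbols and malformed tokens raise with the offending token named.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaParseError("empty formula string")
    s = text.strip()
    counts: Dict[str, int] = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN_RE.match(s, pos)
        if not m or not m.group(1):
            raise FormulaParseError(
                f"malformed formula {text!r}: unexpected token {s[pos:]!r}"
            )
        el, digits = m.group(1), m.group(2)
        if el not in SUPPORTED_ELEMENTS:
            raise FormulaParseError(
                f"malformed formula {text!r}: unknown element {el!r}"
            )
        n = int(digits) if digits else 1
        if n == 0:
            raise FormulaParseError(
                f"malformed formula {text!r}: zero count for {el!r}"
            )
        counts[el] = counts.get(el, 0) + n
        pos = m.end()
    return Formula(counts, charge)


def monoisotopic_mz(
    formula: Formula,
    charge: int | None = None,
    electron_corrected: bool = True,
) -> float:
    """Theoretical monoisotopic m/z of ``formula`` at the given charge.

    For charge 0 this is the neutral monoisotopic mass.  For +1 the
    composition mass is reduced by one electron mass (when
    ``electron_corrected``, the default) because the cation lacks one
    electron relative to its atoms.
    """
    z = formula.charge if charge is None else charge
    if z not in (0, 1):
        raise ValueError(f"only charges 0 and +1 are supported, got {z}")
    if not formula:
        if z != 0:
            raise ValueError("empty formula cannot carry charge")
        return 0.0
    mass = formula.monoisotopic_mass
    if z == 0:
        return mass
    if electron_corrected:
        mass -= z * ELECTRON_MASS
    return mass / z


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error, (observed − theoretical)/theoretical × 1e6."""
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (observed - theoretical) / theoretical * 1e6


def rdbe(formula: Formula) -> float:
    """Ring-and-double-bond equivalents of the neutralized formula.

    RDBE = 1 + C + (N+P)/2 − (H + Cl + Br)/2; O and S contribute zero at
    neutral valence.  A +1 (protonated) formula is neutralized by
    removing one hydrogen first, so even-electron cations give the
    RDBE of the underlying neutral molecule.  The value may be negative
    or half-integral; filtering on it is the caller's decision.
    """
    f = formula.deprotonated_neutral() if formula.charge == 1 else formula
    return (
        1.0
        + f["C"]
        + (f["N"] + f["P"]) / 2.0
        - (f["H"] + f["Cl"] + f["Br"]) / 2.0
    )


def formula_difference(a: Formula, b: Formula) -> Dict[str, int]:
    """Signed per-element delta ``a − b``; zero entries are omitted.

    E.g. dichloro-ion minus parent-ion gives ``{"Cl": 2, "H": -2}`` —
    two chlorines traded for two hydrogens.
    """
    delta: Dict[str, int] = {}
    for el in set(a.counts) | set(b.counts):
        d = a[el] - b[el]
        if d != 0:
            delta[el] = d
    return delta


def nominal_mass(mass: float) -> int:
    """Integer (nominal) mass: round-half-away-from-zero of an exact mass.

    Applied per ion before differencing; reproduces the whole-dalton
    bookkeeping of quick spectral inspection (m/z 347, Δ44, Δ78).
    """
    import math

    return int(math.floor(abs(mass) + 0.5)) * (1 if mass >= 0 else -1)
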