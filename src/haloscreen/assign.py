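"""Candidate elemental-formula enumeration and ranking for observed m/z.

Given an accurate mass and a ppm window, enumerate every ion
composition on a bounded element lattice whose protonated-cation m/z
falls inside the window, filter chemically implausible candidates by
RDBE, and optionally re-rank survivors with an isotope-envelope score.
Default bounds are generous around the halogenated-alkaloid space
(C≤30, H≤40, N≤6, O≤8, Cl≤4, Br≤2) without combinatorial blow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

from .elements import ELECTRON_MASS, monoisotopic_mass_of
from .formula import Formula, ppm_error, rdbe
from .isotopes import IsotopePattern, pattern_similarity, simulate_pattern

__all__ = ["ElementBounds", "CandidateAssignment", "enumerate_formulas", "rerank_with_isotopes"]


@dataclass(frozen=True)
class ElementBounds:
    """Per-element count ranges plus RDBE constraints for the search.

    ``integer_rdbe`` enforces whole-number RDBE on the neutralized
    formula — correct for even-electron [M+H]+ ions; radical fragment
    species (handled by the MS/MS annotator) are exempt.
    """

    bounds: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: {
            "C": (0, 30),
            "H": (0, 40),
            "N": (0, 6),
            "O": (0, 8),
            "Cl": (0, 4),
            "Br": (0, 2),
        }
    )
    rdbe_min: float = 0.0
    rdbe_max: float = 25.0
    integer_rdbe: bool = True

    def __post_init__(self) -> None:
        for el, (lo, hi) in self.bounds.items():
            monoisotopic_mass_of(el)  # validates symbol
            if lo < 0 or hi < lo:
                raise ValueError(f"invalid bounds for {el}: ({lo}, {hi})")

    def lattice_size(self) -> int:
        n = 1
        for lo, hi in self.bounds.values():
            n *= hi - lo + 1
        return n


@dataclass(frozen=True)
class CandidateAssignment:
    """One candidate ion composition for an observed m/z."""

    ion: Formula  # full ion composition at +1, e.g. C16H16O2N2Cl for [M+H]+
    mz_theoretical: float
    ppm: float
    rdbe: float
    iso_score: Optional[float] = None
    rank_score: Optional[float] = None

    @property
    def halogen_count(self) -> int:
        return self.ion["Cl"] + self.ion["Br"]

    def sort_key(self) -> Tuple[float, int, str]:
        return (abs(self.ppm), self.halogen_count, self.ion.to_string())


def enumerate_formulas(
    mz: float,
    window_ppm: float = 5.0,
    bounds: Optional[ElementBounds] = None,
) -> List[CandidateAssignment]:
    """All bounded-lattice ion formulas whose +1 m/z is within the window.

    A depth-first search over element counts with running min/max
    residual-mass pruning makes the default ~1.2M-point lattice cheap.
    Results are sorted by |ppm|, then fewer halogens, then formula
    string — a total, deterministic order.
    """
    if mz <= 0:
        raise ValueError("m/z must be positive")
    if window_ppm <= 0:
        raise ValueError("window_ppm must be positive")
    b = bounds or ElementBounds()

    target = mz + ELECTRON_MASS  # composition mass of the cation
    lo_mass = target * (1 - window_ppm * 1e-6)
    hi_mass = target * (1 + window_ppm * 1e-6)

    # Heavy elements first shrinks the search tree fastest.
    order = sorted(b.bounds.items(), key=lambda kv: -monoisotopic_mass_of(kv[0]))
    masses = [monoisotopic_mass_of(el) for el, _ in order]
    # min/max achievable mass from level i onward
    n = len(order)
    min_rest = [0.0] * (n + 1)
    max_rest = [0.0] * (n + 1)
    for i in range(n - 1, -1, -1):
        lo_c, hi_c = order[i][1]
        min_rest[i] = min_rest[i + 1] + masses[i] * lo_c
        max_rest[i] = max_rest[i + 1] + masses[i] * hi_c

    out: List[CandidateAssignment] = []
    counts: Dict[str, int] = {}

    def dfs(i: int, mass: float) -> None:
        if mass + min_rest[i] > hi_mass or mass + max_rest[i] < lo_mass:
            return
        if i == n:
            if not counts:
                return
            ion = Formula({el: c for el, c in counts.items() if c > 0}, 1)
            if ion["H"] < 1:
                return  # protonated species must carry the extra H
            r = rdbe(ion)
            if not (b.rdbe_min <= r <= b.rdbe_max):
                return
            if b.integer_rdbe and abs(r - round(r)) > 1e-9:
                return
            mz_theo = ion.mz()
            p = ppm_error(mz, mz_theo)
            if abs(p) <= window_ppm:
                out.append(CandidateAssignment(ion, mz_theo, p, r))
            return
        el, (lo_c, hi_c) = order[i]
        m_el = masses[i]
        for c in range(lo_c, hi_c + 1):
            new_mass = mass + m_el * c
            if new_mass + min_rest[i + 1] > hi_mass:
                break
            counts[el] = c
            dfs(i + 1, new_mass)
        counts.pop(el, None)

    dfs(0, 0.0)
    out.sort(key=CandidateAssignment.sort_key)
    return out


def rerank_with_isotopes(
    candidates: List[CandidateAssignment],
    observed: Optional[IsotopePattern],
    window_ppm: float = 5.0,
    w_mass: float = 0.4,
    w_iso: float = 0.6,
) -> List[CandidateAssignment]:
    """Stable re-sort of candidates by mass-accuracy + envelope score.

    Combined score is ``w_mass·(1 − |ppm|/window) + w_iso·similarity``;
    the similarity term compares each candidate's simulated envelope
    with the observed one.  With no observed envelope the input order
    is returned unchanged (flagged by leaving iso_score unset).
    """
    if observed is None or len(observed) == 0:
        return list(candidates)
    out = []
    for cand in candidates:
        theo = simulate_pattern(cand.ion, charge=1)
        iso = pattern_similarity(observed, theo)
        combined = w_mass * (1.0 - min(abs(cand.ppm) / window_ppm, 1.0)) + w_iso * iso
        out.append(replace(cand, iso_score=iso, rank_score=combined))
    out.sort(key=lambda c: (-c.rank_score, c.sort_key()))
    return out
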