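"""Full-scan screening: substitution-series linking, library
dereplication and epimer assignment.

Co-produced halogenated congeners differ by characteristic exact-mass
deltas — Cl-for-H (+33.9610 Da), Br-for-H (+77.9105 Da) and Br-for-Cl
(+43.9495 Da); nominal 34, 78 and 44 Da — so an all-pairs delta scan
over a feature list links a halogen-substitution family even when some
members match nothing in the library.  Dereplication proper matches
each feature's m/z against library [M+H]+ masses within a ppm window;
epimer pairs of one composition are labelled by reversed-phase elution
order (A before B).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .elements import monoisotopic_mass_of
from .formula import ppm_error
from .isotopes import IsotopePattern
from .library import LibraryEntry

__all__ = [
    "Feature",
    "SubstitutionDelta",
    "SeriesLink",
    "LibraryMatch",
    "SUBSTITUTION_DELTAS",
    "link_series",
    "dereplicate",
    "assign_epimers",
]


@dataclass(frozen=True)
class Feature:
    """One full-scan ion: retention time, m/z, intensity, optional envelope."""

    rt_min: float
    mz: float
    intensity: float
    envelope: Optional[IsotopePattern] = None
    msms_id: Optional[str] = None
    feature_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("feature m/z must be positive")
        if self.rt_min < 0:
            raise ValueError("retention time must be non-negative")


@dataclass(frozen=True)
class SubstitutionDelta:
    """A named halogen-substitution exact-mass delta."""

    name: str
    exact_da: float
    nominal_da: int


def _substitution_deltas() -> Tuple[SubstitutionDelta, ...]:
    """Deltas derived from the element table, never hard-coded twice."""
    m_h = monoisotopic_mass_of("H")
    m_cl = monoisotopic_mass_of("Cl")
    m_br = monoisotopic_mass_of("Br")
    return (
        SubstitutionDelta("Cl-for-H", m_cl - m_h, 34),
        SubstitutionDelta("Br-for-Cl", m_br - m_cl, 44),
        SubstitutionDelta("Br-for-H", m_br - m_h, 78),
    )


SUBSTITUTION_DELTAS: Tuple[SubstitutionDelta, ...] = _substitution_deltas()


@dataclass(frozen=True)
class SeriesLink:
    """A feature pair whose m/z difference matches a substitution delta."""

    light: Feature
    heavy: Feature
    delta: SubstitutionDelta
    observed_delta: float
    error_mda: float


def link_series(
    features: Sequence[Feature],
    delta_tol_mda: float = 3.0,
) -> List[SeriesLink]:
    """All-pairs scan for halogen-substitution mass differences.

    Every ordered pair (lighter, heavier) whose m/z difference matches
    one of the three substitution deltas within ``delta_tol_mda``
    (default 3 mDa, roomy because two measured masses contribute
    error) yields a link.  Output order is deterministic: sorted by
    (light m/z, heavy m/z, delta name).
    """
    links: List[SeriesLink] = []
    feats = sorted(features, key=lambda f: (f.mz, f.rt_min))
    for i, lo in enumerate(feats):
        for hi in feats[i + 1 :]:
            obs = hi.mz - lo.mz
            if obs <= 0:
                continue
            for delta in SUBSTITUTION_DELTAS:
                err_mda = (obs - delta.exact_da) * 1e3
                if abs(err_mda) <= delta_tol_mda:
                    links.append(SeriesLink(lo, hi, delta, obs, err_mda))
    links.sort(key=lambda l: (l.light.mz, l.heavy.mz, l.delta.name))
    return links


@dataclass(frozen=True)
class LibraryMatch:
    """Dereplication result for one feature."""

    feature: Feature
    entries: Tuple[LibraryEntry, ...]  # empty => unknown
    ppm_errors: Tuple[float, ...]

    @property
    def is_unknown(self) -> bool:
        return not self.entries


class LibraryRowError(ValueError):
    """A library row failed to parse; carries the 1-based row number."""

    def __init__(self, row: int, message: str):
        super().__init__(f"library row {row}: {message}")
        self.row = row


def dereplicate(
    features: Sequence[Feature],
    library: Sequence[LibraryEntry],
    window_ppm: float = 5.0,
) -> List[LibraryMatch]:
    """Match features against library [M+H]+ masses within ±window_ppm.

    Every entry within the window is reported (epimer pairs share one
    composition, so a feature typically matches both the A and B
    entries of a pair — elution order disambiguates them later).
    Features matching nothing are flagged unknown; they are the
    discovery shortlist.
    """
    if not library:
        raise ValueError("library must be non-empty")
    theo = [(e, e.mz_protonated) for e in library]
    out: List[LibraryMatch] = []
    for f in features:
        hits = []
        errs = []
        for entry, mz_t in theo:
            p = ppm_error(f.mz, mz_t)
            if abs(p) <= window_ppm:
                hits.append(entry)
                errs.append(p)
        out.append(LibraryMatch(f, tuple(hits), tuple(errs)))
    return out


def assign_epimers(
    isobaric_features: Sequence[Feature],
) -> Dict[str, str]:
    """Label a co-matched epimer pair by elution order: earlier RT → A.

    The rule applies only to exactly two features of one composition
    with distinct retention times; any other multiplicity (or an RT
    tie) returns every feature as "undetermined".  Keys are feature
    ids (or ``rt:mz`` strings when ids are absent).
    """

    def key(f: Feature) -> str:
        return f.feature_id or f"{f.rt_min:.3f}:{f.mz:.4f}"

    feats = list(isobaric_features)
    if len(feats) != 2:
        if len(feats) > 2:
            warnings.warn(
                f"{len(feats)} isobaric features; epimer rule needs exactly 2",
                stacklevel=2,
            )
        return {key(f): "undetermined" for f in feats}
    a, b = sorted(feats, key=lambda f: f.rt_min)
    if a.rt_min == b.rt_min:
        warnings.warn("identical retention times; epimer order undetermined", stacklevel=2)
        return {key(a): "undetermined", key(b): "undetermined"}
    return {key(a): "A", key(b): "B"}
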