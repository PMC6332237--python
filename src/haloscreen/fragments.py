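"""MS/MS product-ion annotation as radical/neutral losses and species
classes for the rugulovasine scaffold.

Protonated halogenated rugulovasines fragment along a small, regular
loss grammar at 25 eV:

* class I  — halogen *radical* loss (Cl• or Br•), an odd-electron ion;
* class II — hydrogen-halide loss (HCl or HBr), even-electron;
* class III — II plus water;
* class IV — III plus CO (ring contraction to a new indole);
* class V  — retro-Diels–Alder cleavage of the spiro system yielding
  the C7H10O2N+ oxocarbenium, observed only for B epimers, whose ring
  conformation permits the concerted cleavage.  Presence of V is
  therefore an epimer diagnostic; its absence is not proof of an A
  epimer (absence of evidence), and is reported as such.

The annotator searches loss multisets breadth-first (minimal depth
wins), checks element conservation on every annotation, and tracks
electron parity: each radical loss flips the ion between even- and
odd-electron states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations_with_replacement
from typing import Dict, List, Optional, Sequence, Tuple

from .formula import Formula, parse_formula, ppm_error

__all__ = [
    "Loss",
    "LOSS_CATALOG",
    "RDA_ION",
    "FragmentAnnotation",
    "annotate_products",
    "assign_species_class",
    "epimer_diagnostic",
]


@dataclass(frozen=True)
class Loss:
    """A named neutral or radical loss."""

    name: str
    composition: Formula
    radical: bool = False  # radical loss flips the product ion's electron parity
    max_multiplicity: int = 1


#: The loss grammar of the rugulovasine series.  Water may leave twice;
#: every other loss at most once per pathway.
LOSS_CATALOG: Tuple[Loss, ...] = (
    Loss("Cl", parse_formula("Cl"), radical=True),
    Loss("HCl", parse_formula("HCl")),
    Loss("Br", parse_formula("Br"), radical=True),
    Loss("HBr", parse_formula("HBr")),
    Loss("H2O", parse_formula("H2O"), max_multiplicity=2),
    Loss("CO", parse_formula("CO")),
)

#: The retro-Diels–Alder diagnostic ion.  Its neutral complement is
#: *computed* per precursor (precursor − C7H10O2N, element-wise), so one
#: rule covers the C9H7N / C9H6NCl / C9H5NCl2 complements of the whole
#: series without cataloguing each.
RDA_ION: Formula = parse_formula("C7H10O2N", 1)


@dataclass(frozen=True)
class FragmentAnnotation:
    """One annotated product ion."""

    mz_observed: float
    ion: Optional[Formula]  # matched product composition (+1), None if unassigned
    losses: Tuple[str, ...]  # loss names, catalog order; ("RDA",) for class V
    species_class: str  # "I".."V", "precursor", "unassigned", "impossible"
    ppm: Optional[float] = None
    intensity: Optional[float] = None
    odd_electron: bool = False
    collision_energy_ev: Optional[float] = None

    @property
    def assigned(self) -> bool:
        return self.ion is not None


def assign_species_class(losses: Sequence[str]) -> str:
    """Deterministic loss-multiset → species-class mapping.

    Multisets outside the scheme (e.g. a lone water loss) map to
    "unassigned"; the empty multiset is the surviving precursor.
    """
    bag = sorted(losses)
    if bag == ["RDA"]:
        return "V"
    if not bag:
        return "precursor"
    radical_halogen = [l for l in bag if l in ("Cl", "Br")]
    hx = [l for l in bag if l in ("HCl", "HBr")]
    rest = [l for l in bag if l not in ("Cl", "Br", "HCl", "HBr")]
    if radical_halogen and not hx and not rest and len(radical_halogen) == 1:
        return "I"
    if len(hx) == 1 and not radical_halogen:
        if not rest:
            return "II"
        if rest == ["H2O"]:
            return "III"
        if rest == ["CO", "H2O"]:
            return "IV"
    return "unassigned"


def _loss_multisets(max_depth: int) -> List[List[Tuple[Loss, ...]]]:
    """Loss multisets grouped by depth 0..max_depth, honouring caps."""
    by_depth: List[List[Tuple[Loss, ...]]] = [[()]]
    for depth in range(1, max_depth + 1):
        level = []
        for combo in combinations_with_replacement(LOSS_CATALOG, depth):
            ok = all(combo.count(l) <= l.max_multiplicity for l in set(combo))
            if ok:
                level.append(combo)
        by_depth.append(level)
    return by_depth


def annotate_products(
    precursor: Formula,
    products: Sequence[Tuple[float, float]],
    max_depth: int = 3,
    tol_ppm: float = 5.0,
    collision_energy_ev: Optional[float] = None,
) -> List[FragmentAnnotation]:
    """Annotate product ions of one precursor as sequential losses.

    For each (m/z, intensity) product the minimal-depth loss multiset
    whose residual ion matches within ``tol_ppm`` is chosen; at equal
    depth, multisets without radical losses win, then lower |ppm|.
    The retro-Diels–Alder channel is tested as a depth-1 alternative
    whenever the precursor contains C7H10O2N.  Element conservation
    (precursor == product + losses) holds for every annotation by
    construction and is re-asserted.  Products heavier than the
    precursor (beyond tolerance) are flagged impossible.
    """
    if precursor.charge != 1:
        raise ValueError("precursor must be a +1 cation composition")
    if not products:
        raise ValueError("product list must be non-empty")

    prec_mz = precursor.mz()
    levels = _loss_multisets(max_depth)
    rda_feasible = precursor.contains(Formula(dict(RDA_ION.counts)))
    rda_mz = RDA_ION.mz()

    out: List[FragmentAnnotation] = []
    for mz_obs, inten in products:
        if mz_obs > prec_mz * (1 + tol_ppm * 1e-6):
            out.append(
                FragmentAnnotation(
                    mz_obs, None, (), "impossible", None, inten,
                    collision_energy_ev=collision_energy_ev,
                )
            )
            continue
        chosen: Optional[FragmentAnnotation] = None
        for depth, combos in enumerate(levels):
            candidates: List[Tuple[int, float, FragmentAnnotation]] = []
            for combo in combos:
                try:
                    ion = precursor
                    for loss in combo:
                        ion = ion - loss.composition
                except ValueError:
                    continue
                if not ion:
                    continue
                p = ppm_error(mz_obs, ion.mz())
                if abs(p) > tol_ppm:
                    continue
                names = tuple(l.name for l in combo)
                n_rad = sum(1 for l in combo if l.radical)
                ann = FragmentAnnotation(
                    mz_obs,
                    ion,
                    names,
                    assign_species_class(names),
                    p,
                    inten,
                    odd_electron=(n_rad % 2 == 1),
                    collision_energy_ev=collision_energy_ev,
                )
                candidates.append((n_rad, abs(p), ann))
            if depth == 1 and rda_feasible:
                p = ppm_error(mz_obs, rda_mz)
                if abs(p) <= tol_ppm:
                    ann = FragmentAnnotation(
                        mz_obs, RDA_ION, ("RDA",), "V", p, inten,
                        collision_energy_ev=collision_energy_ev,
                    )
                    candidates.append((0, abs(p), ann))
            if candidates:
                candidates.sort(key=lambda t: (t[0], t[1]))
                chosen = candidates[0][2]
                break
        if chosen is None:
            chosen = FragmentAnnotation(
                mz_obs, None, (), "unassigned", None, inten,
                collision_energy_ev=collision_energy_ev,
            )
        else:
            _assert_conservation(precursor, chosen)
        out.append(chosen)
    return out


def _assert_conservation(precursor: Formula, ann: FragmentAnnotation) -> None:
    """precursor == product + Σ losses, element-wise."""
    total = Formula(dict(ann.ion.counts))
    if ann.losses == ("RDA",):
        complement = Formula(dict(precursor.counts)) - Formula(dict(RDA_ION.counts))
        total = total + complement
    else:
        by_name = {l.name: l for l in LOSS_CATALOG}
        for name in ann.losses:
            total = total + by_name[name].composition
    if dict(total.counts) != dict(precursor.counts):
        raise AssertionError(
            f"element conservation violated: {precursor!r} != {total!r} "
            f"for losses {ann.losses}"
        )


def epimer_diagnostic(annotations: Sequence[FragmentAnnotation]) -> str:
    """Epimer call from annotated MS/MS: class V present → "B-type".

    Without a V ion the spectrum is consistent with an A epimer *or*
    with a B spectrum in which the channel fell below detection, so the
    call is "A-type-or-undetermined"; an empty annotation list is
    simply "undetermined".
    """
    anns = list(annotations)
    if not anns:
        return "undetermined"
    if any(a.species_class == "V" for a in anns):
        return "B-type"
    return "A-type-or-undetermined"
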