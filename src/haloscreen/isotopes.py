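"""Isotope envelope simulation and halogen-count inference.

Chlorine and bromine have heavy isotopes two mass units above the light
one at high abundance (37Cl/35Cl ≈ 0.32, 81Br/79Br ≈ 0.97), so the
relative height of the A+2 (and A+4) isotopologue peaks is a direct
fingerprint of the halogen content of an ion.  This module computes
theoretical envelopes by exact per-element multinomial expansion and
cross-element convolution, compares envelopes with a peak-matched
cosine score, and classifies the (nCl, nBr) content of an observed
envelope by scoring it against simulated halogenation hypotheses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .elements import ELECTRON_MASS, isotope_distribution_of, monoisotopic_mass_of
from .formula import Formula

__all__ = [
    "IsotopePattern",
    "HalogenCall",
    "simulate_pattern",
    "pattern_similarity",
    "classify_halogens",
]

#: Default centroid aggregation width in Da.  Fine structure closer than
#: this collapses into one centroid, matching the ~50k-FWHM QTOF regime
#: where isotopologues differing by a few mDa are not resolved.
DEFAULT_AGGREGATION_WIDTH = 0.02

#: Isotopologues are dropped from the tail of the envelope only while the
#: total dropped abundance stays below this fraction of the whole.
TRUNCATION_MASS_FRACTION = 1e-4

# Pruning threshold for intermediate convolution terms (absolute probability).
_PRUNE = 1e-12


@dataclass(frozen=True)
class IsotopePattern:
    """Centroided isotope envelope: (m/z, relative abundance) peaks.

    Peaks are sorted by increasing m/z, abundances are scaled so the
    base peak is exactly 100.  ``formula``/``charge`` record provenance
    when the pattern was simulated (None for observed envelopes).
    """

    peaks: Tuple[Tuple[float, float], ...]
    formula: Optional[Formula] = None
    charge: int = 1

    def __post_init__(self) -> None:
        pk = tuple((float(m), float(a)) for m, a in self.peaks)
        object.__setattr__(self, "peaks", pk)
        if pk:
            mzs = [m for m, _ in pk]
            if any(b <= a for a, b in zip(mzs, mzs[1:])):
                raise ValueError("pattern m/z values must be strictly increasing")
            if not math.isclose(max(a for _, a in pk), 100.0, abs_tol=1e-9):
                raise ValueError("base peak abundance must equal 100")

    def __len__(self) -> int:
        return len(self.peaks)

    @property
    def mz(self) -> Tuple[float, ...]:
        return tuple(m for m, _ in self.peaks)

    @property
    def abundance(self) -> Tuple[float, ...]:
        return tuple(a for _, a in self.peaks)

    @property
    def base_mz(self) -> float:
        """m/z of the most abundant peak."""
        return max(self.peaks, key=lambda p: p[1])[0]

    @property
    def monoisotopic_mz(self) -> float:
        """m/z of the lightest retained peak (the A peak for CHNOClBr ions)."""
        return self.peaks[0][0]

    def to_rows(self) -> List[Tuple[float, float]]:
        return list(self.peaks)

    @classmethod
    def from_rows(cls, rows: Sequence[Tuple[float, float]]) -> "IsotopePattern":
        """Build from raw (m/z, abundance) rows, renormalizing to base 100."""
        rows = [(float(m), float(a)) for m, a in rows if a > 0]
        if not rows:
            raise ValueError("empty envelope")
        rows.sort()
        top = max(a for _, a in rows)
        return cls(tuple((m, a / top * 100.0) for m, a in rows))


def _element_distribution(symbol: str, n: int) -> List[Tuple[float, float]]:
    """Exact (mass, probability) distribution of ``n`` atoms of one element.

    Enumerates multinomial isotope compositions; with at most four
    isotopes per element the term count stays tiny even for C30/H40.
    """
    isotopes = isotope_distribution_of(symbol)
    k = len(isotopes)
    if k == 1:
        m, _ = isotopes[0]
        return [(m * n, 1.0)]
    out: List[Tuple[float, float]] = []

    def rec(idx: int, remaining: int, mass: float, logp: float, coef_log: float) -> None:
        if idx == k - 1:
            m, a = isotopes[idx]
            if a == 0.0 and remaining > 0:
                return
            p = math.exp(coef_log - math.lgamma(remaining + 1)) * (
                a**remaining if a > 0 else (1.0 if remaining == 0 else 0.0)
            ) * math.exp(logp)
            if p > _PRUNE:
                out.append((mass + m * remaining, p))
            return
        m, a = isotopes[idx]
        for c in range(remaining + 1):
            if a == 0.0 and c > 0:
                break
            rec(
                idx + 1,
                remaining - c,
                mass + m * c,
                logp + (c * math.log(a) if c else 0.0),
                coef_log - math.lgamma(c + 1),
            )

    rec(0, n, 0.0, 0.0, math.lgamma(n + 1))
    return out


def _convolve(
    a: List[Tuple[float, float]], b: List[Tuple[float, float]]
) -> List[Tuple[float, float]]:
    acc: Dict[int, Tuple[float, float]] = {}
    for ma, pa in a:
        for mb, pb in b:
            p = pa * pb
            if p < _PRUNE:
                continue
            m = ma + mb
            key = round(m * 1e6)  # merge numerically identical fine structure
            if key in acc:
                m0, p0 = acc[key]
                acc[key] = ((m0 * p0 + m * p) / (p0 + p), p0 + p)
            else:
                acc[key] = (m, p)
    return list(acc.values())


def _aggregate(
    peaks: List[Tuple[float, float]], width: float
) -> List[Tuple[float, float]]:
    """Greedy centroiding: merge fine structure within ``width`` Da."""
    peaks = sorted(peaks)
    clusters: List[Tuple[float, float]] = []
    start = None
    msum = 0.0
    psum = 0.0
    for m, p in peaks:
        if start is None or m - start > width:
            if psum > 0:
                clusters.append((msum / psum, psum))
            start, msum, psum = m, 0.0, 0.0
        msum += m * p
        psum += p
    if psum > 0:
        clusters.append((msum / psum, psum))
    return clusters


def simulate_pattern(
    formula: Formula,
    charge: int = 1,
    aggregation_width: float = DEFAULT_AGGREGATION_WIDTH,
    max_shift: Optional[int] = None,
) -> IsotopePattern:
    """Theoretical centroided isotope envelope of an ion composition.

    Parameters
    ----------
    formula:
        The ion composition (the full composition of the charged
        species, e.g. C16H16O2N2Cl for the protonated monochloro ion).
    charge:
        0 for a neutral envelope, +1 for a cation (electron-corrected).
    aggregation_width:
        Centroid merge width in Da; isotopologues closer than this
        collapse into one abundance-weighted peak.
    max_shift:
        If given, additionally drop peaks more than this many nominal
        Da above the monoisotopic peak (e.g. 4 keeps A..A+4).  By
        default the envelope is truncated only by the 1e-4
        dropped-mass-fraction rule.
    """
    if not formula:
        raise ValueError("cannot simulate the empty formula")
    if charge not in (0, 1):
        raise ValueError(f"only charges 0 and +1 are supported, got {charge}")

    dist: List[Tuple[float, float]] = [(0.0, 1.0)]
    for el, n in sorted(formula.counts.items()):
        dist = _convolve(dist, _element_distribution(el, n))

    clusters = _aggregate(dist, aggregation_width)
    total = sum(p for _, p in clusters)

    if max_shift is not None:
        mono = min(m for m, _ in clusters)
        clusters = [(m, p) for m, p in clusters if m - mono < max_shift + 0.5]

    # Drop the least abundant peaks while the cumulative dropped mass
    # fraction stays below the truncation budget.
    clusters.sort(key=lambda c: c[1])
    dropped = 0.0
    keep_from = 0
    for i, (_, p) in enumerate(clusters):
        if dropped + p < TRUNCATION_MASS_FRACTION * total:
            dropped += p
            keep_from = i + 1
        else:
            break
    kept = sorted(clusters[keep_from:])

    if charge == 1:
        kept = [(m - ELECTRON_MASS, p) for m, p in kept]
    base = max(p for _, p in kept)
    peaks = tuple((m, p / base * 100.0) for m, p in kept)
    return IsotopePattern(peaks, formula=formula, charge=charge)


def _match_peaks(
    a: Sequence[Tuple[float, float]],
    b: Sequence[Tuple[float, float]],
    tol_da: float,
) -> List[Tuple[Optional[int], Optional[int]]]:
    """Symmetric one-to-one nearest matching of two sorted peak lists."""
    pairs: List[Tuple[float, int, int]] = []
    for i, (ma, _) in enumerate(a):
        for j, (mb, _) in enumerate(b):
            d = abs(ma - mb)
            if d <= tol_da:
                pairs.append((d, i, j))
    pairs.sort()
    used_a: set = set()
    used_b: set = set()
    matches: List[Tuple[Optional[int], Optional[int]]] = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matches.append((i, j))
    for i in range(len(a)):
        if i not in used_a:
            matches.append((i, None))
    for j in range(len(b)):
        if j not in used_b:
            matches.append((None, j))
    return matches


def pattern_similarity(
    observed: IsotopePattern,
    theoretical: IsotopePattern,
    mz_tol_ppm: float = 150.0,
    align: bool = False,
) -> float:
    """Peak-matched normalized dot product of two envelopes, in [0, 1].

    Each envelope is first normalized to unit total abundance; peaks
    are paired one-to-one by nearest m/z within tolerance and the
    score is ``⟨p,q⟩ / max(⟨p,p⟩, ⟨q,q⟩)``.  The max-norm denominator
    (instead of the cosine's geometric mean) makes the score drop
    sharply when the abundance *distributions* differ — a plain cosine
    is dominated by the base peak and barely separates, say, a
    monobromo from a dichloro envelope.  Unmatched peaks on either
    side enter with a zero partner, so missing or extra peaks lower
    the score.  The measure is symmetric, 1.0 exactly for identical
    envelopes, and 0.0 when no peak pairs at all fall within
    tolerance.

    ``align=True`` first shifts the theoretical envelope so its
    monoisotopic peak coincides with the observed one — useful when the
    hypothesis core is only mass-approximate (halogen classification).
    """
    if len(observed) == 0 or len(theoretical) == 0:
        raise ValueError("patterns must be non-empty")
    obs = list(observed.peaks)
    theo = list(theoretical.peaks)
    if align:
        shift = obs[0][0] - theo[0][0]
        theo = [(m + shift, a) for m, a in theo]
    ref_mz = obs[0][0]
    tol_da = ref_mz * mz_tol_ppm * 1e-6
    matches = _match_peaks(obs, theo, tol_da)
    if all(i is None or j is None for i, j in matches):
        return 0.0
    tot_a = sum(a for _, a in obs)
    tot_b = sum(a for _, a in theo)
    dot = 0.0
    na = 0.0
    nb = 0.0
    for i, j in matches:
        x = obs[i][1] / tot_a if i is not None else 0.0
        y = theo[j][1] / tot_b if j is not None else 0.0
        dot += x * y
        na += x * x
        nb += y * y
    if na == 0.0 or nb == 0.0:
        return 0.0
    return dot / max(na, nb)


@dataclass(frozen=True)
class HalogenCall:
    """Best (nCl, nBr) hypothesis for an observed envelope."""

    n_cl: int
    n_br: int
    score: float
    #: ((nCl, nBr), score) for every scored hypothesis, best first.
    alternatives: Tuple[Tuple[Tuple[int, int], float], ...] = field(default_factory=tuple)
    flag: str = ""

    def __post_init__(self) -> None:
        if self.n_cl < 0 or self.n_br < 0:
            raise ValueError("halogen counts must be non-negative")
        scores = [s for _, s in self.alternatives]
        if any(b > a + 1e-12 for a, b in zip(scores, scores[1:])):
            raise ValueError("alternatives must be sorted by descending score")


def _pseudo_core(target_mass: float) -> Formula:
    """CH composition approximating a target residual composition mass.

    Halogen A+2 signatures dominate the fine CHNO detail of the
    envelope, so a carbon/hydrogen stand-in whose mass lands within
    ~0.5 Da of the true core reproduces the A+1/A+2 shape well enough
    for hypothesis ranking.
    """
    m_c = monoisotopic_mass_of("C")
    m_h = monoisotopic_mass_of("H")
    n_c = max(1, int(target_mass // (m_c + m_h)))
    n_h = max(0, round((target_mass - n_c * m_c) / m_h))
    return Formula({"C": n_c, "H": n_h})


def _even_shift_subpattern(pattern: IsotopePattern) -> Optional[IsotopePattern]:
    """The A, A+2, A+4, ... sub-envelope, renormalized to base 100.

    Heavy-halogen isotopes sit two nucleons up, so the halogen content
    of an ion lives almost entirely in the even-shift peaks; the odd
    A+1/A+3 ladder mostly reflects the carbon count, which a
    mass-matched stand-in core gets only approximately right.
    """
    mono = pattern.monoisotopic_mz
    rows = [
        (m, a)
        for m, a in pattern.peaks
        if abs((m - mono) - 2 * round((m - mono) / 2)) < 0.3
    ]
    if not rows:
        return None
    return IsotopePattern.from_rows(rows)


def classify_halogens(
    observed: IsotopePattern,
    max_cl: int = 2,
    max_br: int = 1,
    core_guess: Optional[Formula] = None,
    tie_margin: float = 1e-3,
) -> HalogenCall:
    """Infer the (nCl, nBr) content of an ion from its isotope envelope.

    Every hypothesis with ``nCl ≤ max_cl`` and ``nBr ≤ max_br`` is
    simulated — on the halogen-substituted ``core_guess`` when one is
    supplied (a neutral halogen-free core; halogens replace hydrogens),
    otherwise on a CH pseudo-core mass-matched to the observed
    monoisotopic peak — and scored against the observed envelope with
    :func:`pattern_similarity` restricted to the even-shift (A, A+2,
    A+4) sub-envelope, where the halogen signature lives and where an
    approximate core costs nothing.  Hypotheses within ``tie_margin``
    of the best score are resolved in favour of fewer total halogen
    atoms.
    """
    if len(observed) < 2:
        return HalogenCall(0, 0, 0.0, (((0, 0), 0.0),), flag="insufficient envelope")

    obs_ion_mass = observed.monoisotopic_mz + ELECTRON_MASS
    obs_even = _even_shift_subpattern(observed)
    if obs_even is None or len(obs_even) < 1:
        return HalogenCall(0, 0, 0.0, (((0, 0), 0.0),), flag="insufficient envelope")
    scored: List[Tuple[Tuple[int, int], float]] = []
    for n_cl in range(max_cl + 1):
        for n_br in range(max_br + 1):
            if core_guess is not None:
                n_sub = n_cl + n_br
                if core_guess["H"] < n_sub + 1:
                    continue
                counts = dict(core_guess.counts)
                counts["H"] = counts["H"] - n_sub + 1  # substitute, then protonate
                if n_cl:
                    counts["Cl"] = counts.get("Cl", 0) + n_cl
                if n_br:
                    counts["Br"] = counts.get("Br", 0) + n_br
                hyp = Formula(counts, 1)
            else:
                rem = (
                    obs_ion_mass
                    - n_cl * monoisotopic_mass_of("Cl")
                    - n_br * monoisotopic_mass_of("Br")
                )
                if rem <= 1.0:
                    continue
                core = _pseudo_core(rem)
                counts = dict(core.counts)
                if n_cl:
                    counts["Cl"] = n_cl
                if n_br:
                    counts["Br"] = n_br
                hyp = Formula(counts, 1)
            theo_even = _even_shift_subpattern(simulate_pattern(hyp))
            if theo_even is None:
                continue
            score = pattern_similarity(obs_even, theo_even, align=True)
            scored.append(((n_cl, n_br), score))

    if not scored:
        return HalogenCall(0, 0, 0.0, (((0, 0), 0.0),), flag="no feasible hypothesis")

    # Sort by score desc; near-ties prefer fewer halogens (then fewer Br).
    scored.sort(key=lambda t: (-t[1], t[0][0] + t[0][1], t[0][1], t[0][0]))
    best_score = scored[0][1]
    tied = [t for t in scored if best_score - t[1] < tie_margin]
    tied.sort(key=lambda t: (t[0][0] + t[0][1], t[0][1], t[0][0]))
    (n_cl, n_br), score = tied[0]
    ordered = tuple(sorted(scored, key=lambda t: -t[1]))
    return HalogenCall(n_cl, n_br, score, ordered)
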