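"""Isotope envelope simulation, similarity metric and halogen calls."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from haloscreen.elements import ELECTRON_MASS, isotope_distribution_of
from haloscreen.formula import Formula, parse_formula
from haloscreen.isotopes import (
    IsotopePattern,
    TRUNCATION_MASS_FRACTION,
    classify_halogens,
    pattern_similarity,
    simulate_pattern,
)

# ---------------------------------------------------------------------------
# independent oracle: exhaustive per-atom isotopologue enumeration
# ---------------------------------------------------------------------------


def exhaustive_pattern(formula: Formula, width: float = 0.02):
    """Brute-force envelope by enumerating every atom's isotope choice.

    Feasible only for small formulas (≤ 8 atoms); aggregates raw
    isotopologues into centroids by sorting and greedy clustering —
    written independently of the convolution implementation.
    """
    atoms = []
    for el, n in sorted(formula.counts.items()):
        atoms.extend([isotope_distribution_of(el)] * n)
    assert len(atoms) <= 8, "oracle is exponential; keep it tiny"
    raw = {}
    for combo in itertools.product(*atoms):
        mass = sum(m for m, _ in combo)
        prob = math.prod(a for _, a in combo)
        key = round(mass, 6)
        raw[key] = raw.get(key, 0.0) + prob
    peaks = sorted(raw.items())
    clusters = []
    cur_m, cur_p, start = 0.0, 0.0, None
    for m, p in peaks:
        if start is None or m - start > width:
            if cur_p:
                clusters.append((cur_m / cur_p, cur_p))
            start, cur_m, cur_p = m, 0.0, 0.0
        cur_m += m * p
        cur_p += p
    if cur_p:
        clusters.append((cur_m / cur_p, cur_p))
    return clusters


@pytest.mark.parametrize(
    "formula",
    ["H2O", "CH4", "Cl2", "Br2", "C2H3Cl", "SO2", "C2H2Br2", "C4HCl3", "K2O", "C2H2NOP"],
)
def test_simulator_matches_exhaustive_enumeration(formula):
    """Convolution equals the brute-force oracle within 1e-6 abundance."""
    f = parse_formula(formula)
    oracle = exhaustive_pattern(f)
    total = sum(p for _, p in oracle)
    pattern = simulate_pattern(f, charge=0)
    base = max(p for _, p in oracle)
    matched_oracle = set()
    for mz, ab in pattern.peaks:
        hits = [i for i, (m, _) in enumerate(oracle) if abs(m - mz) < 0.01]
        assert len(hits) == 1, f"no unique oracle peak for {mz}"
        i = hits[0]
        matched_oracle.add(i)
        assert ab / 100.0 == pytest.approx(oracle[i][1] / base, abs=1e-6)
        assert mz == pytest.approx(oracle[i][0], abs=1e-6)
    dropped = sum(p for i, (_, p) in enumerate(oracle) if i not in matched_oracle)
    assert dropped < TRUNCATION_MASS_FRACTION * total


def test_charged_pattern_shifts_by_electron_mass():
    neutral = simulate_pattern(parse_formula("C2H3Cl"), charge=0)
    cation = simulate_pattern(parse_formula("C2H3Cl"), charge=1)
    for (m0, a0), (m1, a1) in zip(neutral.peaks, cation.peaks):
        assert m0 - m1 == pytest.approx(ELECTRON_MASS, abs=1e-12)
        assert a0 == pytest.approx(a1)


def test_single_monoisotopic_atom_gives_single_peak():
    pattern = simulate_pattern(parse_formula("P"), charge=0)
    assert len(pattern) == 1
    assert pattern.peaks[0][1] == 100.0


# ---------------------------------------------------------------------------
# halogen signatures of the alkaloid ions
# ---------------------------------------------------------------------------


def a2_over_a(pattern: IsotopePattern) -> float:
    a_mz, a_ab = pattern.peaks[0]
    hits = [ab for m, ab in pattern.peaks if abs(m - a_mz - 2.0) < 0.3]
    return hits[0] / a_ab if hits else 0.0


def test_monochloro_a2_ratio():
    p = simulate_pattern(parse_formula("C16H16O2N2Cl", 1))
    assert a2_over_a(p) == pytest.approx(0.35, abs=0.02)


def test_dichloro_a2_ratio_and_visible_a4():
    p = simulate_pattern(parse_formula("C16H15O2N2Cl2", 1))
    assert a2_over_a(p) == pytest.approx(0.67, abs=0.02)
    a_mz = p.peaks[0][0]
    a4 = [ab for m, ab in p.peaks if abs(m - a_mz - 4.0) < 0.3]
    assert a4 and a4[0] > 5.0  # A+4 clearly visible for two chlorines


def test_a2_ratio_strictly_increases_with_chlorine_count():
    ratios = []
    for formula in ["C16H17O2N2", "C16H16O2N2Cl", "C16H15O2N2Cl2", "C16H14O2N2Cl3"]:
        ratios.append(a2_over_a(simulate_pattern(parse_formula(formula, 1))))
    assert all(b > a for a, b in zip(ratios, ratios[1:]))


def test_pattern_invariants():
    p = simulate_pattern(parse_formula("C16H15O2N2Cl2", 1))
    mzs = p.mz
    assert all(b > a for a, b in zip(mzs, mzs[1:]))
    assert max(p.abundance) == 100.0
    assert sum(1 for a in p.abundance if a == 100.0) == 1
    assert all(0 < a <= 100 for a in p.abundance)


def test_element_insertion_order_is_irrelevant():
    a = simulate_pattern(Formula({"C": 16, "H": 15, "O": 2, "N": 2, "Cl": 2}, 1))
    b = simulate_pattern(Formula({"Cl": 2, "N": 2, "O": 2, "H": 15, "C": 16}, 1))
    assert a.peaks == b.peaks


def test_max_shift_caps_envelope_depth():
    p = simulate_pattern(parse_formula("C16H15O2N2Cl2", 1), max_shift=4)
    assert p.peaks[-1][0] - p.peaks[0][0] < 4.5


# ---------------------------------------------------------------------------
# similarity metric
# ---------------------------------------------------------------------------


def test_similarity_identity_and_symmetry():
    cl2 = simulate_pattern(parse_formula("C16H15O2N2Cl2", 1))
    br1 = simulate_pattern(parse_formula("C16H16O2N2Br", 1))
    assert pattern_similarity(cl2, cl2) == 1.0
    s_ab = pattern_similarity(cl2, br1, align=True)
    s_ba = pattern_similarity(br1, cl2, align=True)
    assert s_ab == pytest.approx(s_ba, abs=1e-9)


def test_similarity_separates_dichloro_from_halogen_free():
    cl2 = simulate_pattern(parse_formula("C16H15O2N2Cl2", 1))
    cl0 = simulate_pattern(parse_formula("C16H17O2N2", 1))
    assert pattern_similarity(cl2, cl0, align=True) < 0.8


def test_similarity_robust_to_small_abundance_jitter():
    br1 = simulate_pattern(parse_formula("C16H16O2N2Br", 1))
    rng = np.random.default_rng(7)
    jittered = IsotopePattern.from_rows(
        [(m, a * float(np.exp(rng.normal(0, 0.01)))) for m, a in br1.peaks]
    )
    assert pattern_similarity(jittered, br1) > 0.98


def test_similarity_zero_when_nothing_matches():
    a = simulate_pattern(parse_formula("C16H15O2N2Cl2", 1))
    b = simulate_pattern(parse_formula("H2O", 1))
    assert pattern_similarity(a, b) == 0.0


# ---------------------------------------------------------------------------
# halogen classification
# ---------------------------------------------------------------------------

HALOGEN_HYPOTHESES = {
    "C16H17O2N2": (0, 0),
    "C16H16O2N2Cl": (1, 0),
    "C16H15O2N2Cl2": (2, 0),
    "C16H16O2N2Br": (0, 1),
    "C16H15O2N2ClBr": (1, 1),
    "C16H14O2N2Cl2Br": (2, 1),
}


@pytest.mark.parametrize("formula,expected", sorted(HALOGEN_HYPOTHESES.items()))
def test_classifier_confusion_matrix_is_identity(formula, expected):
    """Noise-free envelopes of every (nCl≤2, nBr≤1) hypothesis classify correctly."""
    call = classify_halogens(simulate_pattern(parse_formula(formula, 1)))
    assert (call.n_cl, call.n_br) == expected
    assert call.flag == ""
    scores = [s for _, s in call.alternatives]
    assert scores == sorted(scores, reverse=True)


def test_classifier_with_known_core():
    obs = simulate_pattern(parse_formula("C16H15O2N2Cl2", 1))
    call = classify_halogens(obs, core_guess=parse_formula("C16H16N2O2"))
    assert (call.n_cl, call.n_br) == (2, 0)
    assert call.score > 0.999  # exact core beats the CH stand-in


def test_classifier_single_peak_is_insufficient():
    single = IsotopePattern(((303.0894, 100.0),))
    call = classify_halogens(single)
    assert (call.n_cl, call.n_br) == (0, 0)
    assert call.flag == "insufficient envelope"
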