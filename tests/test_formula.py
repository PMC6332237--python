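"""Formula parsing, mass arithmetic, RDBE and differencing."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haloscreen.elements import ELECTRON_MASS, ISOTOPES
from haloscreen.formula import (
    Formula,
    FormulaParseError,
    formula_difference,
    monoisotopic_mz,
    nominal_mass,
    parse_formula,
    ppm_error,
    rdbe,
)

# ---------------------------------------------------------------------------
# element table sanity: cross-check against the pyteomics NIST table
# ---------------------------------------------------------------------------


def test_element_table_matches_pyteomics_nist():
    """Embedded isotope masses/abundances agree with an independent source."""
    from pyteomics import mass as pyt_mass

    for symbol, isotopes in ISOTOPES.items():
        nist = pyt_mass.nist_mass[symbol]
        for nominal, m, ab in isotopes:
            ref_m, ref_ab = nist[nominal]
            assert m == pytest.approx(ref_m, abs=5e-5), (symbol, nominal)
            assert ab == pytest.approx(ref_ab, abs=2e-3), (symbol, nominal)
    assert ELECTRON_MASS == pytest.approx(5.486e-4, abs=1e-6)


def test_abundances_sum_to_one_and_masses_increase():
    for symbol, isotopes in ISOTOPES.items():
        assert sum(a for _, _, a in isotopes) == pytest.approx(1.0, abs=1e-6), symbol
        masses = [m for _, m, _ in isotopes]
        assert masses == sorted(masses) and len(set(masses)) == len(masses)


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "text,expected",
    [
        ("C16H15O2N2Cl2", {"C": 16, "H": 15, "O": 2, "N": 2, "Cl": 2}),
        ("H2O", {"H": 2, "O": 1}),
        ("C7H10O2N", {"C": 7, "H": 10, "O": 2, "N": 1}),
        ("CHBrClNa", {"C": 1, "H": 1, "Br": 1, "Cl": 1, "Na": 1}),
        ("O2N2C16H16", {"C": 16, "H": 16, "O": 2, "N": 2}),  # order-free
    ],
)
def test_parse_formula(text, expected):
    assert dict(parse_formula(text).counts) == expected


@pytest.mark.parametrize("bad", ["", "  ", "C16X2", "c16", "H2O+", "C0", "2H"])
def test_parse_rejects_malformed(bad):
    with pytest.raises(FormulaParseError):
        parse_formula(bad)


@given(
    st.dictionaries(
        st.sampled_from(sorted(ISOTOPES)),
        st.integers(min_value=1, max_value=40),
        min_size=1,
        max_size=6,
    )
)
@settings(max_examples=200, deadline=None)
def test_parse_format_round_trip(counts):
    f = Formula(counts)
    assert parse_formula(f.to_string()) == f


# ---------------------------------------------------------------------------
# masses
# ---------------------------------------------------------------------------


def test_protonated_rugulovasine_matches_reported_mass(rugulovasine_ion):
    mz = monoisotopic_mz(rugulovasine_ion)
    assert abs(ppm_error(269.1284, mz)) <= 1.5


def test_water_neutral_mass():
    assert monoisotopic_mz(parse_formula("H2O")) == pytest.approx(18.0106, abs=1e-4)


def test_empty_formula():
    assert monoisotopic_mz(Formula()) == 0.0
    with pytest.raises(ValueError):
        monoisotopic_mz(Formula(), charge=1)


def test_electron_correction_is_exactly_one_electron(dichloro_ion):
    corrected = monoisotopic_mz(dichloro_ion)
    uncorrected = monoisotopic_mz(dichloro_ion, electron_corrected=False)
    assert uncorrected - corrected == pytest.approx(ELECTRON_MASS, abs=1e-12)


@given(
    st.dictionaries(
        st.sampled_from(sorted(ISOTOPES)),
        st.integers(min_value=1, max_value=10),
        min_size=1,
        max_size=4,
    ),
    st.dictionaries(
        st.sampled_from(sorted(ISOTOPES)),
        st.integers(min_value=1, max_value=10),
        min_size=1,
        max_size=4,
    ),
)
@settings(max_examples=200, deadline=None)
def test_mass_additivity(ca, cb):
    a, b = Formula(ca), Formula(cb)
    assert monoisotopic_mz(a + b) == pytest.approx(
        monoisotopic_mz(a) + monoisotopic_mz(b), abs=1e-9
    )


# ---------------------------------------------------------------------------
# ppm error
# ---------------------------------------------------------------------------


def test_ppm_error_conventions(dichloro_ion):
    theo = monoisotopic_mz(dichloro_ion)
    assert abs(ppm_error(337.0503, theo)) <= 1.5
    assert ppm_error(theo, theo) == 0.0
    assert ppm_error(theo * (1 + 1e-6), theo) == pytest.approx(1.0, abs=1e-9)
    with pytest.raises(ValueError):
        ppm_error(100.0, 0.0)


def test_ppm_error_antisymmetric_to_first_order():
    a, b = 300.0000, 300.0009
    assert ppm_error(a, b) == pytest.approx(-ppm_error(b, a), rel=1e-5)


# ---------------------------------------------------------------------------
# RDBE
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "formula,charge,expected",
    [
        ("C16H16N2O2", 0, 10.0),  # rugulovasine neutral core
        ("CH4", 0, 0.0),
        ("C6H6", 0, 4.0),  # benzene
        ("C16H17O2N2", 1, 10.0),  # protonated ion neutralizes first
        ("C16H15O2N2Cl2", 1, 10.0),
    ],
)
def test_rdbe(formula, charge, expected):
    assert rdbe(parse_formula(formula, charge)) == pytest.approx(expected)


# ---------------------------------------------------------------------------
# differencing and nominal masses
# ---------------------------------------------------------------------------


def test_two_additional_chlorines(dichloro_ion, rugulovasine_ion):
    assert formula_difference(dichloro_ion, rugulovasine_ion) == {"Cl": 2, "H": -2}


def test_difference_of_self_is_empty(dichloro_ion):
    assert formula_difference(dichloro_ion, dichloro_ion) == {}


def test_bromo_for_chloro_swap():
    br = parse_formula("C16H16O2N2Br")
    cl = parse_formula("C16H16O2N2Cl")
    assert formula_difference(br, cl) == {"Br": 1, "Cl": -1}


def test_nominal_mass_rounding():
    assert nominal_mass(269.1284) == 269
    assert nominal_mass(347.0388) == 347
    assert nominal_mass(0.5) == 1
    assert nominal_mass(-0.5) == -1
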