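"""MS/MS loss annotation: reference product-ion tables, conservation,
depth minimality, parity and the epimer diagnostic."""

from __future__ import annotations

import pytest

from haloscreen.formula import Formula, parse_formula
from haloscreen.fragments import (
    LOSS_CATALOG,
    RDA_ION,
    annotate_products,
    assign_species_class,
    epimer_diagnostic,
    _loss_multisets,
)
from haloscreen.library import REFERENCE_SPECTRA

_BY_NAME = {l.name: l for l in LOSS_CATALOG}


def _reference_cases():
    for spec in REFERENCE_SPECTRA:
        for ion in spec.products:
            yield pytest.param(spec, ion, id=f"{spec.compound}-{ion.mz}")


@pytest.mark.parametrize("spec,ref", list(_reference_cases()))
def test_reference_product_ions_annotate_correctly(spec, ref):
    """Every reported product ion maps to its composition and species class."""
    anns = annotate_products(spec.precursor.ion_formula, [(ref.mz, ref.rel_intensity_pct)])
    (ann,) = anns
    assert ann.ion == ref.ion_formula
    assert ann.species_class == ref.species_class
    assert abs(ann.ppm) <= 5.0


@pytest.mark.parametrize("spec,ref", list(_reference_cases()))
def test_annotations_conserve_elements_and_mass(spec, ref):
    (ann,) = annotate_products(spec.precursor.ion_formula, [(ref.mz, ref.rel_intensity_pct)])
    total = Formula(dict(ann.ion.counts))
    if ann.losses == ("RDA",):
        total = total + (
            Formula(dict(spec.precursor.ion_formula.counts)) - Formula(dict(RDA_ION.counts))
        )
    else:
        for name in ann.losses:
            total = total + _BY_NAME[name].composition
    assert dict(total.counts) == dict(spec.precursor.ion_formula.counts)
    # and the loss masses close the mass balance exactly
    assert total.monoisotopic_mass == pytest.approx(
        spec.precursor.ion_formula.monoisotopic_mass, abs=1e-9
    )


@pytest.mark.parametrize("spec,ref", list(_reference_cases()))
def test_annotation_depth_is_minimal(spec, ref):
    """No shallower loss multiset also matches within tolerance."""
    (ann,) = annotate_products(spec.precursor.ion_formula, [(ref.mz, ref.rel_intensity_pct)])
    depth = len(ann.losses)
    if depth == 0:
        return
    for shallow in range(depth):
        for combo in _loss_multisets(shallow)[shallow]:
            try:
                ion = spec.precursor.ion_formula
                for loss in combo:
                    ion = ion - loss.composition
            except ValueError:
                continue
            if not ion:
                continue
            ppm = (ref.mz - ion.mz()) / ion.mz() * 1e6
            assert abs(ppm) > 5.0, f"shallower multiset {combo} also matches"


def test_precursor_survivor_has_empty_loss_set():
    prec = parse_formula("C16H15O2N2Cl2", 1)
    (ann,) = annotate_products(prec, [(prec.mz(), 73.0)])
    assert ann.losses == ()
    assert ann.species_class == "precursor"


def test_product_heavier_than_precursor_is_impossible():
    prec = parse_formula("C16H15O2N2Cl2", 1)
    (ann,) = annotate_products(prec, [(400.0, 10.0)])
    assert ann.species_class == "impossible"
    assert not ann.assigned


def test_unmatchable_product_is_unassigned():
    prec = parse_formula("C16H15O2N2Cl2", 1)
    (ann,) = annotate_products(prec, [(200.0000, 10.0)])
    assert ann.species_class == "unassigned"
    assert not ann.assigned


@pytest.mark.parametrize(
    "losses,expected",
    [
        (("Cl",), "I"),
        (("Br",), "I"),
        (("HCl",), "II"),
        (("HBr",), "II"),
        (("HCl", "H2O"), "III"),
        (("HBr", "H2O"), "III"),
        (("HCl", "H2O", "CO"), "IV"),
        (("RDA",), "V"),
        ((), "precursor"),
        (("H2O",), "unassigned"),  # outside the scheme
        (("H2O", "H2O"), "unassigned"),
        (("Cl", "HCl"), "unassigned"),
    ],
)
def test_species_class_mapping(losses, expected):
    assert assign_species_class(losses) == expected


def test_radical_loss_gives_odd_electron_ion():
    prec = parse_formula("C16H15O2N2Cl2", 1)
    radical = annotate_products(prec, [(302.0814, 16.0)])[0]
    even = annotate_products(prec, [(301.0736, 68.0)])[0]
    assert radical.losses == ("Cl",) and radical.odd_electron
    assert even.losses == ("HCl",) and not even.odd_electron


def test_rda_complement_is_computed_per_precursor():
    """One rule yields the C9H7N / C9H6NCl / C9H5NCl2 complements."""
    cases = {
        "C16H17O2N2": "C9H7N",
        "C16H16O2N2Cl": "C9H6ClN",
        "C16H15O2N2Cl2": "C9H5Cl2N",
        "C16H16O2N2Br": "C9H6BrN",
    }
    for prec_s, comp_s in cases.items():
        prec = parse_formula(prec_s, 1)
        (ann,) = annotate_products(prec, [(RDA_ION.mz(), 10.0)])
        assert ann.species_class == "V"
        complement = Formula(dict(prec.counts)) - Formula(dict(RDA_ION.counts))
        assert complement.to_string() == comp_s


def test_epimer_diagnostic():
    b_spec = next(s for s in REFERENCE_SPECTRA if s.compound == "2,8-dichlororugulovasine B")
    a_spec = next(s for s in REFERENCE_SPECTRA if s.compound == "2,8-dichlororugulovasine A")
    b_anns = annotate_products(
        b_spec.precursor.ion_formula,
        [(i.mz, i.rel_intensity_pct) for i in b_spec.products],
    )
    a_anns = annotate_products(
        a_spec.precursor.ion_formula,
        [(i.mz, i.rel_intensity_pct) for i in a_spec.products],
    )
    assert epimer_diagnostic(b_anns) == "B-type"
    assert epimer_diagnostic(a_anns) == "A-type-or-undetermined"
    assert epimer_diagnostic([]) == "undetermined"


def test_zero_noise_round_trip_recovers_planted_losses():
    """Spectra generated from the loss templates re-annotate identically."""
    from haloscreen.synth import generate, scenario_presets

    ds = generate(scenario_presets("hbr_supplemented", seed=0, mass_sigma_ppm=0.0))
    checked = 0
    for f in ds.features:
        truth_losses = ds.truth.msms_losses[f.msms_id]
        prec = parse_formula(ds.truth.features[f.feature_id][1], 1)
        spec = ds.msms[f.msms_id]
        anns = annotate_products(prec, list(spec["peaks"]))
        for ann, truth in zip(anns, truth_losses):
            assert tuple(sorted(ann.losses)) == tuple(sorted(truth))
            checked += 1
    assert checked >= 20  # every planted peak, not a vacuous loop
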