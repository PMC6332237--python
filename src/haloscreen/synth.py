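"""Seeded synthetic full-scan and MS/MS data with attached ground truth.

The generator emulates the statistical structure of a fungal extract
measured on a high-resolution instrument: each planted compound yields
one [M+H]+ feature with a simulated isotope envelope, per-peak
Gaussian mass jitter on the ppm scale (default σ = 0.5 ppm, inside the
1.5 ppm calibration bound of a modern QTOF), multiplicative log-normal
envelope-abundance jitter, an A-before-B retention-time layout for
epimer pairs, and an MS/MS peak list built from the reference loss
series with its reported relative intensities.  Optional decoy
features are planted > 20 ppm away from every real m/z so the library
window cannot match them by construction.

Two presets mirror the producing organism's cultivation scenarios:
``"pda"`` (standard potato-dextrose medium — rugulovasines plus the
chlorinated congeners, compounds 1–6) and ``"hbr_supplemented"``
(bromide-amended medium — all eight compounds including the
brominated pair).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .formula import Formula
from .isotopes import IsotopePattern, _pseudo_core, simulate_pattern
from .library import (
    PRESET_RT_MIN,
    REFERENCE_SPECTRA,
    RUGULOVASINE_LIBRARY,
    LibraryEntry,
    ReferenceSpectrum,
    reference_spectrum,
)
from .screen import Feature

__all__ = ["SyntheticSpec", "GroundTruth", "SyntheticDataset", "generate", "scenario_presets", "PRESETS"]

#: Species-class → loss multiset, resolved per halogen type at build time.
_CLASS_LOSSES = {
    "precursor": (),
    "I": ("X",),  # radical halogen
    "II": ("HX",),
    "III": ("HX", "H2O"),
    "IV": ("HX", "H2O", "CO"),
    "V": ("RDA",),
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic dataset; the seed fixes it byte-for-byte."""

    compounds: Tuple[str, ...]
    rt_min: Mapping[str, float] = field(default_factory=lambda: dict(PRESET_RT_MIN))
    #: per-feature base intensity (arbitrary counts)
    base_intensity: float = 1.0e6
    mass_sigma_ppm: float = 0.5
    abundance_sigma: float = 0.02
    n_decoys: int = 0
    with_msms: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mass_sigma_ppm < 0 or self.abundance_sigma < 0:
            raise ValueError("jitter sigmas must be non-negative")
        names = {e.name for e in RUGULOVASINE_LIBRARY}
        unknown = [c for c in self.compounds if c not in names]
        if unknown:
            raise ValueError(f"unknown library compounds: {unknown}")


@dataclass
class GroundTruth:
    """What was planted: the answer key for every pipeline stage."""

    #: feature_id -> (compound name, ion formula string, epimer label, nCl, nBr)
    features: Dict[str, Tuple[str, str, str, int, int]] = field(default_factory=dict)
    #: msms_id -> list of loss multisets (one tuple per peak, same order)
    msms_losses: Dict[str, List[Tuple[str, ...]]] = field(default_factory=dict)
    #: feature ids of decoys
    decoys: List[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "features": {k: list(v) for k, v in self.features.items()},
                "msms_losses": {
                    k: [list(t) for t in v] for k, v in self.msms_losses.items()
                },
                "decoys": self.decoys,
            },
            indent=2,
            sort_keys=True,
        )


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    features: List[Feature]
    #: msms_id -> {"precursor_mz": float, "peaks": [(mz, intensity), ...]}
    msms: Dict[str, Dict[str, object]]
    truth: GroundTruth


def _losses_for(compound_entry: LibraryEntry, cls: str) -> Tuple[str, ...]:
    halogen = "Cl" if compound_entry.formula["Cl"] else "Br"
    out = []
    for token in _CLASS_LOSSES[cls]:
        if token == "X":
            out.append(halogen)
        elif token == "HX":
            out.append("H" + halogen)
        else:
            out.append(token)
    return tuple(out)


def _jitter_mz(rng: np.random.Generator, mz: float, sigma_ppm: float) -> float:
    if sigma_ppm == 0:
        return mz
    return mz * (1.0 + rng.normal(0.0, sigma_ppm) * 1e-6)


def generate(spec: SyntheticSpec) -> SyntheticDataset:
    """Build one synthetic dataset from a :class:`SyntheticSpec`.

    Compounds are planted in library order; each gets a feature with a
    jittered simulated envelope and, when ``with_msms``, a product-ion
    list generated from its reference loss series using *theoretical*
    masses (so at σ=0 every m/z equals theory exactly) and the
    reported relative intensities.
    """
    rng = np.random.default_rng(spec.seed)
    entries = {e.name: e for e in RUGULOVASINE_LIBRARY}

    features: List[Feature] = []
    msms: Dict[str, Dict[str, object]] = {}
    truth = GroundTruth()

    planted_mz: List[float] = []
    for i, name in enumerate(spec.compounds):
        entry = entries[name]
        ion = entry.formula.protonated()
        pattern = simulate_pattern(ion)
        # anchor the A peak to the exact theoretical m/z: the convolution
        # centroid agrees only to ~1e-13 Da (summation order)
        anchor = ion.mz() - pattern.peaks[0][0]
        pattern = IsotopePattern(
            tuple((m + anchor, a) for m, a in pattern.peaks), ion, 1
        )
        # jitter envelope: independent per-peak mass jitter, multiplicative
        # log-normal abundance jitter, renormalized to base 100
        jittered = []
        for m, a in pattern.peaks:
            m_j = _jitter_mz(rng, m, spec.mass_sigma_ppm)
            a_j = a * float(np.exp(rng.normal(0.0, spec.abundance_sigma))) if spec.abundance_sigma else a
            jittered.append((m_j, a_j))
        envelope = IsotopePattern.from_rows(jittered)
        feat_mz = jittered[0][0]
        planted_mz.append(ion.mz())

        fid = f"F{i:04d}"
        msms_id: Optional[str] = None
        if spec.with_msms:
            msms_id = f"S{i:04d}"
            ref = reference_spectrum(name)
            peaks: List[Tuple[float, float]] = []
            losses: List[Tuple[str, ...]] = []
            for ref_ion in ref.all_ions:
                mz_theo = ref_ion.ion_formula.mz()
                peaks.append(
                    (_jitter_mz(rng, mz_theo, spec.mass_sigma_ppm), ref_ion.rel_intensity_pct)
                )
                losses.append(_losses_for(entry, ref_ion.species_class))
            msms[msms_id] = {"precursor_mz": feat_mz, "peaks": peaks}
            truth.msms_losses[msms_id] = losses

        intensity = spec.base_intensity * float(np.exp(rng.normal(0.0, 0.3)))
        features.append(
            Feature(
                rt_min=spec.rt_min[name],
                mz=feat_mz,
                intensity=intensity,
                envelope=envelope,
                msms_id=msms_id,
                feature_id=fid,
            )
        )
        truth.features[fid] = (
            name,
            ion.to_string(),
            entry.epimer_label,
            entry.formula["Cl"],
            entry.formula["Br"],
        )

    # Decoys: random masses rejected until > 20 ppm from every planted m/z,
    # with a halogen-free pseudo-core envelope.
    for d in range(spec.n_decoys):
        while True:
            mz = float(rng.uniform(150.0, 600.0))
            if all(abs(mz - p) / p * 1e6 > 20.0 for p in planted_mz):
                break
        core = _pseudo_core(mz)
        pattern = simulate_pattern(core.replace_charge(1) if core.charge == 0 else core)
        shift = mz - pattern.peaks[0][0]
        envelope = IsotopePattern.from_rows([(m + shift, a) for m, a in pattern.peaks])
        fid = f"D{d:04d}"
        features.append(
            Feature(
                rt_min=float(rng.uniform(0.5, 9.5)),
                mz=mz,
                intensity=spec.base_intensity * float(np.exp(rng.normal(-2.0, 0.5))),
                envelope=envelope,
                feature_id=fid,
            )
        )
        truth.decoys.append(fid)

    return SyntheticDataset(spec, features, msms, truth)


#: name -> compounds planted by that scenario.
PRESETS: Dict[str, Tuple[str, ...]] = {
    # standard potato-dextrose cultivation: H and Cl series only
    "pda": tuple(e.name for e in RUGULOVASINE_LIBRARY[:6]),
    # bromide-supplemented medium: brominated pair co-produced
    "hbr_supplemented": tuple(e.name for e in RUGULOVASINE_LIBRARY),
}


def scenario_presets(name: str, seed: int = 0, **overrides) -> SyntheticSpec:
    """A ready-made :class:`SyntheticSpec` for a named cultivation scenario."""
    if name not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    return SyntheticSpec(compounds=PRESETS[name], seed=seed, **overrides)
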