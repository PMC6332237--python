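"""Isotope envelopes and halogen-count inference.

Chlorine and bromine leave unmistakable A+2 / A+4 fingerprints in an
ion's isotope envelope; the classifier reads the halogen count straight
off the envelope without knowing the formula.
"""

from haloscreen import classify_halogens, parse_formula, simulate_pattern

for comp in ["C16H17O2N2", "C16H16O2N2Cl", "C16H15O2N2Cl2", "C16H16O2N2Br"]:
    pattern = simulate_pattern(parse_formula(comp, 1))
    a_mz, a_ab = pattern.peaks[0]
    print(f"\n{comp}+ envelope:")
    for m, ab in pattern.peaks[:5]:
        print(f"  {m:9.4f}  {ab:6.2f}")
    call = classify_halogens(pattern)
    print(f"  halogen call: {call.n_cl} Cl, {call.n_br} Br (score {call.score:.4f})")

# The A+2/A ratio grows from ~0.02 (no halogen) to ~0.34 (one Cl),
# ~0.66 with a clear A+4 (two Cl), and ~0.97 (one Br) — which is why a
# dichloro and a monobromo ion are easy to tell apart even at the same
# nominal mass region.
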