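"""Candidate formula enumeration with isotope-envelope re-ranking.

An accurate mass alone rarely pins a composition: at m/z 337.0506
several formulas fit within 5 ppm.  The observed isotope envelope
breaks the tie.
"""

from haloscreen import enumerate_formulas, parse_formula, rerank_with_isotopes, simulate_pattern

mz_observed = 337.0506  # unknown ion from the extract
candidates = enumerate_formulas(mz_observed, window_ppm=5.0)
print(f"{len(candidates)} candidates within 5 ppm of {mz_observed}:")
for c in candidates:
    print(f"  {c.ion.to_string():16s} ppm {c.ppm:6.2f}  RDBE {c.rdbe:5.1f}")

# Pretend the instrument recorded the dichloro envelope:
observed_envelope = simulate_pattern(parse_formula("C16H15O2N2Cl2", 1))
ranked = rerank_with_isotopes(candidates, observed_envelope)
print("\nafter isotope re-ranking:")
for c in ranked[:3]:
    print(f"  {c.ion.to_string():16s} iso {c.iso_score:.4f}  combined {c.rank_score:.4f}")
print("\ntop assignment:", ranked[0].ion.to_string())
# The dichlorinated composition wins once the envelope is considered,
# even though a Br-containing near-isobar has the smaller ppm error.
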