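"""Exact masses, ppm errors and formula differencing.

Reconciles the reported [M+H]+ masses of the rugulovasine alkaloid
series with their ion compositions, and shows how the dichlorinated
unknown differs from the parent alkaloid by exactly two chlorines.
"""

from haloscreen import formula_difference, monoisotopic_mz, nominal_mass, parse_formula, ppm_error

series = [
    ("rugulovasine A/B [M+H]+", 269.1284, "C16H17O2N2"),
    ("8-chlororugulovasine [M+H]+", 303.0894, "C16H16O2N2Cl"),
    ("2,8-dichlororugulovasine [M+H]+", 337.0503, "C16H15O2N2Cl2"),
    ("2-bromorugulovasine [M+H]+", 347.0388, "C16H16O2N2Br"),
]

print(f"{'ion':34s} {'reported':>10s} {'theoretical':>12s} {'ppm':>6s}")
for name, observed, comp in series:
    theo = monoisotopic_mz(parse_formula(comp, 1))
    print(f"{name:34s} {observed:10.4f} {theo:12.4f} {ppm_error(observed, theo):6.2f}")

# Every reported mass sits within ~1.2 ppm of theory: the sub-5-ppm
# agreement is what justifies the formula assignments.

dichloro = parse_formula("C16H15O2N2Cl2", 1)
parent = parse_formula("C16H17O2N2", 1)
print("\ndichloro ion - parent ion:", formula_difference(dichloro, parent))
# {'Cl': 2, 'H': -2}: two chlorines substituted for two hydrogens.

print(
    "nominal deltas: Br-vs-Cl",
    nominal_mass(347.0388) - nominal_mass(303.0894),
    "Da, Br-vs-H",
    nominal_mass(347.0388) - nominal_mass(269.1284),
    "Da",
)
# 44 and 78 Da: the whole-dalton fingerprints of Br-for-Cl and
# Br-for-H substitution used for quick spectral inspection.
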