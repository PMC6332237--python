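"""MS/MS loss annotation and the retro-Diels–Alder epimer diagnostic.

Annotates the reported product ions of the dichlorinated B epimer:
radical Cl loss (I), HCl loss (II), +H2O (III), +CO (IV), and the
C7H10O2N+ retro-Diels–Alder ion (V) that marks B epimers.
"""

from haloscreen import annotate_products, epimer_diagnostic, parse_formula

precursor = parse_formula("C16H15O2N2Cl2", 1)  # 2,8-dichlororugulovasine B [M+H]+
reported_products = [
    (302.0812, 5),
    (301.0734, 27),
    (283.0628, 33),
    (255.0677, 6),
    (140.0703, 18),
]

annotations = annotate_products(precursor, reported_products, collision_energy_ev=25.0)
print(f"{'m/z':>9s}  {'losses':16s} {'class':8s} {'ion':14s} {'ppm':>6s}")
for a in annotations:
    print(
        f"{a.mz_observed:9.4f}  {'+'.join(a.losses):16s} {a.species_class:8s}"
        f" {a.ion.to_string():14s} {a.ppm:6.2f}"
    )
print("\nepimer diagnostic:", epimer_diagnostic(annotations))
# The class V ion is present, so this spectrum is B-type: only the B
# epimers' ring conformation permits the retro-Diels-Alder cleavage.
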