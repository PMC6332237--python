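"""Halogen-substitution series linking and library dereplication.

On a synthetic bromide-supplemented extract, the all-pairs delta scan
ties the m/z 347 features to both the chloro (Δ44) and the parent
(Δ78) series, and the ±5 ppm library match names every feature.
"""

from haloscreen import default_library, dereplicate, link_series
from haloscreen.synth import generate, scenario_presets

ds = generate(scenario_presets("hbr_supplemented", seed=42))

links = link_series(ds.features)
print(f"{len(links)} substitution links found; the bromo-series ones:")
for l in links:
    if l.delta.name.startswith("Br"):
        print(
            f"  {l.light.mz:9.4f} -> {l.heavy.mz:9.4f}  {l.delta.name:9s}"
            f" (nominal {l.delta.nominal_da} Da, err {l.error_mda:+.2f} mDa)"
        )

print("\ndereplication against the built-in library:")
for match in dereplicate(ds.features, default_library()):
    names = ", ".join(e.name for e in match.entries) or "UNKNOWN"
    print(f"  {match.feature.mz:9.4f} @ {match.feature.rt_min:.1f} min -> {names}")
# Epimer pairs share one composition so each feature matches both the A
# and the B entry; elution order (A first) settles which is which.
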