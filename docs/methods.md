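# Methods

This note records the models, conventions and numerical choices behind
haloscreen, in the order the pipeline applies them.

## Mass arithmetic and conventions

All masses derive from a single static isotope table embedded in
`haloscreen.elements` (ten elements: C, H, N, O, S, P, Cl, Br, Na, K; exact
masses and natural abundances from the standard atomic-mass evaluations,
six-plus decimals). The table is the only source of mass constants in the
package — substitution deltas, envelope simulations and every theoretical
m/z are computed from it, never duplicated. The test suite cross-checks the
table against the pyteomics NIST table as an independent source.

**Cation m/z.** For a +1 composition, m/z = Σ(lightest-isotope masses) −
m_e, with m_e = 5.48580×10⁻⁴ Da. The electron correction is on by default
and is not cosmetic: at m/z 140 it is 3.9 ppm, larger than the 1.5 ppm
calibration of a modern QTOF, and the reported C7H10O2N+ ion mass
(140.0705) reconciles only under the corrected convention (0.75 ppm vs
4.67 ppm uncorrected).

**ppm sign.** ppm = (observed − theoretical)/theoretical × 10⁶. Published
inline ppm values for this compound series are not reproducible under any
single sign/reference convention, so all comparisons in this package use
magnitudes.

**RDBE.** 1 + C + (N+P)/2 − (H+Cl+Br)/2 on the neutralized formula
(protonated ions lose one H first); O and S contribute zero. Negative and
half-integral values are returned, filtering is the caller's decision.

**Nominal mass.** Round-half-away-from-zero of the exact mass, applied per
ion *before* differencing. This reproduces whole-dalton inspection values
(m/z 347; Δ44 Br-vs-Cl; Δ78 Br-vs-H) exactly.

## Isotope envelopes

Envelopes are computed exactly: per element, the n-atom isotopologue
distribution by multinomial expansion (pruning terms below 10⁻¹²), then
cross-element convolution, then greedy centroiding with a 0.02 Da
aggregation width — the centroid regime of a ~50,000-FWHM QTOF, where fine
structure within a nominal mass is not resolved. Peaks are dropped from the
envelope tail only while the cumulative dropped abundance stays below 10⁻⁴
of the total; a `max_shift` parameter can additionally cap the envelope at
A+k when a fixed-depth envelope is wanted. We keep the mass-fraction rule as
the default (rather than a hard A+4 cap) because Cl₂- and Br-containing
ions carry more than 10⁻⁴ of their abundance above A+4, and the A+4/A+6
region is exactly where the Cl₂-vs-Br distinction lives. An envelope's
abundances are scaled so the base peak is exactly 100.

The simulator is verified against an independent brute-force oracle
(exhaustive per-atom isotope enumeration) to 10⁻⁶ relative abundance for
all tested ≤8-atom formulas.

**Similarity metric.** Envelopes are compared by a peak-matched normalized
dot product: both envelopes are normalized to unit total abundance, peaks
are paired one-to-one by nearest m/z within tolerance (default 150 ppm,
generous because envelope peaks are ≥1 Da apart), and the score is
⟨p,q⟩ / max(⟨p,p⟩, ⟨q,q⟩). The max-norm denominator was chosen over the
cosine's geometric mean deliberately: a plain cosine is dominated by the
base peak and scores a monobromo envelope ≈0.98 against a dichloro
observation, too close to rank reliably under ppm-scale mass noise; the
max-norm form scores identical envelopes exactly 1, is symmetric, penalizes
missing/extra peaks, and separates the halogen hypotheses sharply (Cl₂ vs
halogen-free ≈ 0.58, Cl₂ vs Br₁ ≈ 0.82).

**Halogen classification.** Hypotheses (nCl ≤ 2, nBr ≤ 1 by default) are
simulated on the substituted core when the CHNO core is known, otherwise on
a CH pseudo-core mass-matched to the observed monoisotopic peak. Scoring
uses only the even-shift sub-envelope (A, A+2, A+4, …): the halogen
signature lives entirely two nucleons up, while the odd A+1/A+3 ladder
mostly encodes the carbon count — which a mass-matched stand-in core gets
wrong by several atoms, and which would otherwise leak core error into the
halogen call. Near-ties (score difference < 10⁻³) resolve toward fewer
total halogen atoms. On noise-free envelopes of all six (nCl ≤ 2, nBr ≤ 1)
hypotheses of the alkaloid core the confusion matrix is the identity.

## Formula assignment

Candidates are enumerated by depth-first search over per-element count
ranges with running residual-mass pruning; the default bounds (C 0–30,
H 0–40, N 0–6, O 0–8, Cl 0–4, Br 0–2) cover the halogenated-alkaloid space
at ~1.2 M lattice points, of which the pruned search visits a tiny
fraction. Filters: 0 ≤ RDBE ≤ 25 on the neutralized formula, integer RDBE
for even-electron [M+H]+ ions (radical species occur only in MS/MS and are
handled there), and at least one H (the proton). Order is total and
deterministic: |ppm|, then fewer halogens, then the formula string.
Re-ranking combines 0.4·(1 − |ppm|/window) + 0.6·envelope similarity; the
weights favour the envelope because at ±5 ppm the window typically contains
near-isobars whose ppm differences are sub-noise while their envelopes
differ qualitatively.

## Screening

Substitution links: all ordered feature pairs whose m/z difference matches
m(³⁵Cl)−m(¹H), m(⁷⁹Br)−m(³⁵Cl) or m(⁷⁹Br)−m(¹H) within 3 mDa. The delta
tolerance is looser than the formula window on purpose — two measured
masses contribute error (3 mDa ≈ 10 ppm at m/z 300). Only light-isotope
deltas are scanned; envelope A-peaks are used as feature m/z so
isotopologue cross-links do not arise. Dereplication matches feature m/z
against library [M+H]+ masses within ±5 ppm; epimer pairs share a
composition, so both entries match and the pair is then labelled by elution
order — A before B in reversed phase, applied only when exactly two
features of one composition with distinct RT are present (anything else is
"undetermined" with a warning).

## MS/MS annotation

Loss multisets are searched breadth-first over the catalogue {Cl•, HCl,
Br•, HBr, H2O, CO} with per-loss multiplicity 1 (H2O: 2) to depth 3 — the
reference loss series never needs more. The first depth with a match wins
(depth minimality is asserted in tests); equal-depth ties prefer multisets
without radical losses, then lower |ppm|. The retro-Diels–Alder channel is
not catalogued as a loss: the class V ion is fixed (C7H10O2N+) and its
neutral complement is computed per precursor by element-wise subtraction,
accepted when non-negative — one rule that yields the C9H7N, C9H6NCl,
C9H5NCl2 and C9H6NBr complements across the series. Element conservation
(precursor = product + losses) is asserted on every annotation. Radical
losses flip the product ion's electron parity, which is tracked per
annotation. Class V presence calls a spectrum "B-type"; its absence is
reported as "A-type-or-undetermined" because a missing channel is not
evidence of the A configuration. Collision energy is carried as metadata
and never scored; the published relative intensities are
instrument-dependent and are used only as generator templates.

## Synthetic data

The generator plants library compounds as [M+H]+ features with simulated
envelopes and builds their MS/MS peak lists from the reference loss series
(theoretical product masses, reported relative intensities, plus the
precursor survivor peak). Noise model: per-peak Gaussian m/z jitter in ppm
(default σ = 0.5 ppm, chosen inside the 1.5 ppm calibration bound;
envelope peaks jittered independently) and multiplicative log-normal
abundance jitter (σ = 0.02). Retention times are fixed per compound in the
3–8 min window with each A epimer 0.2 min before its B partner (the
dichloro pair at 3.7/3.9 min). Decoy features (opt-in) are drawn uniformly
in m/z 150–600 and regenerated until > 20 ppm from every planted mass, so
they cannot enter the ±5 ppm library window by construction; they carry
halogen-free pseudo-core envelopes. The seed fixes the dataset
byte-for-byte. Two presets mirror the cultivation scenarios: "pda"
(compounds 1–6, no bromine) and "hbr_supplemented" (all eight).

What the generator does *not* emulate: chromatographic peak shapes,
UV/Vis traces, adducts other than [M+H]+, polyketide matrix background
beyond point decoys, intensity-dependent mass error, or detector
saturation. Passing the recovery benchmarks therefore demonstrates the
correctness of the inference chain under calibrated-instrument noise, not
robustness to every artefact of real chromatograms.

## Problem sizes and determinism

The recovery benchmarks use the 8-compound bromide scenario at σ = 0 and
20 seeded replicates at σ = 0.5 ppm (160 features), and the jitter
calibration check uses 1000 replicate features of one compound — sizes at
which the full suite runs in seconds while the binomial confidence on a
≥95% rate is meaningful. All randomness flows through
`numpy.random.default_rng(seed)`; reports print m/z to 4 decimals and ppm
to 2 so identical runs are byte-identical.

## Known limitations

- Charge states are restricted to 0 and +1; no multiply charged ions, no
  adduct deconvolution (Na/K masses are computable but nothing interprets
  them).
- The element alphabet is fixed to ten elements; others are rejected.
- Profile-mode spectra and fine isotope structure below 0.02 Da are out of
  scope; observed envelopes are assumed centroided.
- The halogen classifier assumes the observed monoisotopic peak is the
  true A peak; a missing A peak (very weak signals) would shift every
  hypothesis.
- MS/MS annotation is combinatorial, not mechanistic: it proposes the
  minimal consistent loss multiset and makes no claim about pathway order
  or intensities.
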