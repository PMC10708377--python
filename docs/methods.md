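# Methods

## Scope and model

The package analyses the membrane topology of the syndecan-4
ecto/TM/cyto construct (57 residues; a 4-residue ecto stub, the
25-residue TM helix at construct positions 5–29, and the full
cytoplasmic domain with its C1/V/C2 subregions) and its interaction
with PIP₂, from peak lists alone. Three computations are chained:

1. an ideal-helix forward model of oriented-sample SLF spectra (PISA
   wheels),
2. tilt/rotation fitting of observed SLF peak lists against that model,
   including a two-wheel fit for the GXXXG-mediated dimer in which the
   two monomers sit at different tilts, and
3. CSP mapping between free and ligand-bound HSQC peak lists.

No lineshapes, relaxation, or spectral processing are modelled — the
inputs and outputs are peak coordinates.

## Helix geometry

The backbone is generated residue by residue from fixed standard
internal coordinates (N-Cα 1.458 Å, Cα-C 1.525 Å, C-N 1.329 Å, ideal
sp² amide angles, ω = 180°) at user torsions, default Φ = −69°,
Ψ = −42° (a slightly tighter-than-canonical TM helix; twist 95.3°/res,
rise 1.43 Å/res). PISA observables depend on these bond constants only
weakly; they are constants of the library, not fit parameters. The
residue→residue screw transform is extracted by Kabsch superposition of
the chain onto itself shifted by one residue, and the whole chain is
rigidly mapped so the screw axis is +z with rise toward +C. Torsions
producing a near-zero rise (< 10⁻³ Å) are rejected as non-helical
rather than silently accepted. The amide H sits in the peptide plane,
1.02 Å from N, trans to the carbonyl oxygen. The test suite checks the
builder against an independent Kahn-style axis construction (bisectors
of consecutive Cα-Cα bonds), not against the builder's own
superposition route.

## ¹⁵N tensor orientation and magnitudes

Only σ₁₁ = 64 ppm and σ₂₂ = 77 (or 88) ppm are established for this
system; σ₃₃ and the tensor orientation in the molecular frame are not.
We use the standard amide values: σ₃₃ = 217 ppm, σ₃₃ in the peptide
plane at β = 17° from the N-H bond (rotated toward the preceding
carbonyl carbon), σ₂₂ perpendicular to the peptide plane. All four
quantities are configuration parameters (`sigma33`, `beta_deg`,
`sigma22` selectable between 77 and 88), so either printed σ₂₂ choice
and any tensor convention can be explored without touching code.

## Bicelle scaling and the 1D region rule

Observed = iso + S·f·(static − iso), with S ∈ [0, 1] the bicelle order
parameter (default 0.85, the upper end of the 0.80–0.85 range
characteristic of these preparations) and f = −1/2 for unflipped
bicelles (bilayer normal ⊥ B₀) or +1 for flipped. No additional
pulse-sequence scaling is applied to the dipolar axis: the 2–4.5 kHz
transmembrane band is taken to be the bicelle-scaled coupling as
observed. Peak lists report coupling magnitudes; the sign is retained
on each simulated peak separately.

`classify_1d` implements the reported unflipped-bicelle convention for
1D CP spectra (shift < 120 ppm → surface, ≥ 120 ppm → transmembrane;
ties go transmembrane). Note that a direct tensor projection with a
standard downfield σ₃₃ predicts the opposite region assignment for an
unflipped bicelle (TM amides, N-H near the normal ⊥ B₀, resonate
upfield of iso); the function exposes `surface_below=False` for the
physics-based rule and records the discrepancy in its output metadata
instead of adjudicating.

## Tilt fitting

Simulated and observed peaks are compared after normalizing each axis
by its physically available span — (σ₃₃ − σ₁₁)·S·|f| for shifts,
ν∥·S·|f| for couplings — so both dimensions contribute comparably.
Matching is minimum-total-cost one-to-one assignment (Hungarian
algorithm via `scipy.optimize.linear_sum_assignment`) for unassigned
lists, or label-constrained when both lists carry residue assignments;
the score is the rms matched distance. The search is a deterministic
grid (τ 0–30° step 0.5°, ρ₀ 0–360° step 5° by default) followed by
three rounds of coordinate-wise golden-section refinement within one
grid cell; there is no random initialization. On noiseless
self-generated data the fit recovers the generating tilt to ≲ 10⁻⁴
degrees; at 0.5 ppm / 0.1 kHz Gaussian noise the median tilt error over
20 replicates is ≈ 0.2°.

The two-wheel (dimer) fit runs a joint coarse grid (τ step 2°, ρ₀ step
20°) over unordered pairs of wheels, scoring each peak against the
nearer wheel, then partitions the peaks at the coarse optimum and
refines each component with an independent single-wheel fit on a fine
local grid. Handing it single-wheel data yields one component holding
every peak and one flagged empty (`n_peaks = 0`). Degeneracy: if both
generating components coincide, both fitted tilts agree to within the
refinement tolerance.

## CSP

CSP_i = √((ΔδH_i)² + α(ΔδN_i)²), α = 0.14 (the field-standard nitrogen
weighting; configurable). The quadratic form is also available without
the radical (`sqrt_form=False`) for comparison with conventions that
print it that way; the square-root form is the default and the one all
derived values use. CSP requires residue-assigned lists on both sides —
assignment itself (done experimentally via selective labelling and
HMQC-NOESY) is out of scope and emulated by labelled synthetic lists.
Residues present in only one list are reported as unmatched, never
scored.

Flagging defaults to mean + 3·sd over the scored residues. The
three-sigma multiplier is a deliberate choice for this construct size:
with ~54 scored residues the maximum of the noise-only CSPs exceeds
mean + 1·sd almost surely, so a 1·sd rule cannot isolate a genuinely
perturbed residue; at 3·sd a perturbation ≥ 5× the noise floor is
flagged uniquely and reproducibly. Both the rule (`mean_plus_sd` /
`fixed`) and the multiplier are configuration parameters.

## Numbering conventions

The construct's full-length numbering is anchored so its unique
cytoplasmic serine (construct position 38) maps to Ser179, the
PKC-regulatory phosphosite; under this offset (first residue = 142) the
V-domain tyrosine at position 47 is Tyr188. The alternative
one-lower anchor (which names that tyrosine Tyr187) is selectable via
`first_full_number=141`: the two published anchors are mutually
inconsistent by one residue for the printed sequence, and the package
supports both rather than asserting either.

## Synthetic data

The generators stand in for spectra that are not publicly deposited;
recovery tests on them are therefore self-consistency and robustness
statements about the method, not re-measurements of the experimental
system.

* HSQC pairs: one peak per amide-bearing residue (residue 1 and the two
  prolines, positions 45 and 51, are skipped). Base positions are drawn
  once per residue from uniform windows (¹H 7.5–9.0, ¹⁵N 105–130 ppm)
  seeded by the residue index — stable across runs, geometrically
  realistic, spectroscopically arbitrary. Perturbations are added to
  the bound list only; Gaussian noise (defaults 0.01 ppm ¹H, 0.05 ppm
  ¹⁵N) is independent between the two lists.
* SLF lists: exact forward-model peaks plus independent Gaussian noise
  per axis (defaults 0.5 ppm, 0.1 kHz, a realistic linewidth-limited
  peak-picking uncertainty for these spectra); negative noisy couplings
  fold back to magnitudes. Zero noise reproduces the forward model
  bit-for-bit.
* Dimer lists: union of two wheels (default truths 6° and 16°, the
  fitted monomer tilts) over disjoint or identical residue spans.

All generators are deterministic under a fixed seed
(`numpy.random.default_rng`). Side-chain NH₂ pairs (the Asn-doubling
dimer evidence in HSQC) are not generated; peak-count-based multimer
inference is out of scope.

## What the tests do and do not show

Because the experimental SLF and HSQC peak coordinates are not
tabulated anywhere, the 6°/16° tilts and the Tyr187/188 CSP cannot be
re-fit from real data at desk scale. What is checked instead: (a) the
printed sequence facts; (b) that the forward model at the fitted tilts
confines every TM coupling to the printed 2–4.5 kHz band; (c) exact
agreement between the closed-form frequencies and a brute-force
rotation-matrix oracle; (d) physical limits (τ = 0 collapse, S = 0
isotropy, magic-angle zero, powder average = σ_iso); (e) parameter
recovery on synthetic data generated at the published values. Real
spectra add peak overlap, missing assignments, linewidth variation and
deviations from ideal helicity, none of which the generators emulate.

## Problem sizes and tolerances

Default grids (61 × 72 single-wheel; 16 × 18 joint coarse pairs) and
replicate counts (20 seeds for recovery statistics, 100 draws for
oracle equivalence) keep the full suite under ~10 s while leaving the
statistical checks well-powered. Numerical tolerances: orthonormality
and oracle equivalence at 1e-9; ideal-helix symmetry at 1e-6 degrees;
numerically integrated powder averages at 0.5 ppm with fixed-seed
quadrature grids.
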