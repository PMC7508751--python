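# Methods

## The pressure-shift model

Chemical shifts of random-coil peptides respond non-linearly to pressure
between 0.1 and 200 MPa.  The package models the response of each
resonance as a truncated Taylor expansion around the reference pressure
P₀ = 0.1 MPa,

    δ(P) = δ₀ + B₁ ΔP + B₂ ΔP²,     ΔP = P − P₀,

optionally extended to third order for small molecules with stronger
curvature.  ΔP is handled internally in GPa — the design matrix of a
0.1–200 MPa series is then well-conditioned without scaling tricks — and
B₁/B₂ carry the customary units ppm·GPa⁻¹ and ppm·GPa⁻².  For almost all
side-chain resonances B₂ has the sign opposite to B₁ ("saturation-like"
response: the drift weakens at high pressure); when B₂/B₁ < 0 the
implied zero-slope pressure is P_ex = P₀ − B₁/(2B₂), which lies outside
the measured range for every reference resonance (the mean Hβ ratio of
−1.4 GPa⁻¹ puts it at ΔP = 357 MPa).

Fitting is ordinary least squares (unweighted by default, because the
reference data carry no per-point uncertainties; 1/σ² weighting is
available when a σ column is provided).  Confidence intervals are
t-based with n − (degree+1) degrees of freedom; their frequentist
calibration is verified by simulation (95% nominal, recovered within
sampling error at 2000 replicates).

## The reference database

The packaged tables hold, verbatim, the side-chain ¹H/¹⁵N coefficients
of the twenty Ac-Gly-Gly-Xxx-Ala-NH₂ peptides (283 K, pH 6.7; His also
at pH 4.0 and 8.5; Pro cis/trans and Cys reduced/oxidized as separate
variants), the SAIL-amino-acid isotope shifts supporting stereospecific
assignments, and the sequence-correction factors.  Errors are stored as
the published 95% confidence half-widths.  Load-time validation checks
value ranges per nucleus, the B₂/B₁ column against the stored
coefficients (with a tolerance that propagates half an ulp of the
printed B₁/B₂, since the published ratios were computed from unrounded
fits), the recomputation of every isotope-shift difference, the
40-record Hβ count, and the 9+9 nitrogen-table count.

Conventions worth knowing:

* **Geminal pairs.**  Each physically distinct proton environment is one
  record.  Unresolved but distinct pairs ("Hβ2/β3" rows with different
  numbers) are stored under HB2/HB3 in printed (upfield-first) order
  with `stereo_status="ambiguous"` — the labels are interchangeable.
  Truly degenerate pairs (one resonance for both protons, or symmetric
  aromatic positions like Phe Hδ1/Hδ2) are duplicated with identical
  numbers and `stereo_status="degenerate"`.  Footer statistics
  deduplicate records expanded from a single printed row; correlation
  analyses count atoms.
* **Methyls and equivalent groups** live under pseudo-atoms (QB, QG1,
  QD1, QE, QZ, QH1/QH2) with an alias map from per-proton IUPAC names.
* **Variant defaults.**  Pro → trans, Cys → reduced.  His has no
  default: its coefficients differ strongly between pH 4.0 and 8.5, so a
  silent choice would be misleading and lookups require an explicit tag.
* The source tables disagree internally on two countings.  The
  per-position atom counts (Hδ = 18, Hε = 12) exclude the Asn/Gln amide
  NH₂ protons, while the same tables' Hδ/Hε slopes are those obtained
  *with* them; and the chemical-group count for aromatic ring CH protons
  counts symmetric pairs once (14) where the position analysis counts
  them twice.  `group_summary` follows the count-faithful reading
  (NH₂ protons excluded from positions, ring pairs as two atoms) and
  offers `include_h2n=True` for the other one.  The published proton
  footer of the nitrogen table also prints the B₂ and B₂/B₁ means with
  inverted sign relative to its own rows; the package reports the
  recomputed values (+0.067, +0.57).

## Sequence-neighbor corrections

Random-coil pressure coefficients depend on sequence neighbors.  The
correction factors were obtained from the tetrapeptide design by
differencing reporter coefficients against the all-Gly peptide,

    C₁,₂^(−1,a)(y) = B₁,₂^a(Ac-GGyA-NH₂) − B₁,₂^a(Ac-GGGA-NH₂),

with the +1/+2 offsets read off the Gly2/Gly1 reporters, and are applied
additively:

    B₁,₂^corr(x) = B₁,₂(x) + C₁,₂^(−1)(u) + C₁,₂^(+1)(y) + C₁,₂^(+2)(z)

for x in the context -uxyz-.  This construction is exactly closed:
re-applying a derived table to the peptide it came from reproduces the
reporter coefficients, which is property-tested.  Corrections exist for
HN and Hα of all twenty residues (His at pH 4.0, Pro as trans) and for
the Ala β-methyl at offset −1.  Absent neighbors — chain ends, capping
groups — contribute zero, mirroring the Gly reference; offsets without
data (−2 and beyond, +3 and beyond) contribute zero silently.  Column
means include the all-zero Gly row, matching the published footer
(HN: 0.08/0.01/0.04 ppm·GPa⁻¹ for C₁ at −1/+1/+2).

Only the *pressure coefficients* are corrected.  δ₀ neighbor effects are
published as means without a usable per-residue table, so δ₀ always
comes from the reference record; predicted absolute curves therefore
carry an uncorrected ambient-shift offset (the deviation score removes
constant offsets for exactly this reason).

Note that the HN/Hα *base* coefficients belong to the backbone dataset
of the companion studies and are not packaged; applying corrections to
them requires user-supplied extra tables (`extra_*.tsv` in a data
directory, or an explicit `base=(b1, b2)` pair).

## Multi-state thermodynamics

A nucleus in fast exchange between M states shows the population
average ⟨δ⟩ = Σ p_j δ_j with Boltzmann weights p_j ∝ exp(−ΔG_1j/RT) and

    ΔG(ΔP) = ΔG⁰ + ΔV⁰ ΔP + ½ (∂ΔV⁰/∂P) ΔP².

Units exploit 1 mL·MPa = 1 J: ΔG⁰ in kJ·mol⁻¹, ΔV⁰ in mL·mol⁻¹, ΔP in
MPa, ∂ΔV⁰/∂P (= −Δβ′) in mL·mol⁻¹·GPa⁻¹.  Transitions are
chain-parameterized (ΔG_1j as cumulative sums of consecutive-state
differences), which keeps multi-state fits identifiable; populations are
evaluated in log space so extreme energies saturate to exactly 0/1.

Each state's intrinsic shift is itself pressure dependent through
conformer compression.  Fitting per-state δ₀/B₁/B₂ plus thermodynamics
is hopelessly over-parameterized, so the package implements the
shared-compression simplification: with state-independent B₁/B₂ the
ensemble shift separates *exactly* into population-weighted δ₀ plus
B₁ΔP + B₂ΔP² (an algebraic identity, property-tested to 1e−12), and the
compression term can either be fixed at random-coil values inside the
fit or subtracted from the data beforehand (`compression_correct`).

`fit_two_state` solves for (ΔG⁰, ΔV⁰, δ₀₁, δ₀₂), with ∂ΔV⁰/∂P fixed at 0
by default (freed by flag), by bounded trust-region least squares from
16 multi-starts on a seeded Latin-hypercube-style spread (default seed
20200622).  The two-state model is invariant under swapping the states
with ΔG → −ΔG; fits are canonicalized to ΔG⁰ ≥ 0 (state 1 dominant at
ambient pressure).  Flat series and fits whose amplitude |δ₀₁ − δ₀₂| is
within 3 residual SDs raise a non-identifiability error; fits whose
population change across the observed range is below 5 percentage points
are flagged (the flag is computed from the fitted model — weakly
identified data often admit equivalent solutions, so it is a diagnostic,
not a guarantee).

In the two-state small-|ΔG/2RT| regime the ensemble shift is linear in
tanh(ΔG/2RT) ≈ ΔG/2RT and a degree-2 fit of such data obeys
B₂/B₁ ≈ −½ Δβ′/ΔV; the simulation suite verifies this closed form to
within 10% (observed: <1%).  `compressibility_ratio` attaches exactly
this interpretation, with its validity caveat, to a coefficient pair.

## Aggregate statistics and disorder scoring

Group curvature ratios are estimated as the OLS slope of B₂ on B₁ *with
intercept* — the choice was settled by recomputing the published group
values from the packaged rows (NH₂ nitrogens: slope 1.39, r 0.74; H₂N
protons: −0.42, −0.40; Hβ: −1.39, r −0.82), which a through-origin
regression does not reproduce.  Slopes computed from printed (rounded)
coefficients match the published ones within the published precision for
all large groups; tiny groups can differ in the second decimal.

`random_coil_deviation` scores a measured series against a predicted
random-coil curve: (i) offset-corrected RMS deviation divided by the
stated noise SD, and (ii) z-scores of the fitted B₁/B₂ against the
reference half-widths combined in quadrature with the fit's own 95%
half-widths (without the second term, fit noise alone would flag any
noisy series whose reference happens to have a tight half-width).  A
series is labelled random-coil-like when RMS/noise ≤ 2 and both |z| ≤ 2;
both thresholds are package conventions, configurable, and deliberately
conservative.

## The simulator

`gen_series` evaluates the chosen forward model (polynomial, two-state,
chained multi-state) on a pressure grid and adds i.i.d. Gaussian noise
from a seeded generator; the seed fully determines the output.  Defaults
mirror the experimental design: an 11-point grid from 1 to 200 MPa in
20 MPa steps, 283 K, and a noise SD of 0.002 ppm, a realistic
peak-position reproducibility for well-resolved signals at 800 MHz.
`gen_reference_like_dataset` draws coefficient sets with a controlled
B₁–B₂ correlation (B₂ = slope·B₁ + scaled noise) to exercise the
correlation analysis at known ground truth.

What the generator does *not* emulate: correlated noise from baseline
distortions, exchange broadening, peak overlap, temperature drift, or
slow/intermediate exchange regimes.  Passing recovery tests therefore
demonstrates the estimators' correctness under the stated noise model,
not robustness to every pathology of real spectra.

Problem sizes used by the test and reproduction scripts — 2000
replicates for interval coverage, 1000 parameter draws for the
shared-compression identity, 100 noisy replicates for two-state
recovery, 11–21-point grids — were chosen to pin each property within
sampling error while keeping a full run in the tens of seconds.

## Known limitations

* Coefficients are tied to the measurement conditions (283 K, pH 6.7,
  low ionic strength, protected termini); no temperature or field
  conversion is attempted.
* Backbone and ¹³C coefficients are accepted as extra tables but not
  shipped.
* M > 3 state fitting, global multi-atom fits, and exchange-regime
  lineshape effects are out of scope.
* δ₀ sequence corrections are not applied (see above).
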