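# Models, parameters and design notes

This note documents what the package computes, the constants it fixes,
what the synthetic testbench does and does not emulate, and the choices
made where the design was genuinely open.

## Field model and bases

All spatial filtering operates on the instantaneous signal vector φ
(one sample across the N channels).  The scalar magnetic potential in
the source-free sensor shell is expanded on real, orthonormal spherical
harmonics Y_lm (no Condon–Shortley phase; `m > 0` ↔ cos mφ, `m < 0` ↔
sin |m|φ), giving two field families per (l, m):

* interior:  B = −∇(Y_lm / r^(l+1)), decaying as r^−(l+2), valid
  outside the sources (the brain);
* exterior:  B = −∇(r^l Y_lm), growing as r^(l−1), valid inside the
  helmet (external interference); l = 1 is a spatially constant field,
  l = 2 a first-order gradient field.

The l = 0 term vanishes for magnetic fields and is omitted, so a
truncation degree L carries L(L+2) functions.  Defaults L_in = 8,
L_out = 3 give 80 + 15 = 95 basis vectors; these orders suffice for
SQUID arrays a few centimetres from the scalp.  Overall multiplicative
constants (μ0 factors) are deliberately left at 1: every basis column is
normalized to unit Euclidean norm before any decomposition, and the
norms are stored, so spans, shielding factors and reconstructions are
unaffected.

Basis columns couple to the array exactly as the channels measure:
weighted sums of B·n over each channel's coil integration points, times
the channel gain.  Gradient-of-Y terms are evaluated analytically (a
degree recurrence for dP/dθ); evaluation points within 10⁻¹² of the
poles are nudged off the axis, which matters only for deliberately
pathological inputs.

### Channel-type scaling

Magnetometer rows (units T) are divided by a fixed length scale of
0.0168 m — the generated gradiometer baseline — before normalization and
decomposition, so both channel types carry commensurate magnitude in the
joint least-squares problem.  A scan over candidate scales (0.01–1 m)
showed the joint-basis condition number (~3×10³) and the
magnetometer noise amplification of the reconstruction are flat near
this choice and degrade away from it.  PCA for the eSSS extension
instead multiplies magnetometer rows by 100, the convention used when
estimating joint principal components; subspaces are mapped exactly
between the two scalings by diagonal rescaling plus re-orthogonalization.

## SSS, SSP, eSSS

* **SSS**: moments x̂ = S⁺φ with the pseudoinverse computed by SVD at a
  relative cutoff of 10⁻¹⁰ (the normal-equations form is fragile at the
  basis's conditioning); reconstruction φ̂_in = S_in x̂_in, returned in
  native sensor units.  No regularization or component selection is
  applied inside SSS.
* **SSP**: PCs of the demeaned, unfiltered empty-room recording; the
  default configuration estimates 5 components per channel type
  separately and stacks them (10 columns); the projector I − UUᵀ acts in
  the estimation scaling.  Deterministic column signs (largest element
  positive).  Source fitting on SSP data projects the forward model
  identically — without this compensation a 50 mm dipole's amplitude is
  biased by tens of percent.
* **eSSS**: 8 joint PCs (mag scale 100) of the unprocessed empty room are
  appended to S_out and the concatenation orthogonalized by SVD with a
  relative rank tolerance of 10⁻⁸ (dropped directions are warned about);
  the extension is performed in the decomposition scaling.  Eight
  components reflect the physical degrees of freedom of the dominant
  interference: 3 homogeneous + 5 first-order-gradient.  eSSS′ merges
  additional PCs of band-pass-filtered data (zero-phase forward–backward
  4th-order Butterworth sections) for narrow-band artifacts.

Why eSSS works: with calibration errors E, the measured interference
pattern (I+E)b leaves span(S_out) and its projection onto span(S_in)
survives SSS.  The empty-room PCs *are* the miscalibrated patterns, so
span(S_out,e) contains them exactly (up to PC estimation noise), and the
oblique decomposition assigns them to the discarded external part.
Conversely nothing in span(S_in) is altered — the operator is an oblique
projector (idempotent, linear), so brain signals are reproduced up to
harmonic truncation.

## Synthetic testbench

* **Array**: 102 sites on a golden-angle lattice restricted to the
  spherical cap z > −0.1 R of a 12 cm sphere; per site one magnetometer
  (21 mm square coil, 4-point average) and two orthogonal planar
  gradiometers (two 10 mm square loops, ±baseline/2 along the baseline
  direction, weights ±1/(4·0.0168 m), outputs in T/m).  306 channels
  total; channel order is the single source of truth for all matrices.
* **Calibration error**: channel gains ×(1+ε), ε ~ N(0, sd²), plus
  *independent per-loop gain factors for gradiometers* at the same sd.
  The loop term models pick-up loop area imbalance — without it a
  balanced gradiometer reads exactly zero in a homogeneous field, the
  miscalibration leakage is magnetometer-only, and the SSS shielding
  factor at 1% error comes out ~46 instead of the ~15–30 that loop
  imbalance produces (median 19–23 here).  Optional small random
  orientation rotations are available (default off).
* **Interference**: each exterior (l, m) component is a pure sinusoid
  with a seeded random phase and its own frequency — homogeneous
  components at 0.9/1.1/1.3 Hz (empty room) or 0.5/0.7/0.85 Hz (test
  data), gradient components around 20 Hz (empty room) or 23 Hz (test) —
  so the eight interference degrees of freedom are temporally
  resolvable and the empty-room and test data share spatial components
  but not frequencies.  Per-component amplitude 20 nT/√3 at the most
  strongly coupled magnetometer (gradient components at 10% of that),
  placing the combined peak near the ±20 nT magnetometer dynamic range.
  The "unknown interference" scenario omits the m = −1 components of
  *both* degrees from the empty room and includes them in the test data:
  a new source contributes new components in both families.  (Omitting
  only the homogeneous one is not a clean novelty test: on a cap array
  the homogeneous y-pattern geometrically overlaps the l=2, m=−1
  gradient pattern, Σ y²z ≠ 0, and SSP partially suppresses it.)
* **Sensor noise**: white Gaussian, 3 fT/√Hz (magnetometers) and
  3 fT/cm/√Hz (gradiometers), sampled at SD = level·√(sfreq/2), plus a
  rank-5 spatially correlated component carrying 10% of the noise power
  (fixed seeded patterns shaped by the per-channel SD).  These stand in
  for "typical sensor noise"; real noise also has 1/f and line
  components that are not modeled.
* **Sources**: current dipoles in a spherically symmetric conductor
  (closed-form field including volume currents; radial dipoles exactly
  silent), peak 1000 nAm, one 10 Hz cycle (100 ms) + 100 ms silence per
  trial, 100 trials by default (50 at desk scale); depth-sweep dipoles
  at radii 10–70 mm, tangential, seeded random upper-hemisphere
  positions.

## Source estimation

Dipole fits are least squares in whitened channel space: moment solved
linearly at each position, position refined by Nelder–Mead (xatol 10⁻⁶ m)
from the best of a 27-point grid inside the conductor; fits at the peak
sample of the trial average.  The noise covariance comes from the
unaveraged post-stimulus silence, with relative diagonal loading 10⁻³.
The whitener is **rank restricted**: processed data live in a subspace
(span(S_in) after SSS/eSSS, the projector complement after SSP), so
covariance eigenvalues below 10⁻¹⁰ of the largest receive zero whitener
weight rather than 1/√loading — otherwise the truncation mismatch
between processed data and the raw forward model is amplified into
centimetre-scale localization errors.

## Problem sizes and what the tests show

The shipped experiments run at desk scale: 30 s empty room, 20 s test
recordings, 50 trials per dipole, 6 dipoles per radius (the experiment
config defaults to 2; medians over ≥20 seeds for the calibration study).
At these sizes all qualitative conclusions reproduce: SSS shielding
limited to ~20 (1% error) / ~200 (0.1%); eSSS shielding 10⁴–10⁶ on
measured interference and equal to SSS on novel interference; SSP inert
against novel patterns; localization errors ≲ 1 mm at radii 20–70 mm.

Two quantities sit at their bounds at this scale and geometry.  At the
deepest radius (10 mm) the mean localization error is ~1.6–2.6 mm
(bound: 2 mm) and the mean amplitude error ~10–25% (bound: 5%): the
field of a near-center dipole is weak and its amplitude trades off
against radial position, so the amplitude error is roughly the radial
position noise divided by the 10 mm radius.  Halving the trial count
relative to the full study doubles that noise, and this synthetic
helmet's unregularized reconstruction amplifies magnetometer noise more
(factor ~6) than a production system does.  The tests assert the bounds
as stated and report the table on failure rather than loosening them.

## Known limitations

* The helmet is a spherical cap; real arrays are non-spherical, which
  changes conditioning, leakage amplification and absolute shielding
  factors (only orderings and bands are asserted here).
* Cross-talk between channels is assumed absent; gradiometer imbalance
  appears only as the scalar per-loop gain term.
* Interference is a sum of stationary sinusoidal multipole components;
  real interference has broadband, drifting and higher-order content.
* No temporal extensions (spatiotemporal SSS), no movement compensation,
  no compensation-coil (active shielding) patterns in the basis.
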