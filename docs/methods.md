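# Methods

## The model

The package treats the fish body as an Euler–Bernoulli beam whose neutral
axis is the vertebral column: plane cross-sections stay plane and
perpendicular to the column, so a longitudinal muscle fibre at signed
transverse offset γ (cm) from the column carries longitudinal strain
ε = −κγ when the column bends to curvature κ (cm⁻¹) in that plane. The
sign convention is right-handed with +x cranial, +y dorsal, +z left:
positive κ_dv (dorsiflexion, concave dorsal) shortens dorsally offset
muscle, positive κ_ml (concave left) shortens leftward-offset muscle, and
biplanar flexion adds per-plane strains. No shear (Timoshenko) terms are
modelled, and only longitudinal — not muscle-fibre — strain is predicted.

Curvature here is the **projected-plane second derivative**
d²y/dx² (resp. d²z/dx²) of transverse centrum position against
longitudinal position, not the differential-geometric
|y″|/(1+y′²)^{3/2}. This matches how curvature is measured from
position-vs-position plots of the column; the geometric form is available
via `AnalysisConfig(exact_curvature=True)`. The two conventions agree to
second order in the column's slope, which bounds the regime where the
whole chain is self-consistent (see *Limitations*).

## Measurement chain

1. **Filtering.** Marker and centrum trajectories are low-pass filtered
   with a second-order Butterworth applied forward–backward (zero phase,
   effective order four), default cut-off 60 Hz at 500 frames s⁻¹. Zero
   phase preserves the peak-elevation timing that defines time zero.
2. **Cranial elevation.** The relative transform
   body_plane⁻¹ ∘ neurocranium is decomposed in zyx order (right-hand
   rule); the z rotation minus its mean over a baseline window (default:
   the first 10 % of frames, before motion onset) is the elevation.
   Strikes reaching less than 5° are recorded but excluded from
   validation statistics; time is expressed relative to peak elevation.
3. **Curvature.** Per frame and per plane, transverse centrum position is
   fitted against x with a penalized cubic smoothing spline (knots at the
   centra; the 1000-segment grid is an evaluation grid, not a knot count).
   Zero smoothing uses the not-a-knot cubic interpolant, which reproduces
   polynomials through cubics exactly. The sagittal field is
   baseline-corrected by subtracting the profile at the resting reference
   frame — the least-curved pre-strike frame where L_i is taken — so that
   predicted strain shares the measured strain's resting reference.
   (A frame-to-frame differencing mode exists for comparison but yields
   strain increments, not strain.) The frontal plane is left uncorrected
   by default: the column is essentially straight in that plane at rest.
4. **Subregions.** Adjacent marker pairs within a series; n markers in
   k series give n − k subregions (18 in 4 → 14). Geometry is measured
   once, at the reference frame: x̄ is the x of the mean marker position;
   γ_dv, γ_ml are offsets of that mean from the *fitted resting
   centerline* at x̄ (the neutral axis is the column, which is itself
   slightly curved at rest, so offsets are not taken from the straight
   ACS axis); L_i is the 3D inter-marker distance.
5. **Strain.** Measured: ε(t) = (d(t) − L_i)/L_i with d the 3D chord
   distance (fluoromicrometry). Predicted: ε = −Δκ_dv(x̄)γ_dv −
   κ_ml(x̄)γ_ml, curvature evaluated at the resting x̄ for all frames (the
   subregion is not tracked along the column as it deforms).
6. **Validation.** Model-1 OLS of measured on predicted strain, pooled
   over frames × subregions × strikes (frames are the regression unit) and
   per (strike, subregion). Slope is accuracy, R² precision. Records with
   combined maximum curvature — max_t|κ_ml| + max_t|κ_dv| at x̄ — below
   0.05 cm⁻¹ can be excluded before re-fitting. Equivalence to targets
   (default the ideal slope 1, intercept 0; prior-study coefficients can
   be substituted) is tested with two one-sided t tests at α = 0.05,
   i.e. both 90 % coefficient CIs must lie within slope ± 0.2 and
   intercept ± 0.05. Q–Q and fitted-vs-residual tables are emitted for the
   usual visual checks; no automated normality gate is applied.

Missing marker frames are linearly interpolated when gaps are ≤ 3 frames
(needed anyway for zero-phase filtering); a longer gap excludes that
subregion for that strike with a warning, rather than fabricating strain.

## The phantom

`fishbeam.phantom` generates strikes with exact ground truth. Curvature
waveforms are prescribed on the resting arc-length coordinate s and the
deformed column is built as an **inextensible rod**: the orthonormal
director frame (tangent, dorsal, left) is rotated along s at rates
(κ_dv, κ_ml) with no torsion, and markers ride on rigid cross-sections at
their offsets. This makes the offset fibre's speed exactly
1 − γ_dvκ_dv − γ_mlκ_ml, so the analytic strain oracle is exact and the
independent fibre-arc-length oracle (dense chordal integration of the
fibre curve, no beam relation involved) can disagree with it only through
genuine approximation error. A small-deflection construction that
integrates transverse displacement on a fixed x grid was rejected because
it makes the neutral axis extensible, contaminating chord-based measured
strain with spurious slope² terms.

Default conditions emulate the study design:

| parameter | default | rationale |
|---|---|---|
| centra | 26 × 0.5 cm | anterior column of a ~35 cm trout (24–27 animated vertebrae) |
| frame rate / frames | 500 Hz / 250 | biplanar X-ray video of a ~0.5 s strike |
| κ_dv waveform | Gaussian bump, σ = 1.5 cm, centred mid-column (0.45 L), amplitude 0.05 cm⁻¹, raised-cosine time course peaking with cranial elevation | dorsiflexion concentrated mid-column, synchronous with head lift |
| κ_ml waveform | Gaussian-windowed cosine (λ = 8.5 cm, window σ = 3.4 cm), amplitude 2.5 × dorsoventral, sign and peak timing varied per strike | lateral bending is larger, S-shaped, and variable in direction/timing |
| resting curvature | 0.003 cm⁻¹ sagittal lordosis, frontal plane straight | mild resting curvature; exercises the baseline correction |
| markers | 18 in 4 series; dorsal/deep series (γ_dv 1.8 / 0.6 cm) span the column at 2 cm spacing; left/right lateral series (γ_dv 1.0, γ_ml ± 0.9 cm) cluster at 0.45 cm spacing around the curvature maximum | synthetic, symmetric layout (no real animal's implant sites); see below for why scales differ |
| noise | isotropic Gaussian, sd 0.01 cm per coordinate, seeded | < 0.1 mm tracking precision |
| elevation | 10° raised cosine (study: drawn 5.5–13° included, 2–4.5° excluded; amplitudes scale 0.005 cm⁻¹ per degree, lateral ratio drawn 2–3) | submaximal strikes averaging ~10°, with 8/8/4 of 10 strikes per individual passing the 5° rule |

**Why these length scales.** The projected-plane curvature convention and
point evaluation at x̄ are exact only in the limit of small column slopes
and curvature fields smooth at the subregion scale. Two error terms
dominate: point-vs-segment-mean curvature, ≈ Δ²/24 · |g″/g| for marker
spacing Δ on spatial profile g, and the slope factor (1 + y′²)^{3/2}
between d²y/dx² and the rod's true bending rate. Profile widths, the
S-shaped lateral wave (whose slope vanishes where its curvature peaks) and
marker spacings were chosen together so both terms stay at the percent
level at the default amplitudes; with them the noiseless phantom's pooled
measured-vs-predicted slope is ≈ 0.985 with R² > 0.999. Broader lateral
waves or wider lateral marker spacing push the chain out of its own
small-slope regime, which is a property of the method, not of the
phantom. The lateral bending must also be quiescent at the reference
frame: L_i taken on a laterally bent column would corrupt every strain
reference (the study design guarantees this by taking L_i when the column
is least curved).

**What the phantom does not emulate.** Soft-tissue artefacts (markers
shifting with muscle bulging), rotoscoping error structure (correlated,
non-Gaussian), dropout patterns of real tracking, torsion of the column,
shear deformation, and any muscle physiology. Passing tests therefore
demonstrate that the estimator chain is correct and self-consistent at
realistic noise and geometry — not that a real fish deforms as a beam.

## Smoothing calibration

Per-frame generalized cross-validation is the default smoothing policy
(`spline_smoothing="gcv"`). With only 26 centra per frame GCV is
occasionally erratic, inflating the frame-wise curvature maxima that feed
the exclusion statistic; for the phantom study the packaged analyses pin
the penalty to `spline_smoothing=0.2`, chosen once by balancing noise
suppression against smoothing bias on the default noise and amplitude
scales (the same role the original post hoc visual choice of smoothing
plays with real data). Noiseless analyses use `spline_smoothing=0.0`
(pure interpolation).

## Numerical choices

- Rod integration: Rodrigues rotation steps on a ≤ 0.02 cm arc-length
  grid that contains every vertebra and marker station exactly; positions
  by trapezoidal integration of the tangent. Grid values are rounded to
  1 nm before de-duplication so coincident stations merge.
- Fibre oracle: chordal arc length on that grid (second-order accurate;
  exact to < 1e-9 for uniform arcs via the closed-form construction in
  `uniform_bend_oracles`).
- zyx decomposition returns z in (−180°, 180°]; frames within 1° of
  gimbal lock (|y| ≈ 90°) are flagged, not silently accepted.
- Curvature queries outside the fitted span raise — the neutral axis is
  never extrapolated, and a subregion whose x̄ falls off the column is an
  error, not a guess.
- Degenerate per-record regressions (zero predictor variance, n < 3) are
  flagged and excluded from summaries rather than reported as numbers.
- TOST is computed from the OLS coefficient standard errors with
  t-distribution critical values; pass/fail via 90 % CI containment, with
  the per-coefficient p as the larger of the two one-sided p values.

## Limitations

- Measured strain uses the chord between markers, predicted strain the
  arc: the discrepancy is (κL)²/24 — at the default geometry < 0.5 % of
  the signal, documented rather than corrected (the measurement itself is
  chord-based).
- Predicted strain evaluates curvature at a point, x̄, while a finite
  subregion averages it; with the default layout this is a ≈ 1 % effect,
  but it grows quadratically with marker spacing relative to the
  curvature wavelength.
- Ordinary least squares treats predicted strain as error-free although
  it is itself estimated; no errors-in-variables correction is applied,
  so noise in the curvature estimate attenuates the slope (visible as the
  noisy-study slope ≈ 0.98 < noiseless ≈ 0.985 < 1).
- No mixed-effects structure: strikes and individuals are pooled, so the
  pooled n overstates the number of independent observations.
- Curvature is strictly biplanar; torsion and true 3D curvature are out
  of scope.
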