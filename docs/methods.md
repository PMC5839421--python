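# Methods

This note documents the models and numerical choices behind `odatlas`, the
parameters that matter, what the synthetic phantoms do and do not emulate,
and the known limitations.

## Pose normalization

Landmarks are 0-based pixel-centered (x right, y down).  The pose angle is
`α = arctan((y_OD − y_mac)/(x_mac − x_OD))`, so a macula below the OD gives a
negative angle; angles live in [−π/2, π/2] and are averaged arithmetically
(no circular mean is needed on that interval).  The similarity transform
`A x = s R(α − α_avg) x + T` is exact on landmarks by construction: the
translation is chosen so the OD center lands on the population-mean OD
center to machine precision, and the macula then lands at the mean distance
and angle automatically.  Image resampling is bilinear with constant (0)
padding; every patch records a pad mask flagging pixels with any
out-of-image contribution so downstream statistics can exclude them.  The
crop window is centered on the mean OD center; with an even patch size the
window sits half a pixel off the integer grid, which is inherent and
harmless.  Images whose macula falls outside the field of view are rejected
at landmark validation rather than guessed.

## Four-cluster representation

Labels {background, rim, cup, vessel} are encoded for registration at
evenly spaced intensities (0, 1/3, 2/3, 1, configurable): equal spacing
gives every boundary a comparable gradient magnitude and hence comparable
demons forces.  Label priority is vessel > cup > rim.

**Cup fit.** The cup is the ellipse maximizing the *signed* outward radial
gradient of the (smoothed, channel-averaged) intensity along its boundary —
the cup is brighter than the rim, so the true boundary has intensity falling
outward.  The signed objective is deliberate: an unsigned gradient-magnitude
objective is attracted to the strong edges of vessels crossing the disc,
whereas vessel crossings contribute alternating signs to the signed mean and
cancel.  The optimizer is a coarse grid over axes (0.25–0.85 of the disc
radius) and orientation (15° steps) about the disc centroid, refined by
Nelder–Mead over (center, axes, orientation); center excursions beyond
±20 px from the centroid are rejected back to the grid solution.  On
phantoms this recovers the cup to < 0.2 px; the tests assert the looser
2 px / 0.1 rad.

**Vessels.** 3-class K-means on RGB triples inside the disc dilated by 10%
of its radius (so rim-boundary vessels are included); the vessel cluster is
the one with the lowest mean green intensity — vessels have maximal contrast
in green, and "dark red" needs a metric to be operational.  Population
filtering: each subject's (disc + vessels) encoding enters the average-model
construction; subjects' binary vessel masks warped by the final velocity
fields are averaged into a per-pixel vessel frequency, and the simplified
model keeps pixels with frequency strictly above 0.75.  Strictness matters:
at a 10-subject population the achievable frequencies are multiples of 0.1,
so the retained minimum is 0.8.

## Log-demons registration

Stationary velocity fields are `(2, H, W)` arrays ((y, x) component order,
matching numpy indexing); `exp(v)` is computed by scaling and squaring with
the step count chosen per field so the scaled displacement is below 0.5 px,
and compositions use bilinear interpolation.  The demons force uses
pixelwise (not global) norms in the denominator and is capped at 2 px per
iteration to keep label edges stable.  Regularization is
`v' = (v + u ⊛ K_fluid) ⊛ K_diff` with σ_fluid = σ_diff = 1.5 px (reflective
boundaries, kernels truncated at 4σ); the additive update is the first-order
Baker–Campbell–Hausdorff approximation, accurate for the capped updates used
here.  Multiresolution runs 3 levels (factor 2) with iteration budgets
(30, 30, 20) coarse→fine; a level stops early when the mean update magnitude
falls below 0.01 px, and if the SSD energy rises for 5 consecutive
iterations the best field seen is kept (this guard fires occasionally on
piecewise-constant images and is benign).  Velocities are upsampled between
levels with their values scaled by the resolution factor.

Verification: `exp` agrees with 4th-order Runge–Kutta integration of
dφ/dt = v(φ) to < 0.05 px RMS; exp(v)∘exp(−v) ≈ id; one-parameter-subgroup
consistency; positive Jacobian for every field the test suite produces;
warping agrees with SimpleITK's displacement-field resampler to 1e−6.

## Average model

Guimond-style iteration: register all subjects to the current reference,
average the warped intensities, compose with `exp(−mean(v_i))` (velocity
fields form a vector space, so averaging and inversion are exact), repeat.
The stopping rule is a mean per-pixel norm of the average velocity field
below 0.1 px (reported alongside the looser 0.5 px check the convergence
experiments use); at most 10 outer iterations.  After convergence every
subject is re-registered once to the final model so stored velocities map
subject → atlas exactly.  The RGB average model is the population *mean* of
warped patches — the only convention consistent with the scalar averaging.
Reference choice is a caller-specified index (default 0);
`reference_robustness_check` quantifies its (small) influence as pairwise
RMSE between models built from different references.

## Statistics and descriptor

The variance field is the second moment about zero, σ²(x) = (1/N) Σ|v_i(x)|²
— no mean subtraction, because the construction drives the mean field to ≈ 0.
PCA, in contrast, mean-centers: modes come from the N×N Gram matrix of the
centered flattened fields, are lifted back to field shape, unit-L2-
normalized (so projections are in pixels), sign-fixed (largest-magnitude
entry positive) and sorted by descending eigenvalue; at most N−1 modes are
nonzero and all are retained by default.  The deviation map divides the
velocity vector by σ (not σ²) where σ > ε = 0.05 px and is zero elsewhere;
`d_avg`/`d_max` are taken over the whole patch by default, optionally over a
caller-supplied region.  The descriptor of a new image registers its
representation onto the average model with the same demons configuration the
atlas used.

## Synthetic phantoms

Phantoms emulate the anatomy the pipeline analyses: an elliptical disc
(semi-axes 0.30/0.33 of the patch, vertical major axis), a smaller slightly
temporal cup, three vessel branches (superior and inferior arcades, a nasal
trunk) of width ≈ 0.028·m, fundus-like colors, Gaussian intensity noise
(sd 0.02) and a macula landmark.  Deformed subjects are produced by warping
the *continuous* level maps (normalized ellipse radius, signed vessel
centerline distance) and re-thresholding, which keeps boundaries accurate to
interpolation rather than to mask quantization — at the small deformations
typical of a healthy population this materially lowers the registration
noise floor.

The two default healthy modes are broad smooth fields: a Gaussian-windowed
expansion about the disc center (σ = 0.29·m; joint disc-and-cup enlargement)
and a horizontal shift windowed slightly nasal of the disc center
(σ = 0.31·m; nasal displacement of vessels and OD content), orthogonalized
and scaled to unit peak displacement, with amplitude standard deviations of
2.5 and 1.8 px.  Broad modes are a modelling decision, not a convenience: a
velocity component supported where the piecewise-constant representation has
no gradient produces *no* observable image change, so no intensity-driven
registration can recover it; planting such components would make "mode
recovery" ill-posed by construction.  The pathology direction is
deliberately more local — an inward ring field at the cup boundary plus a
tighter nasal shift over the vessel trunk (default amplitude 3 px) — so
pathological deformation concentrates where healthy variability is low.
Draws whose exponential would fold (non-positive Jacobian) are rejected and
resampled.

What the phantoms do **not** emulate: photometric variability
(illumination, camera differences), peripapillary atrophy, hemorrhages,
vessel branching variability beyond one optional cilioretinal-style branch,
and segmentation errors of an upstream disc segmenter.  Passing tests
therefore demonstrate the correctness and statistical behavior of the
pipeline under controlled geometry, not clinical performance.

## Problem sizes and experiment conditions

The shipped experiments run at desk scale, chosen once: atlas convergence on
20 phantoms at 192×192 with free smooth deformations of peak amplitude
≤ 5 px; the vessel filter on 10 subjects at 192×192 with an extra branch in
30% of them; mode recovery and healthy/pathological discrimination on
30-subject populations at 96×96 (30 healthy + 30 pathological held out for
discrimination, amplitude 3 px pathology).  Seeds are fixed in the test
suite (42 for the population draws) so results are reproducible.

## Known limitations

- Registration recovers deformation only where the representation has
  gradients; the deviation map is uninformative deep inside uniform regions.
- The demons energy on piecewise-constant images is noisy at small
  amplitudes (< ~1 px); descriptors of near-identical images carry a noise
  floor of that order.
- The atlas mean-field norm occasionally stalls just above the 0.1 px
  tolerance on mode-structured populations (≈ 0.15 px); the model is
  reported with a warning and is well below the 0.5 px convergence bound.
- log-demons is not symmetric: registering A→B and B→A gives fields whose
  sum is small but not zero (≤ 30% of the field norm on smooth phantoms).
- The pipeline consumes external OD/macula landmarks and disc masks;
  localization and disc segmentation are out of scope.
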