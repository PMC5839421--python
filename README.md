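# odatlas — statistical optic-disc atlas and shape descriptor

Changes in the geometry of the optic disc (OD) region — enlargement of the
cup, narrowing of the neuroretinal rim, nasal displacement of the blood
vessels — are early signs of glaucoma and other optic neuropathies, but the
clinical indices used to grade them (cup-to-disc ratio, ISNT rule) reduce
the whole geometry to one or two numbers and miss subtle or local change.
`odatlas` instead characterizes the *full* deformation of the OD region
statistically: it builds an atlas of healthy OD anatomy by diffeomorphic
registration and measures how far a new image deviates from the healthy
variability, locally and per deformation mode.  It is written for
researchers in retinal image analysis who have fundus patches with OD/macula
landmarks and disc segmentations and want a shape descriptor richer than a
cup-to-disc ratio.

## Method

1. **Pose normalization.** Right eyes are mirrored into left eyes; each
   image is mapped into the population-mean pose by a similarity transform
   with scale `s = d_avg/d_i`, rotation `α_i − α_avg` and a translation
   fixing the OD center, where `α_i = arctan((y_OD − y_mac)/(x_mac − x_OD))`
   and `d_i` is the macula–OD distance.  An `m×m` patch centered on the OD
   is extracted (default m = 384).
2. **Four-cluster representation.** Each patch is reduced to labels
   {background, rim, cup, vessel}: the cup as the ellipse maximizing image
   gradients along its boundary, vessels by 3-class K-means in RGB space,
   then filtered to the *statistically significant* vessels — those whose
   registered-vessel frequency in a vessels average model exceeds 75%.
3. **Diffeomorphic registration.** Pairs of representations are registered
   with the log-demons algorithm on stationary velocity fields `v`: the
   demons force `u = ∇R̃ (R − R̃) / ((R − R̃)² + |∇R̃|²)` is alternated with
   fluid (σ = 1.5 px) and diffusion (σ = 1.5 px) Gaussian regularization in
   a 3-level multiresolution scheme; deformations `φ = exp(v)` are computed
   by scaling and squaring and are folding-free (positive Jacobian).
4. **Unbiased average model.** Starting from an arbitrary reference, every
   subject is registered to the current reference, warped intensities are
   averaged, and the result is composed with `exp(−mean(v_i))`; iteration
   stops when the mean velocity field is a null displacement (typically a
   few iterations, always < 10 on the suites shipped here).
5. **Atlas statistics and descriptor.** The variance field
   `σ²(x) = (1/N) Σ |v_i(x)|²` maps local geometric variability; PCA on the
   flattened velocity fields (computed via the N×N Gram matrix) yields the
   principal deformation modes.  A new image is registered onto the average
   model and summarized by the atlas-based shape descriptor
   `ASD = [d_avg, d_max, p_0, …, p_{N−1}]`, where `d = v_new/σ` is the local
   deviation map and `p_j` the projection of the velocity field onto mode j.

Everything is testable offline: `odatlas.synthetic` renders OD phantoms
(elliptical disc and cup, vessel branches, macula landmark) with exact masks
and deforms them by *known* diffeomorphic modes, so atlas construction, mode
recovery and healthy/pathological discrimination run against ground truth.

## Worked example

`examples/02_build_atlas.py` builds an average model from 10 phantoms
warped by smooth random deformations:

```
population: 10 subjects, converged=True
  iteration 0: mean field norm 0.472 px, mean residual 13.0
  iteration 1: mean field norm 0.079 px, mean residual 4.6
peak local variability: sigma=1.46 px
top deformation modes explain [0.371 0.241 0.143 0.114] of the variance
```

The mean velocity-field norm dropping below 0.1 px means no residual
displacement separates the model from the population barycenter; the
registration residual halves as subjects align onto it.
`examples/03_shape_descriptor.py` then describes a held-out healthy phantom
and one with a planted pathology (localized cup enlargement + nasal vessel
shift):

```
healthy      d_avg=0.559 d_max=0.714 p0,p1=[-122.9   31.3]
pathological d_avg=0.626 d_max=1.683 p0,p1=[ 58.7 146.7]
```

`d_max` — the largest local deviation in units of healthy variability — is
2.4× larger for the pathological disc: its deformation is big exactly where
healthy discs barely vary.  The other examples demonstrate pose
normalization (`01`) and the statistically-significant-vessel filter (`04`).

A thin CLI wraps the same pipeline for shell use:

```bash
odatlas phantom --n 20 --seed 1 --out pop/
odatlas build-atlas --manifest pop/manifest.csv --out atlas.h5
odatlas describe --atlas atlas.h5 --labels pop/subj003_labels.png --out desc/
```

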