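# Methods

This note records the models implemented in `junctionzone`, their assumptions,
the design of the synthetic-cohort generator, and the numerical choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Normative model and standardization

Thickness maps are standardized per pixel against a reference set of
non-atrophic eyes: `z(x) = (t(x) − β₀(x) − β₁(x)·age) / σ(x)`.

* **Linear age model.** Each pixel gets an ordinary least-squares fit of
  thickness on age; σ(x) is the residual SD (ddof = 2). Aging of the
  photoreceptor laminae over the 55–95-year range covered here is close
  enough to linear that anything richer would be unidentifiable from a
  few dozen reference eyes; the model sits behind the `NormativeModel`
  interface and can be swapped.
* **Homoscedastic in age.** One SD map, independent of age. The SD describes
  location-specific between-eye variability, which dominates any age trend in
  spread at these sample sizes.
* **SD floor, default 1 µm.** Guards the division at low-variance pixels;
  purely numerical.
* **Laterality.** Left eyes are mirrored to right-eye orientation before
  fitting and standardization, because retinal topography is
  nasal/temporal-asymmetric. The synthetic topography includes a deliberate
  asymmetric term so that mishandled mirroring is caught by tests.
* **Extrapolation.** Standardizing an eye whose age falls outside the
  reference range warns but proceeds — a real cohort routinely contains a few
  such eyes and dropping them silently would bias the analysis population.

Self-standardization of the training set yields per-pixel mean ≈ 0 and
SD ≈ 1 up to small-sample error (tolerance 3/√n in the tests).

## Contour-ring geometry

* **Distance definition.** Exact Euclidean distance transform (EDT) from each
  extra-lesional pixel center to the nearest lesion pixel center, converted
  to degrees by the pixel pitch. Iterated morphological dilation (the other
  natural reading of "dilation") is available behind `method="dilation"` for
  comparison; its 8-connected generations measure Chebyshev distance, which
  underestimates Euclidean distance by up to √2 and makes outer rings
  anisotropic — the EDT is the default for exactly that reason, and has a
  clean brute-force oracle (KD-tree nearest-lesion-pixel search in the
  tests).
* **Annuli, not 1-pixel contours.** Ring k is the half-open band
  ((k−1)·w, k·w] with w = 0.43°, so the rings partition the near field and
  every extra-lesional pixel within K·w contributes to exactly one ring.
  The boundary pixel row (distance 0) is the lesion itself and belongs to no
  ring.
* **Bin-edge ties.** Quotients d/w within 1e-9 of an integer are snapped
  before `ceil`, so pixels lying exactly on a band edge bin identically
  regardless of floating-point evaluation order.
* **Frame clipping.** A ring whose nominal annulus extends past the image
  frame is flagged `frame_clipped`; its mean uses the pixels that remain.
  Empty rings are omitted with a warning rather than padded.
* **Multifocal lesions.** Distance is taken to the union of all foci, so
  bands fuse naturally as foci grow together.
* **Units.** 291 µm/° (emmetropic scale), making the 2.58° and 5.16°
  contour-lines 751 µm and 1502 µm. Native anisotropic B-scan spacing is out
  of scope: inputs are assumed resampled to isotropic en-face grids.

## Longitudinal mixed models

Per layer × contour-line, on follow-up visits only (no imputation; eyes
missing a visit contribute no row):

```
change_z ~ arm + baseline_z + visit + arm:visit,  (1 | participant)
```

REML estimation via statsmodels `MixedLM`. Numerical notes:

* The response is internally rescaled to unit variance before optimization
  (REML variance components are equivariant under response scaling); the
  fixed-effect GLS step and all inference are then recomputed on the raw
  scale from the closed-form random-intercept likelihood (Woodbury identity
  per participant block). Ring means are precise enough that raw-scale
  variances can be ~1e-3, which destabilizes the profiled optimizer
  otherwise.
* Saturated, noise-free data drive σ̂² to zero; a vanishing floor
  (1e-10 × response variance) keeps the GLS limit defined.
* Singular fits (τ̂² ≈ 0) are flagged on the result, not refit silently.

**Degrees of freedom.** Satterthwaite: df = 2·g²/(∇g' A ∇g) with
g(θ) = c'Φ(θ)c, Φ the fixed-effect covariance, and A the inverse observed
REML information of θ = (τ², σ²), computed from the closed-form restricted
likelihood with boundary-aware finite differences. The Kenward-Roger
approximation was the natural alternative; for the balanced random-intercept
designs generated here the two agree closely, and the test suite verifies the
contrasts, df, adjusted p-values and CIs against R `lme4`/`emmeans` with
Kenward-Roger df directly.

**Familywise adjustment.** Single-step (Tukey) over the 3 pairwise arm
contrasts: p_adj(j) = P(max|T| ≥ |t_j|) under the central multivariate t with
the contrasts' estimated correlation matrix, with the family df taken as the
mean of the per-contrast Satterthwaite df. The 3-contrast correlation matrix
is singular (the third contrast is the difference of the other two), which
generic CDF quadratures mishandle; the distribution of max|T| is therefore
evaluated by a seeded 400 000-draw Monte Carlo in the rank-reduced eigenbasis
(p-value error < 1e-3, deterministic given the fixed internal seed).
Confidence intervals use the same equicoordinate critical value, so intervals
and p-values are consistent with each other, and with how `emmeans` reports
a Tukey-adjusted family. Adjusted p-values are floored at the unadjusted
two-sided p.

**Growth model.** Change in √area from baseline with arm, baseline √area,
visit, arm×visit and baseline×visit fixed effects, random intercept.
"Percent slowing" of a treatment arm is reported two ways — from the
month-12 least-squares-mean change and from a continuous-time refit
(per-arm slope in mm/y) — because a percentage can legitimately be read off
either; the two agree in expectation under linear growth.

**Bland–Altman.** bias = mean(x−y), t-based CI with n−1 df, limits of
agreement bias ± 1.96·SD. Convention is computed-minus-reference.

## Analysis populations

* mITT: study eyes with ≥ 1 injection and ≥ 1 follow-up at month 2+.
* PP: mITT ∩ received ≥ floor(0.75 × expected injections) before month 12
  (9 of 12 on the monthly schedule, 4 of 6 every-other-month).
* PP without exudation: PP, dropping all visits of eyes that ever developed
  exudation.
* Fellow: fellow eyes without macular neovascularization and baseline
  atrophy ≥ 2.5 mm².

The main grid runs mITT, PP and fellow (27 models); the exudation-excluded
population is a supplementary grid. Fellow-eye models reuse the study-eye
fixed-effect structure with the participant's randomized arm, which doubles
as a specificity check: the drug reaches only the injected eye, so fellow
contrasts should be null.

## Synthetic cohort generator

The generator is first-class, tested code that defines the study conditions
for every downstream test. Per eye and visit, thickness is

```
t(x) = μ_layer(x, age + t) + σ_layer(x) · z(x, t)
z(x, t) = b_eye + v_visit − D(t)·K(d(x, t)) − u_eye·δ_arm·t + ε(x)
```

* Topographic mean surfaces with a foveal peak and a temporal asymmetry;
  layer age slopes −0.20/−0.05/−0.10 µm/y (ONL/IS/OS).
* **Junctional kernel** K(d) = 0.6·e^(−d/0.7°) + 0.4·e^(−d/3°): a steep
  gradient inside ~2° of the boundary and a shallow tail beyond, with
  baseline depth 2 z at the boundary.
* **Progression.** The junctional depth accrues at an arm-specific rate and a
  diffuse macula-wide drift δ_arm acts everywhere; both are scaled by a
  per-eye rate factor u ~ N(1, 0.3). Defaults (sham accrual 1.5 z/y at the
  boundary, drift 0.25 z/y; monthly 0.3/0.05, every-other-month 0.42/0.07)
  imply a month-12 monthly-vs-sham contrast of ≈ +0.29 z at the 5.16°
  contour-line — the effect size the analysis is meant to detect.
* **Lesion growth** is linear on the √area scale: sham 0.30 mm/y (the value
  implied by a 0.076 mm/y arm difference being a 25% slowing), reduced 25%
  (monthly) and 22.2% (every-other-month), with per-eye SD 0.08 mm/y.
  Circular foci (optionally two, placed apart at baseline) grown on the
  radius keep √(πr²) linear and the ring geometry analytically checkable.
* **Noise structure.** Per-pixel i.i.d. noise (0.4 z), a per-eye intercept
  (0.3 z), and a per-acquisition visit offset (0.15 z). The intercept cancels
  in change-from-baseline; the shared baseline acquisition error is what the
  LMM's random intercept actually estimates, and the visit offsets set a
  realistic floor on contrast precision (CI half-widths ~0.15 z at 20
  eyes/arm, matching the scale of a real trial rather than the unrealistic
  precision that averaging thousands of pixels per ring would otherwise
  imply).
* **Fellow eyes**: frozen lesion, frozen junctional depth, no drift — only
  noise terms — so fellow analyses are a true negative control.
* **Population structure**: compliance, follow-up loss and exudation flags
  drawn at configurable rates (8%/3%/10%) to exercise the filters; the
  manifest carries a reference (autofluorescence-style) baseline √area set
  0.02 mm below the lesion truth with 0.02 mm noise, giving the agreement QC
  a known bias to recover.
* Sham arms are generated pooled under one label, as they are analyzed.

Everything derives from one `numpy` Generator seeded from the config, so a
config + seed reproduces rasters and manifests bit for bit.

### What the generator does not emulate

Speckle and B-scan-level artifacts, segmentation errors (inputs are
thickness maps, not volumes), informative dropout, subretinal drusenoid
deposits or other focal pathology unrelated to the junctional zone, axial-
length variation in the °→mm scale, and device differences. Passing tests
therefore demonstrate that the pipeline measures what this data-generating
model produces — junctional-gradient thinning with dose-dependent
attenuation — not that any particular clinical dataset satisfies those
assumptions.

## Problem sizes

Unit and acceptance tests run at 5–20 eyes/arm on 100×100 to 200×200 grids;
the Monte-Carlo calibrations use the ring-level simulator (the same
data-generating model without rasters: 200 replicates for effect recovery
and CI coverage, 500 for null familywise error, 30 for growth-reduction
recovery), because the sampling distribution of the estimators depends on the
ring-level model only, while the raster path is verified separately by exact
oracle equivalence and end-to-end runs. `scripts/acceptance.py` uses 60
study eyes on 200×200 grids for the raster pipeline and 150 eyes/arm for the
growth percentage.

## Known limitations

* The Satterthwaite default can diverge from Kenward-Roger in strongly
  unbalanced designs; the optional comparison path is the R cross-check, not
  an in-package Kenward-Roger implementation.
* Ring means weight pixels uniformly; A-scan-density weighting on native
  anisotropic grids is not implemented.
* The normative model is linear and homoscedastic in age by design; sex and
  axial length are not modeled.
* Percentage growth slowing is a ratio of estimates; its sampling noise at
  trial-scale n is several percentage points, so single-cohort values
  scatter around the configured truth.
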