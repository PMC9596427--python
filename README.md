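# junctionzone

Quantifying photoreceptor degeneration *beyond* the atrophy boundary in eyes
with geographic atrophy (GA), from en-face OCT layer-thickness maps.

GA trials traditionally track the area of retinal pigment epithelium (RPE)
atrophy. But photoreceptors also thin outside the lesion — steeply in the
junctional zone immediately around the boundary, and diffusely across the
macula. `junctionzone` implements the full analysis pipeline needed to measure
that thinning longitudinally and test whether a treatment slows it, plus a
synthetic-cohort generator that emulates a sham-controlled trial so every stage
is testable end to end without patient data. It is aimed at ophthalmic imaging
and trial-methodology researchers.

## Method

1. **Normative z-score standardization.** Photoreceptor laminae thickness
   (outer nuclear layer ONL, inner segments IS, outer segments OS) varies
   strongly with retinal location and age. Each A-scan position *x* of a map
   *t* is standardized against a reference set of non-atrophic eyes:

   z(x) = ( t(x) − μ(x, age) ) / σ(x),

   with per-pixel linear age model μ(x, age) = β₀(x) + β₁(x)·age and
   location-specific residual SD σ(x).

2. **Traveling contour-rings.** The extra-lesional map is partitioned into
   evenly spaced distance bands of width w = 0.43° around the current GA mask
   (exact Euclidean distance transform; ring k covers distances
   ((k−1)·w, k·w]). Rings 1, 6 and 12 are the 0.43°, 2.58° and 5.16°
   contour-lines (126/751/1502 µm at the emmetropic scale of 291 µm/°).
   Rings are recomputed at every visit, so they travel outward as the lesion
   grows and the extracted features are independent of the atrophy growth
   rate itself.

3. **Change-from-baseline mixed models.** Per layer × contour-line:

   Δz ~ arm + baseline z + visit + arm:visit, (1 | participant),

   fitted by REML with visit categorical. Pairwise arm contrasts at each
   visit get Satterthwaite denominator degrees of freedom and single-step
   (Tukey) multivariate-t adjustment of p-values and confidence intervals for
   the family of 3. The full grid is 3 contour-lines × 3 layers ×
   3 populations (mITT, per-protocol, fellow eyes) = 27 models; the primary
   cell is the ONL 5.16° month-12 monthly-vs-sham contrast.

4. **Supporting analyses.** A mixed model for change in √area quantifies
   atrophy growth and per-arm percentage slowing; Bland–Altman agreement
   compares mask-derived √areas against a reference measurement.

## Worked example

```python
import junctionzone as jz

cfg = jz.TrialConfig(n_per_arm=20, seed=7)      # 60 study eyes, 3 arms
report = jz.run_full_analysis(config=cfg)

p = report.primary_outcome
print(f"models fitted: {report.n_models}")
print(f"primary outcome ({p['cell']}): {p['estimate']:+.2f} z "
      f"[{p['ci_low']:.2f}, {p['ci_high']:.2f}], adjusted p = {p['p_adjusted']:.2g}")
print(f"sqrt-area growth slowing, monthly vs sham: "
      f"{report.ga_progression.reduction_pct_slope['monthly']:.0f}%")
```

prints

```
models fitted: 27
primary outcome (ONL 5.16deg month-12 monthly - sham_pooled): +0.37 z [0.22, 0.51], adjusted p = 3.7e-08
sqrt-area growth slowing, monthly vs sham: 20%
```

Here +0.37 z means the monthly-treated arm retained, on average, about a third
of a normative standard deviation more ONL tissue along the (traveled) 5.16°
contour-line at month 12 than sham — the generator injects a true effect of
+0.29 z, and a single 60-eye cohort estimates it with a CI half-width of
~0.15 z. The growth slowing recovers the configured 25% up to sampling noise.

The same stages are available from the shell:

```sh
junctionzone simulate --seed 1 --out-dir run/data
junctionzone extract  --data-dir run/data --out run/features.csv
junctionzone report   --data-dir run/data --out-dir run/report
junctionzone all      --seed 1 --out-dir run      # everything at once
```

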