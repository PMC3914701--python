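# cardiatlas

Automated cardiac phenotyping for high-resolution left-ventricular (LV)
imaging: multi-atlas patch-based segmentation of 3D cine volumes,
wall-thickness mapping at anatomically corresponded surface points, and the
voxelwise statistics — test-retest reliability, per-point sample-size maps,
Bonferroni-corrected significance maps — that quantify how much imaging
resolution buys in statistical power.

The intended users are imaging scientists studying regional myocardial
phenotypes (e.g. the wall-thickness patterns of left-ventricular
hypertrophy) in populations, where conventional thick-slice 2D short-axis
stacks (8 mm sections, 2 mm gaps) blur the base and apex and inflate
test-retest variance, while isotropic-ish 3D acquisitions (~2 mm sections)
resolve them. The package makes both the image-analysis chain and the
power arithmetic reproducible on fully synthetic phantoms with analytic
ground truth, so every stage is testable without scans.

## Method

**Segmentation.** A target grayscale volume is segmented by patch-based
label fusion against a pool of labeled atlases. After a six-landmark
similarity alignment, every target voxel collects label votes from the
best-matching atlas patches inside a local search window, weighted by

```
w = exp(−SSD / (h² n)) · exp(−‖offset‖² / s²)
```

(the non-local-means form: a Gaussian in the mean squared intensity
difference between 5 × 5 × 5 mm patches, times a Gaussian in the candidate's
physical displacement). The fused label is the argmax of accumulated vote
mass. Cavity volume and myocardial mass follow by voxel counting at a
myocardial density of 1.05 g/mL.

**Thickness.** Endocardial and epicardial surfaces are extracted by
marching cubes; a mean-shape template built from the atlas pool is
registered to each subject (similarity + iterative-closest-point
projection), giving every subject the same P surface points. Wall thickness
at point *k* is measured along the normal of the midwall surface (the
pointwise endo/epi midpoint): the distance between the endocardial and
epicardial crossings of that normal line.

**Power.** Treating the P myocardial points independently with Gaussian
test-retest differences, the per-group sample size needed to detect a
thickness change δ at point *j* with two-sided level α and power p is

```
N_j = 2 f(α, p) σ_j² / δ²,     f(α, p) = (u_α + u_{2(1−p)})²
```

where σ_j² is the variance of test-retest differences at point *j* and
u_γ is the two-sided standard-normal critical value (central mass 1 − γ).
With the conventional α = 0.05 Bonferroni-corrected over P = 16386 points
and p = 0.9: f = 35.3892 and N_j = 70.7784 σ_j². Comparing a 2D and a 3D
arm point-by-point gives the percentage reduction map
100 (N_j^2D − N_j^3D)/N_j^2D, and paired Wilcoxon signed-rank tests give a
−ln(p) significance map whose Bonferroni threshold is
−ln(0.05/16386) = 12.70.

## Worked example

```python
import numpy as np
from cardiatlas import (
    PhantomSpec, generate_atlas_pool, power_constant,
    MultiAtlasSegmenter, dice_coefficient,
)
from cardiatlas.surfaces import TemplateMapper

# a pool of 5 noisy synthetic LV phantoms (b-SSFP-like contrast)
pool = generate_atlas_pool(
    PhantomSpec(noise_sd=20.0), n_atlases=5, rng_seed=11,
    spacing=(2.5, 2.5, 2.5),
)

# segment the first phantom with the other four
seg = MultiAtlasSegmenter(search_radius_mm=6.0).fit(pool[1:])
labels = seg.predict(pool[0].intensity, pool[0].landmarks)
print("myocardium Dice vs truth:",
      round(dice_coefficient(labels, pool[0].labels, 2), 3))

# corresponded wall-thickness map against the pool's mean-shape template
mapper = TemplateMapper().fit(pool)
thickness = mapper.transform(labels)
print("template points P:", mapper.n_points_)
print("mean wall thickness (mm):", round(thickness.values.mean(), 2))

# sample size to detect a 1 mm difference at one point with unit variance
f = power_constant(0.05, 0.9, n_points=16386)
print("f(alpha/P, p) =", round(f, 4), "-> N per mm^2 variance =", round(2 * f, 4))
```

prints

```
myocardium Dice vs truth: 0.991
template points P: 437
mean wall thickness (mm): 9.57
f(alpha/P, p) = 35.3892 -> N per mm^2 variance = 70.7784
```

The Dice coefficient (1 = perfect overlap) scores the fused segmentation
against the phantom's exact labels; P is the number of corresponded
myocardial template points at this phantom resolution; the mean recovered
thickness is close to the phantom's 10 mm prescription net of the basal
truncation region; and 70.7784 subjects per mm² of test-retest variance is
the per-point sample-size constant at the reference parameters.

A full seeded study — atlas pool, leave-one-out accuracy in 3D and
thick-slice 2D arms, test-retest cohort, sample-size and significance
maps, manifest with checksums — runs from one config:

```bash
cardiatlas run --seed 1 --out study/
```

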