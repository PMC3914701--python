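# Methods

This note documents the models, numerical choices and limitations behind
`cardiatlas`, in the order data flows through the package.

## Coordinate conventions

All geometry lives in physical millimetres. A volume maps voxel index
(i, j, k) to `origin + index * spacing` (voxel-center, 0-based). Label
volumes use codes 0 background, 1 LV cavity, 2 myocardium, 3 RV cavity.
Meshes and landmarks share the same mm frame, so volumes of different
spacing (2 mm high-resolution vs 10 mm thick-slice stacks) compare
directly. NIfTI affines are written axis-aligned; on read, spacing is the
column norm of the affine.

## Synthetic phantoms

The phantom is a truncated-ellipsoid LV shell. The endocardium is an
ellipsoid with semiaxes (a, b, c) (defaults 20, 20, 45 mm — a normal adult
LV scale); the myocardium is the offset band {x : 0 < d(x) ≤ t} of points
within wall thickness t (default 10 mm) of the endocardial surface; the
base is cut by the plane z = `base_fraction`·c (default 0.5), above which
everything is background. Because the epicardium is the *exact* offset
surface, the true normal-ray wall thickness equals t everywhere for
constant t — the analytic acceptance surface for the whole thickness
chain. An optional low-order harmonic modulation
t(θ) = t₀(1 + A cos(mθ)) in the endocardial polar angle stands in for
regional thickness variation.

Point-to-ellipsoid distance uses the Lagrange foot-point parametrisation
solved by 90 rounds of vectorised bisection (interval contraction 2⁻⁹⁰;
exact closed form for spheres). Exact voxel coordinates at the ellipsoid
center are a degenerate foot-point case handled by a 1e-9 mm clamp.

Ground-truth volumes: the truncated-ellipsoid cavity has the closed-form
segment volume π a b (z₀ − z₀³/3c² + 2c/3). The truncated offset-band
myocardium has a closed form only for spheres (difference of spherical-cap
volumes); for general ellipsoids it is computed by midpoint quadrature of
the indicator at 0.5 mm, documented as such. Tests assert the exact cases.

Intensities mimic bright-blood b-SSFP: blood 400, myocardium 200,
background 50, plus seeded Gaussian noise (default SD 20 for atlas pools —
a blood/myocardium contrast-to-noise of about 7, in the range of clinical
cine imaging). Six landmarks (apex, base center, two mitral-ring points,
two RV-insertion points) are placed analytically on the shell; the naming
is this package's convention.

Atlas pools perturb semiaxes (SD 1.5 mm per axis), wall thickness (SD
0.8 mm), rotation (SD 3° per rotation-vector component) and translation
(SD 2 mm) — chosen once as a plausible inter-subject spread for healthy
adults at desk scale. Draws with non-positive wall are rejected and
redrawn. Test-retest pairs share one anatomy and field of view, with
independent noise and a small rigid repositioning (SD 1.5 mm / 2°),
emulating a subject leaving and re-entering the scanner. Every stochastic
operation takes an explicit seed and is bit-reproducible.

What the phantoms do **not** model: papillary muscles and trabeculae, bias
fields, banding or flow artefacts, breath-hold misregistration between 2D
sections, realistic LV shape beyond a truncated ellipsoid, and any right
ventricle. Passing tests therefore demonstrate correctness of the
algorithms and the direction of resolution effects, not clinical-grade
accuracy on real scans.

## 2D-stack emulation

`resample_to_stack` pools slabs of `slice_thickness` mm separated by
`gap` mm along z (half-open windows over voxel centers, measured from the
physical edge of the first voxel): grayscale by slab mean, labels by
majority vote with ties broken toward the lower code (background-
conservative). Output z-spacing is thickness + gap and the output origin
is the first slab center, so thickness = input spacing with zero gap is an
exact identity. A final partial slab is kept, truncated, and logged. The
default emulation (8 mm + 2 mm) reproduces the conventional short-axis
cine protocol's through-plane sampling.

## Patch-based label fusion

Atlases are brought into the target frame by the least-squares similarity
transform (Umeyama) over the six landmarks, then resampled onto the target
grid (linear for intensity, nearest for labels). Fusion is an exhaustive
scan of a spherical search window (default radius 6 mm): for each voxel
and each in-window integer offset whose displaced center stays in bounds,
the SSD between the target patch and the displaced atlas patch (cubes of
odd voxel extent nearest 5 mm; edge-replicated sampling at borders) sets
the weight exp(−SSD/(h²n))·exp(−‖offset‖²/s²). Per atlas the n_best = 5
heaviest candidates vote with the label at their displaced center; the
fused label is the argmax of summed vote mass, ties toward the lower code.
Voxels with zero admissible vote mass become background and are counted.

Choices worth noting:

- *Exhaustive search, not randomized propagation.* At desk scale the
  window is small enough to scan deterministically; a PatchMatch-style
  randomized search optimises the same objective and can replace the scan
  behind the same interface.
- *Similarity bandwidth h.* Default is a robust noise estimate
  (1.4826 × MAD of the 3×3×3 high-pass residual), the standard
  non-local-means scaling. On a noiseless volume h collapses toward zero
  and fusion degrades gracefully to near-hard matching, which makes
  noiseless self-segmentation exactly label-preserving.
- *Spatial bandwidth s* defaults to the search radius.
- *Exact foreground restriction.* Voxels farther than the search radius +
  patch size from every atlas's foreground can only receive background
  votes, so fusion is computed inside that bounding box only; the result
  is identical to the full scan.
- The vectorised implementation (per-offset shifted arrays + box filters)
  is verified label-for-label against a brute-force per-voxel vote on
  small volumes.

Volumetry counts cavity voxels (LVEDV) and converts myocardial voxel
volume to mass at 1.05 g/mL; both index to body surface area.

## Surfaces, template and thickness

Endo- and epicardial surfaces are marching-cubes isosurfaces (level 0.5)
of the cavity and cavity∪myocardium masks after a physical-space Gaussian
smoothing of 1.5 mm (per-axis sigma = 1.5/spacing voxels). The smoothing
removes voxelisation staircase — at 1 mm isotropic it brings every
recovered point of a 10 mm spherical shell within ±0.2 mm of truth —
while biasing a radius-20 mm sphere by well under 0.1 mm; thick-slice
stacks are barely smoothed through-plane (sigma < 1 voxel), so the 2D
arm's step artefacts at base and apex survive, as they should.

The template is built from the first atlas's endocardial mesh: each endo
vertex casts its (1-ring–smoothed) outward normal to the epicardium,
giving a paired epi point; the midwall is the pointwise midpoint. Points
whose epi partner is closer than half the median separation lie on the
basal-cap closure (the valve plane marching cubes seals) and are flagged
invalid — they stay in the meshes for registration but never enter a
thickness map. The reference is registered to every other atlas
(landmark-initialised similarity + ICP with nearest-vertex matching,
convergence when the residual changes < 1e-4 mm, cap 60 iterations; final
exact projection onto the target triangles) and the corresponded points
are averaged. Registration to a new subject without landmarks initialises
from centroid/RMS-radius moments instead. The number of valid points P is
fixed by the template and defines every thickness map's length; for
symmetric shapes ICP has a tangential null space, so correspondence is
reproducible rather than anatomically unique there.

Thickness at point k: cast the midwall vertex normal (smoothed over the
1-ring, 10 iterations) from m_k = (endo_k+epi_k)/2; thickness is the
distance between the endocardial and epicardial crossings nearest m_k.
The crossing search is capped at the direct endo–epi distance + 5 mm so an
oblique line cannot latch onto the far side of the shell; misses fall back
to ‖epi_k − endo_k‖ and are logged. Ray–mesh and point–mesh queries use
exact Möller–Trumbore and Ericson kernels with KD-tree pruning (pruning
bounds are conservative, so results equal the unpruned scan within the
stated caps).

## Reliability statistics

Bland–Altman: bias = mean(A−B), limits of agreement bias ± 1.96·SD(A−B)
(the conventional normal multiplier, not t-based). ICC(2,1) — two-way
random effects, absolute agreement, single measures — is computed from the
ANOVA mean squares, with the McGraw–Wong F-based 95% interval
(Satterthwaite degrees of freedom). The implementation is cross-checked in
the tests against a brute-force ANOVA oracle (1e-10) and against
`pingouin.intraclass_corr`.

## Power mapping

Per point j, σ²_j is the sample variance (ddof = 1) of test-retest
differences and N_j = 2 f(α/P, p) σ²_j/δ², with
f = (u_{α/P} + u_{2(1−p)})², u_γ = Φ⁻¹(1 − γ/2). The factor is squared —
(4.6673 + 1.2816)² = 35.3892 at the reference parameters — and the
Bonferroni family size defaults to the field's own P (16386 for the
reference high-resolution template, exposed as a parameter since any
template carries its own point count). Raw (continuous) N_j feeds the
median/IQR summaries; the integer requirement is the ceiling. Zero-variance
points get N_j = 0 and are flagged.

The normality screen runs Shapiro–Wilk per point at the Bonferroni level
α/P; constant columns are indeterminate. The Wilcoxon significance map
uses exact signed-rank p-values for N ≤ 25 (without ties/zeros) and the
continuity-corrected normal approximation above; it is rendered as −ln(p)
because the Bonferroni threshold −ln(0.05/16386) = 12.70 then sits
directly on the map scale. All-zero difference columns are masked.

`simulate_power` verifies the formula empirically: two Gaussian groups of
the computed size, a two-sided two-sample z-test at α/P, rejection
fraction over seeded replicates. The z-test matches the formula's
known-variance normal derivation; at α ≈ 3·10⁻⁶ a Welch t-test is
measurably more conservative and would test a different claim. At the
reference parameters the integer size is 71 and the analytic power
0.9016, so a 10,000-replicate estimate carries a ±0.6% two-sigma Monte-
Carlo band around it; the acceptance test therefore checks the 10,000-
replicate value against its own sampling error and pins the strict ≥ 0.9
bound with a 500,000-replicate run.

## Pipeline scale

The demo pipeline and the test suite run phantoms at 2.5 × 2.5 × 2 mm
(3D arm) against an 8 mm + 2 mm slab emulation (2D arm), pools of 3–10
atlases and test-retest cohorts of 2–8 subjects — sizes chosen so a full
study completes in minutes on one CPU while preserving the contrasts of
interest (the 3D arm's Dice, thickness RMS error and per-point N all beat
the 2D arm with wide margins at these sizes). The in-plane resolution of
the acquisition protocols (1.2 mm) is exercised in I/O tests; analysis
phantoms trade it for speed, which attenuates but does not change the
resolution effects being measured.

## Known limitations

- The template correspondence is similarity + ICP projection, not
  deformable registration; it is adequate for shell-like phantoms and
  replaceable behind `register_template`.
- The midwall is the pointwise endo/epi midpoint, a first-order
  approximation to a geodesically equidistant surface.
- Per-point tests are treated as independent (Bonferroni); no spatial
  random-field correction.
- The phantom's "2D arm" models through-plane blurring and gaps only, not
  inter-breath-hold slice misalignment, so it understates the real
  disadvantage of 2D stacks.
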