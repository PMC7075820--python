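# Methods

## Geometry and coordinate model

All computation happens on a single 3D grid with a voxel-index → world-mm
affine (RAS+, 0-based indices). Distances are Euclidean between voxel
*centers* in world space, so anisotropic spacings and oblique affines are
handled by construction. Resampling between grids is deliberately out of
scope: inputs that do not share a grid raise an error, because silent
resampling of binary masks changes volumes and border geometry in ways the
user should control upstream.

### SVZ band

The subventricular zone is a few-millimetre ribbon of germinal tissue on
the lateral-ventricle walls. Given a ventricle mask V and brain mask B,
the band is

  surface(V) ∪ { v ∈ B \ V : dist(v, V) ≤ t },

where surface(V) are ventricle voxels with a 6-connected non-ventricle
neighbor, dist is the Euclidean distance transform of the ventricle
complement with the grid spacing as sampling, and t is the rim thickness
(default **3 mm**; t = 0 degenerates to the ventricle surface alone, so
both a "surface" and a "volumetric band" reading of the niche are
available). The band is represented both as world-space voxel centers (for
distance queries via a KD-tree) and as voxel indices (for exact
cell-sharing contact tests). Restriction to the *lateral* ventricles is
the responsibility of the input label selection; the phantom's ventricle
mask contains only the two lateral tubes.

### SGZ points

The subgranular zone lives in the dentate gyrus, which is bilateral. A
single whole-structure center of mass would fall between the hemispheres
in tissue that is not hippocampus, so the dentate foreground is split at
the midline plane x = 0 (template space is midline-aligned) and one
unweighted centroid is computed per non-empty side. Downstream distances
take the minimum over the returned points.

### Per-lesion measures

The "tumor center" is the unweighted centroid of foreground voxel centers
— the only parameter-free definition. Border distance is the minimum over
lesion-voxel/niche-element pairs and is **exactly zero on contact**:
contact is cell-sharing (band voxel = lesion voxel, or an SGZ point inside
a lesion voxel's half-open cell), not a tolerance window; the band's
nonzero thickness already provides the physically meaningful margin.
Distances to the band are point-to-voxel-center rather than
point-to-surface-mesh; on 1–2 mm grids the difference is below the
digitization error discussed under *Numerical behavior*.

## Statistics

The rank tests are implemented from their tie-corrected formulas (mid-ranks
throughout, two-sided p, α = 0.05):

- **Mann–Whitney**: U = R₁ − n₁(n₁+1)/2;
  Var(U) = n₁n₂/12 · [(N+1) − Σ(t³−t)/(N(N−1))]; z = (U − n₁n₂/2)/√Var;
  p = 2Φ(−|z|) with **no continuity correction**. All-tied input returns
  U = n₁n₂/2, p = 1.
- **Kruskal–Wallis**: H = [12/(N(N+1)) Σ Rⱼ²/nⱼ − 3(N+1)] /
  (1 − Σ(t³−t)/(N³−N)), df = k−1, χ² upper tail; all-tied input → H = 0,
  p = 1.
- **Pearson χ²** without continuity correction, df = (r−1)(c−1); zero
  marginals are errors.

scipy's implementations are used only as independent cross-checks in the
test suite, never as the computation path. At the cohort sizes this
package targets (≥ 45 per group) the normal/χ² approximations are
adequate; the enumeration oracle in the tests bounds the small-sample
error. No multiple-testing correction is applied by default (a Holm
adjustment is available as an opt-in utility), matching common practice of
reporting a small fixed battery unadjusted. Normality screening is not
performed: the nonparametric tests are used unconditionally.

Quantiles use linear interpolation at (n−1)·p between order statistics
(numpy's default), so table outputs are reproducible bit-for-bit within
this package. Table percentages are integers rounded half-up.

### Accuracy of the no-continuity-correction p-value

For small samples the U distribution is discrete; the continuity-
*uncorrected* normal approximation estimates the permutation **mid-p**
(more-extreme labelings in full, exactly-as-extreme at half weight), not
the plain exact p. On untied samples with n₁, n₂ ≥ 4 the normal p agrees
with the enumerated mid-p within 0.05; against the plain exact p the
discrepancy can reach ~0.1 at n = 4 per group purely from the atom at the
observed U. Heavily tied samples of size 3–4 make the pooled rank
distribution too lumpy for any continuous approximation; the tests
therefore check the U statistic itself against enumeration for tied and
untied samples, and the p agreement on untied ones.

## Synthetic phantom and cohorts

The phantom stands in for a real template plus anatomical atlases, with
every structure parametric so ground truth stays analytic:

- grid 91×109×91 at 2 mm isotropic, origin (−90, −126, −72) mm;
- brain: ellipsoid centered (0, −16, 4), semi-axes (68, 86, 62) mm
  (≈1.5 l);
- lateral ventricles: two mirrored tubes of radius 4 mm along a spline
  through anterior horn → body → atrium → temporal horn control points;
- dentate gyri: ellipsoids at (±24, −24, −16) mm, semi-axes (5, 13, 6) mm,
  so figure-style slices at z = 0 and z = −20 mm pass through ventricle
  body and hippocampal level respectively;
- lobar atlas: half-space rules (frontal y ≥ 8; temporal z ≤ −8; a deep
  central box; a posterior-inferior cerebellum/brainstem wedge; parietal
  as remainder).

Lesions are digitized spheres of radius r = (3V/4π)^{1/3} at a seed voxel
drawn from P(v) ∝ exp(−d_target(v)/λ) over brain voxels (uniform without
bias); λ is the attraction length scale in mm — smaller λ, stronger niche
bias. Spheres are intersected with the brain; clipping is flagged in the
truth table because it shifts the centroid off the seed. An optional
smooth surface perturbation (a random traceless quadratic form on the
sphere of directions, relative amplitude ≤ 20%) roughens the boundary; it
defaults to **0** so that the recovery tests retain exact analytic truth.
A `require_svz_contact` switch restricts the seed density to voxels within
r of the SVZ band, producing cohorts in which every lesion touches the
ventricle wall.

Default cohort (the package's study conditions): groups of **50/64/45**
subjects with log-normal volumes of median **48.4/73.4/45.9 ml** and
log-scale dispersions 1.10/0.88/1.25 (chosen so the quartile spreads match
volumes' reported IQRs of ~79/93/115 ml; the long upper tail is capped at
250 ml), and bias settings **SVZ λ=12 / SGZ λ=25 / SGZ λ=9** calibrated
once by forward simulation so the group medians of center-to-SGZ distance
fall near **42/31/21 mm** with border-to-SVZ medians of 0 mm — the
qualitative pattern the pipeline is designed to detect (across seeds the
realized medians are ≈40/33/21 mm).

What the generator does *not* emulate: infiltrative, anisotropic tumor
growth; registration error and scanner heterogeneity; slice-gap
resampling; correlated laterality. Passing tests therefore demonstrate
correctness of the measurement and inference machinery under known
geometry, not the clinical conclusions themselves.

## Numerical behavior

- **Center distances** of unclipped digitized spheres are exact to
  floating precision: the voxelized ball is symmetric about its (lattice)
  seed, so its centroid is the seed.
- **Border distances** carry a one-sided digitization error: measured ≥
  analytic max(0, d−r), with a provable upper bound of one voxel diagonal
  (√3·spacing = 3.46 mm at 2 mm; once the lattice covering radius for
  finding a lesion voxel near the sphere surface toward the target, once
  for the geometry at the niche side). Empirically the error stays below
  ~2 mm; the test suite asserts the provable bound, and the acceptance
  report prints the observed maximum.
- Axial slice selection takes the plane whose voxel-center z is nearest to
  the requested z; exact midpoints resolve to the lower slice index.
- Region assignment: majority voxel overlap, exact ties broken by a
  configured precedence order, zero overlap → "unclassified"; background
  label 0 never wins.
- Pipeline outputs use fixed column order and 6-significant-digit float
  formatting with newline-terminated rows, making reruns byte-identical;
  the run log records a config hash.
- Degenerate inputs: empty lesion masks, empty niches, singular affines,
  non-3D volumes, grid mismatches, unknown group labels and missing mask
  files each raise a distinct named error (missing masks name the
  subject).

## Problem sizes

The default test suite and the acceptance script use the 2 mm phantom,
159-lesion cohorts, 100 cohort replicates for power, 1000 null replicates
for type-I calibration, 200 random pairs for the distance oracle and 100
spheres for analytic recovery; one full acceptance run takes about four
minutes on a single CPU.

## Known limitations

- Distances are straight-line Euclidean; they ignore white-matter
  anatomy, so they measure proximity, not plausible migration paths.
- The SVZ band is a voxel construct, not the manually delineated surface
  an expert would draw; thickness is a free parameter rather than a
  measured quantity.
- The center-inside-band case (center distance 0) is allowed by the
  contract though rare in practice.
- Group labels are inputs; the package does not adjudicate molecular
  classification, and the stored published-cohort counts retain the
  internal inconsistencies of their printed source tables.
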