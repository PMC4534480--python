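# Methods

## The perfusion-vector statistic

The left-ventricular mid-myocardial surface is discretised into rectangles
carrying centres (mm), areas (mm²) and dimensionless intensity weights. The
area-and-intensity weighted centroid

C = (Σ xᵢAᵢWᵢ, Σ yᵢAᵢWᵢ, Σ zᵢAᵢWᵢ) / Σ AᵢWᵢ

is evaluated twice: with unit weights (anatomical centroid C_A) and with
weights set to the measured tracer intensity (perfusion centre of gravity
C_P). The perfusion vector P = C_P − C_A points away from a perfusion defect;
its magnitude grows with defect severity and extent. The statistic is a ratio
of weighted sums, so it is exactly invariant to global rescaling of the
weights and equivariant under rigid motions of the surface (P rotates with
the grid). Both properties are enforced by tests at 1e-12 (scale) and 1e-9 mm
(rigid motion).

Degenerate inputs fail loudly: all-zero weights raise an error rather than
silently returning the anatomical centroid, because a vanishing Σ AᵢWᵢ almost
always signals a segmentation or sampling failure, not true absent perfusion.

Stress/rest comparisons report two numbers: the difference of the magnitudes
|P_s| − |P_r| (the headline metric; it is signed, positive when the stress
defect is larger) and the magnitude of the vector difference ‖P_s − P_r‖
(which also captures direction changes). Neither is privileged by downstream
code; cohort tables carry both.

## Surface model

The mid-wall is a truncated prolate ellipsoid: semi-axes `mid_short_radius`
(x and y) and `mid_long_radius` (z), apex pole included at +z, base left open
at the plane z = −f·(long radius) with truncation fraction f (default 0.35).
An ellipsoid is used because any smooth closed-apex LV-like surface carries
the statistic equally well, while the ellipsoid admits closed-form oracles
for area, volume and normals.

Defaults: short radius 25 mm, long radius 45 mm, wall thickness 10 mm. When a
target cavity volume is set (default 148 mL, a standard male end-diastolic
volume), both radii are rescaled by one common factor — solved by bisection
on the closed-form truncated-ellipsoid volume of the endocardial surface
(mid-surface semi-axes minus half the wall) — giving a ≈ 33.7 mm,
c ≈ 60.6 mm. The cavity-volume solver is verified against independent
numerical integration to 1 %.

The grid has `n_longitudinal × n_circumferential` cells (default 32 × 64;
the resolution is a free parameter because no canonical rectangle spacing
exists for this surface family). Cells sit at parameter-space midpoints;
areas are the local metric product (meridional arc spacing × circumferential
arc spacing), which converges to the analytic surface area at second order.
Cell centres at half-integer angular positions make the default grid exactly
mirror-symmetric about the x–z and y–z planes, so the anatomical centroid
lies on the long axis to machine precision.

Frame convention: +x septal→lateral, +y anterior→inferior, +z basal→apical,
right-handed; θ measured from +x toward +y (anterior wall at 270°). With
these signs an anterior defect produces a positive y component and a lateral
defect a negative x component.

## Digital phantom

The phantom replaces a full Monte-Carlo SPECT chain with the two
degradations that dominate the reconstructed short-axis images the statistic
actually consumes:

1. **Rasterisation** — voxels whose centres lie between the endo- and
   epicardial ellipsoids (mid-surface ∓/± half wall thickness) and above the
   base plane receive uptake 1, scaled by the defect field. Default voxel
   size 4.8 mm isotropic, matrix auto-fitted to the ventricle plus a
   two-FWHM margin. Sharp voxel-centre membership keeps the rasteriser
   verifiable against a brute-force scan; the integrated uptake converges
   under voxel halving within 2 %.
2. **Gaussian point spread** — isotropic convolution with
   σ = FWHM/(2√(2 ln 2)), default FWHM 7 mm, sampled-and-normalised kernel
   truncated at 4σ, zero padding (mass conserved to 0.1 % given the rendering
   margin).
3. **Poisson counting noise** — the volume is scaled so its hottest voxel has
   expectation `counts_scale` (default 500, a typical clinical myocardial
   count level; the activity/uptake/time accounting of a real acquisition is
   not reproduced) and every voxel is replaced by a Poisson draw. Noise is
   applied after the blur; in a real chain reconstruction and filtering
   re-correlate the noise, so this is an approximation, documented as such.

Not modelled: photon transport, collimator response, attenuation and scatter,
tomographic reconstruction, cardiac/respiratory motion, gating. Consequences:
phantom noise is uncorrelated between voxels (real reconstructed noise is
smoother), defect borders are sharper than scanner resolution allows before
the blur stage, and no reconstruction artifacts exist. Passing tests
therefore demonstrate the statistic's geometric and statistical behaviour,
not robustness to reconstruction- or motion-induced artifacts.

### Defect geometry

A defect is a circumferential sector (opening angle α around a centre angle)
intersected with a meridional band of `extent_mm` of arc (default 60 mm);
uptake inside is multiplied by 1 − severity. Severity defaults to 1.0 (zero
uptake): defect contrast is otherwise a free parameter, and full severity
matches the visually absent uptake of transmural defects. Apical defects are
defined by arc distance from the apex pole alone.

The meridional band is **centred on the mid-ventricular level** — the
area-weighted meridional centroid of the surface (≈ 57.7 mm of the ≈ 96.9 mm
apex-to-base arc at the default shape) — shifted only as needed to stay on
the surface, so a full-length extent still covers everything. This placement
was chosen over apex-anchored bands because an apex-anchored defect's
area centroid sits well apex-ward of the surface centroid, dragging the
vector strongly along the long axis as α grows (long-axis drift ≈ 80 % of
the in-plane response), which contradicts the observed behaviour of real
mid-ventricular defects where the long-axis component stays stable;
the area-centred band reduces that drift to ≈ 2 % geometry-only (≈ 4 %
through the full blur/sampling pipeline). Apex- and base-anchored bands
remain available via `DefectSpec.extent_anchor`.

On the surface grid, defect weights use **fractional cell coverage**: border
rectangles get 1 − severity × (overlap fraction of their θ–arc cell with the
defect window). Interior and exterior rectangles behave exactly as sharp
membership would, but the discrete defect area fraction then matches the
analytic sector fraction within 2 % at the default resolution, and the "true
defect extent" recorded in cohorts is the coverage-weighted area fraction.
Coverage within 1e-9 of 0 or 1 is snapped so limiting cases (no defect,
total defect) are bit-exact.

## Weight sampling

Each rectangle's weight is taken from the volume by probing along the local
surface normal: trilinear interpolation at 1-mm steps within ±10 mm, reduced
by the maximum of the profile (default) or the mean. Profile-max is the
common choice in perfusion quantification because it is robust to mild
surface misplacement; the mean is provided for sensitivity analyses, and
max ≥ mean element-wise by construction. Normals come from the ellipsoid
parameterisation (not mesh differencing, which would inject resolution
artifacts); grids re-read from CSV lack that metadata and fall back to the
outward radial direction from the long axis, which profile-max sampling
tolerates well. Samples outside the volume contribute 0; a grid whose
centres leave the field of view is an error, as is an all-zero sampling
result.

Known edge effects: the open basal rim and the apex sample into partial
volume after blurring, so even the defect-free phantom yields a small
long-axis offset of C_P (|P| ≈ 0.46 mm noiseless at defaults). This is the
real basal-delineation sensitivity of the method, visible here as a constant
bias; it cancels out of defect-induced trends, and the noise floor
(median |P| ≈ 0.44 mm at 500 counts) stays far below a 30° defect's
response (≈ 2 mm). For sensitivity analyses, `exclude_basal` trims the
basal-most fraction of the surface (by meridional arc) before the centroid
computation.

## Synthetic cohorts

`generate_cohort` emulates a stress/rest validation cohort: 40 normal studies
and 20 per defect-location group (apical, inferior, anterior, lateral) by
default. Abnormal studies draw α ~ U(20°, 70°), severity ~ U(0.5, 1.0),
extent ~ U(40, 70) mm; half of each group is ischemia-like (rest severity =
stress severity × U(0.2, 0.6)) and half infarct-like (identical stress and
rest defects). Ranges bracket the phantom experiment's defect sizes and span
mild-to-transmural contrast; rest ratios put reversibility clearly inside
the measurable range. Every study runs the full render→blur→noise→sampling
pipeline for both phases; per-study noise seeds derive from the master seed
via SHA-256 of (seed, study id, phase), keeping the whole table reproducible
byte-for-byte and every derived seed below 2³¹. The table records per-phase
vector components and magnitudes, both difference metrics, and the true
defect area fraction.

The cohort generator produces cleaner group separation than clinical data:
defects are single, well-placed and noise-limited, with no motion,
attenuation, or reader-dependent labelling. Statistical recoveries on it
(extent–magnitude correlation, normal-vs-ischemia differences) validate the
pipeline's plumbing and direction conventions, not clinical effect sizes.

## Statistics

Two-sided tests throughout (sidedness is otherwise a free choice; two-sided
is conservative). Mann-Whitney uses the exact null when the pooled sample is
≤ 12 without ties, else the tie-corrected, continuity-corrected normal
approximation; the branch taken is reported. At 6+6 the exact null is a
lattice with spacing 2/924, and the normal approximation can differ from it
by up to ≈ 0.015 mid-range — an inherent limit of the approximation, checked
by test. Kruskal-Wallis uses the tie-corrected rank statistic with the
χ²(k−1) approximation; the all-ties degenerate case returns H = 0, p = 1.
Spearman uses average ranks, exact permutation p for n ≤ 7 (7! = 5040
enumerations is the tractability cut-off) and the t approximation above.

`compare_groups` mirrors the validation workflow: an omnibus Kruskal-Wallis
over all groups per metric, pairwise Mann-Whitney of each abnormal group
against the reference only when the omnibus p < 0.05, each judged at the
Bonferroni threshold 0.05/k (0.0125 for four pairwise tests, 0.025 for two).
The gate plus correction keeps the null pairwise type-I rate well below
nominal (measured ≈ 0.005 over 1000 null replicates). Output is invariant to
row and label order.

## Problem sizes

Default experiment sizes keep every check cheap while leaving headroom above
discretisation error: 2048-rectangle grids, ~30³-voxel auto-cropped volumes
at 4.8 mm, 100 noise replicates for null distributions, 120-study cohorts,
1000 replicates for the type-I simulation. The full test suite runs in
seconds; the acceptance script in well under a minute.

## Interchange formats

Surface grids: CSV (`index,x_mm,y_mm,z_mm,area_mm2,weight`, 9 significant
digits, index contiguous from 0; coordinates are cardiac-frame mm, never
voxel indices). Volumes: NIfTI-1 with mm spacing in the header (integer
count volumes stored as int32 for exact round-trips). Results: JSON with
`{phase, C_A, C_P, P, magnitude}`. Cohorts: CSV with stress_/rest_ prefixed
component columns plus both difference metrics, the true extent fraction and
the defect parameters. Configuration: one YAML file mirroring the spec
dataclasses, with CLI flags taking precedence over the file and the file
over built-in defaults. Malformed input is rejected with a named error.
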