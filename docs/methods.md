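# Methods

This note documents the models, parameter choices and numerical conventions
behind `petphantom`, and what the synthetic data can and cannot say about
real PET.

## Lesion geometry

Irregular lesions are star-shaped solids: a sphere of radius `R` whose
surface is radially modulated, `r(θ, φ) = R·(1 + A·f(θ, φ))`, where `f` is a
seeded band-limited random function on the sphere (real spherical harmonics
of degree 2..`lmax`, coefficients ~ N(0, 1/ℓ), normalized to peak 1) and
`A ∈ [0, 1)` is the deformation amplitude. Star-shapedness guarantees a
single connected component and gives concentric sub-regions in closed form:
the set `{ρ/r(θ,φ) ≤ t}` holds exactly `t³` of the volume.

The ground-truth surface and volume come from meshing the zero level of the
continuous field `r(θ,φ) − ρ` with marching cubes, which avoids the
staircase bias of binary masks; a 1 mm grid reproduces the analytic sphere's
volume and sphericity to ~0.1%. `f` is tabulated once per (seed, lmax) on a
1° angular grid and bilinearly interpolated; for a degree-≤14 function the
interpolation error is far below the rasterization error. Amplitude is
calibrated to a sphericity target by bisection (sphericity is scale-free and
monotone in amplitude for a fixed seed); the default shell family spans
sphericity ≈ 0.49–0.74 (`lmax` 8, raised to 14 for the most irregular
shell, which band-limited deformation at `lmax` 8 cannot reach).

## Uptake compositions

Seven layouts cover the study's configurations: concentric, blob and wedge
necrosis (C₀ = 0 inside C₁); one or two hot foci at C₂ = 5·C₁; and combined
variants. Focal blobs are spheres seeded from the config seed; their
direction is chosen among 24 seeded candidates to maximize the local shell
radius so the blob fits inside strongly deformed shells. After
rasterization the *realized* voxel fractions are measured and stored back —
the digital counterpart of weighing each gel compartment — and all
ground-truth indices (COV_GS, Gini, H_GS, L/B_GS) are computed from these
nominal pre-blur compartment concentrations and fractions, never from the
noisy image. Necrotic volume is included in the COV/Gini modality sets but
excluded from the active volume `V_GS_active` and from the mean-uptake
numerator of L/B.

Gini normalization: the categorical index `(1 − Σ pᵢ²)` cannot reach 1 for
two modalities, so the normalized form `(1 − Σ pᵢ²)·k/(k−1)` is used (0 for
one modality by definition). This makes an even two-way split score exactly
1 and keeps H_GS = COV·Gini within 0–100 for all two-level C/5C
compositions (the observed maximum over random fractions is ≈ 72.6 at a hot
fraction near 0.37). Three-compartment compositions with large necrotic and
hot fractions can push H_GS above 100; the default cohort recipes stay
below it (cohort maximum ≈ 86).

## Default cohort

`build_cohort` mirrors a nine-acquisition phantom campaign: five shells
(A–E) with fixed volume targets 6.8–32.3 cc reused across acquisitions, 38
lesions total, 20 uniform and 18 heterogeneous, lesion-to-background ratios
4–27, backgrounds per body compartment (thorax 0.006, breast 0.005, lung
0.004, liver 0.013, myocardium 0.023 MBq/cc), C₁ in roughly 0.02–0.16
MBq/cc as implied by L/B targets. Shell shapes depend only on the master
seed and shell identity; noise seeds differ per lesion and acquisition.
Cohorts smaller than 38 take an evenly spaced subset of the plan so the
uniform/heterogeneous mix survives truncation.

## Acquisition surrogate

Tomographic reconstruction is emulated in image domain: Gaussian system PSF
(FWHM 6.4 mm, 4.8 mm when PSF modelling is on), linear resampling onto the
reconstruction grid (in-plane pixel = 700 mm FOV / matrix, slice 3.27 mm),
seeded multiplicative Gaussian noise, then the Gaussian post-filter (5 or
7 mm). The noise scale (default 0.2 before the post-filter) stands in for
count statistics: it scales as `1/√(iterations × subsets)` relative to the
standard 3 × 18 protocol and ×1.3 without TOF. After the standard 5 mm
filter this leaves ≈ 5% COV in a uniform region, matching clinical liver
noise (< 8%). Test-retest pairs share the signal and differ only in noise
seeds derived from the parent seed by a counter scheme recorded in the
volume metadata.

What this surrogate does **not** model: scatter, randoms, attenuation,
dead time, reconstruction non-negativity and convergence artifacts,
spatially varying PSF, and correlated noise textures of iterative
reconstruction. Conclusions about *which* features survive which screen on
real scanners should therefore not be read off the synthetic report; what
the tests do establish is that the indices, matrices and statistics are
computed correctly and that the pipeline's qualitative biases (threshold
under- vs over-segmentation, matrix-size sensitivity) behave as expected.

## Segmentation

* **fixed60**: voxels ≥ 60% of the in-region maximum (inclusive, so the
  peak voxel always belongs), largest 26-connected component kept. On
  blurred lesions at high L/B this systematically under-segments.
* **adaptive**: iterative background-corrected threshold
  `T_k = ε(V̂_k, L/B)·(mean_mask − B) + B`, initialized from the fixed-60%
  mask, converged at 0.5% relative volume change (max 50 iterations,
  non-convergence raises an error carrying the last iterate). The threshold
  fraction ε is bilinearly interpolated from a table calibrated on
  noiseless simulated spheres (diameters 15–40 mm × L/B 3–30, ε scanned in
  0.25–0.90 by 0.01, minimizing absolute volume error). The fitted ε falls
  from ≈ 0.66 for the smallest spheres to ≈ 0.50 for the largest —
  the partial-volume trend — and is non-increasing in L/B. The table ships
  as JSON and is regenerable with `calibrate_adaptive`.

MTV percent error uses `100·(V_GS_active − MTV)/V_GS_active`:
under-segmentation positive, over-segmentation negative. The opposite
convention is available via `sign="overestimate_positive"`; one convention
is applied consistently and unit-tested, since published error tables are
not always explicit about the sign.

## Feature extraction

Preprocessing: trilinear resampling to an isotropic grid at the in-plane
pixel size (nearest-neighbour for the mask; anisotropy ratio > 10 is
rejected), then fixed-bin-count discretization of the within-mask range to
64 levels using `level = max(1, ceil(64·(v − min)/(max − min)))`. The ceil
convention maps min→1, max→64 and splits a 640-sample arithmetic ramp into
64 bins of exactly 10 voxels; the floor-plus-clip alternative provably
leaves one bin with 11. Constant regions map to level 1 and are flagged.

The 58 features follow the classical texture-analysis definitions, with
matrices built at distance 1 over the 13 unique directions of 26-voxel
connectivity (opposite offsets are redundant after symmetrization):

* **GLCM** (9): merged symmetric co-occurrence matrix over the 13
  directions; Haralick-style formulas (SumAverage is E[i+j] under the
  normalized matrix; Correlation's zero-variance case returns the sentinel
  0). A per-direction averaging mode is available behind a flag.
* **GLRLM** (13): run matrices summed over the 13 directions; run
  percentage is normalized by directions × voxels so it is 1 for a fully
  fragmented image.
* **GLSZM** (13): zones are 26-connected components of equal level,
  orientation-free; zone percentage = zones / voxels.
* **NGTDM** (5): per-level summed absolute difference from the mean of the
  in-mask 26-neighbourhood; denominators are ε-guarded (ε = 1e-12), so a
  constant region yields Contrast 0 and Coarseness capped at 1/ε.

Morphology: MTV is the exact voxel count × voxel volume. The surface is the
marching-cubes mesh of the mask smoothed with a one-voxel Gaussian;
Sphericity and Spherical disproportion compare that mesh's area with its
own enclosed volume. Using the mesh volume rather than the voxel count in
the sphericity numerator is deliberate: the two estimators disagree at
small sizes in a way that pushes a mixed-form index above 1 (a digital
sphere of ~160 voxels would score 1.25), while the pure-mesh form scores
0.98–1.00 across all sizes and matches the analytic 4:1:1 spheroid to 0.5%.
SV remains Surface / MTV.

Degenerate inputs (single voxel, constant region) produce documented NaN
sentinels plus a flag map, keeping cohort tables rectangular.

## Statistics

* **Friedman vs segmentation**: with exactly two methods the Friedman
  statistic degenerates, so the exact two-sided binomial sign test on
  non-tied pairs is used (all ties → p = 1); three or more methods use the
  Friedman chi-square. At 38 lesions the exact test's achievable type-I
  error is 0.041 at α = 0.05, inside the calibration band.
* **COV vs reconstruction**: per lesion, population-SD COV of the feature
  across a family's settings (on |mean| with a flag when the mean is
  negative), averaged over lesions; the representative COV is the maximum
  over families; classes at 5/10/20% with inclusive left boundaries.
* **ICC**: one-way random single-measure ICC(1,1) from the ANOVA mean
  squares (an absolute-agreement form: a constant shift between test and
  retest lowers it); ICC(3,1) behind a flag is shift-invariant. Reproducible
  ⇔ ICC > 0.6 in every test-retest dataset; undefined ICCs flag the feature
  non-reproducible. The implementation is cross-checked against an
  independent ANOVA oracle in the tests.
* **Mann–Whitney** (two-sided, tie-corrected), **Spearman** correlation
  with H_GS (Pearson behind a flag), **paired t-test** of Sphericity vs
  S_GS with necrotic lesions excluded (their active surface is
  ill-defined). No multiple-testing correction is applied to the p < 0.05
  flags; a Benjamini–Hochberg column is emitted alongside.

The report funnel counts reproducible features, those also discriminating
heterogeneous from homogeneous uptake, and those additionally correlated
with H_GS.

## Reproducibility and problem sizes

Every stochastic step is a pure function of its seed; the master seed fans
out per stage/lesion/setting via `numpy.random.SeedSequence` counters, so a
rerun of `run_study` is byte-identical. The test suite exercises the full
pipeline on reduced cohorts (4–6 lesions, one or two reconstruction
families) and the statistical calibration on 1000 simulated null replicates;
the default 38-lesion, five-family study is the package's standard
configuration for actual use. Statistical analyses whose minimum sample
sizes a reduced cohort cannot meet (Friedman and ICC below 5 lesions,
H_GS correlation below 5 heterogeneous lesions) are reported as NaN rather
than aborting the run.

## Known limitations

* Thresholding multifocal or necrotic lesions can lock onto the hottest
  focus; the MTV error analysis is therefore most meaningful for uniform
  lesions, as threshold methods are in practice.
* The wedge and blob compartments hit their fraction targets only
  approximately (the realized, measured fractions are the ground truth).
* The Gini variant is the normalized categorical heterogeneity index; the
  unnormalized form can be obtained by scaling back by `(k−1)/k`.
* L/B measured on blurred images is biased low at the mask rim
  (partial-volume voxels); ROI-erosion is advised when estimating uptake.
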