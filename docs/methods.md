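# Methods

This note documents the models, conventions and numerical choices behind
`cardaxes`, and what the synthetic generators do and do not emulate.

## Coordinate frames and spherical conventions

All comparable axes live in the patient DICOM LPS frame: +x left, +y
posterior, +z superior. The vectorcardiogram is constructed in the Frank
lead frame (X left, Y inferior, Z posterior) and re-expressed in LPS by the
signed permutation x = X, y = Z, z = −Y. This mapping is a configuration
parameter of `frank_to_lps` (any orthogonal 3×3 matrix is accepted), since
device conventions for the Frank leads vary in sign.

Spherical coordinates of a unit axis are

* θ = atan2(−z, x), the frontal-plane angle in (−180°, 180°]: 0° points
  left, positive rotates toward inferior (the clinical frontal-axis
  convention; anticlockwise is negative);
* ϕ = arccos(y), the polar angle from the anterior–posterior axis in
  [0°, 180°]: 0° posterior, 180° anterior.

At the poles (ϕ = 0° or 180°) θ is undefined; `to_spherical` returns θ = 0
with a `degenerate` flag rather than an arbitrary value. An alternative ϕ
convention (elevation from the transverse plane, 90° − polar) is selectable
because the in-plane versus polar reading of "angle from the
anterior–posterior axis" is genuinely ambiguous; the polar form is the
default and all internal consumers go through the same switch.

ΔAE3D = cos⁻¹(a·e) is deliberately **not** folded to an acute angle:
apex→base anatomical directions sit roughly opposite depolarisation
directions, so population means are obtuse and folding would destroy them.
Planar deltas, by contrast, are minimal signed differences wrapped into
(−180°, 180°] to avoid artificial extremes at the boundary. All dot products
are clamped to [−1, 1] before arccos; note arccos amplifies float error near
±1 (arccos(1 − 1e−16) ≈ 1e−8 rad), which sets the realistic "exact" tolerance
for geodesic quantities.

## Anatomical axes

Landmark methods (MVA/MAVA/VPA) use a basal landmark that is the mean of
per-valve ring centroids — each valve contributes equally, so ring sampling
density cannot bias the landmark (vertex pooling would). The apex is the LV
endocardial vertex furthest from the basal landmark, recomputed
independently per method (the apex genuinely shifts slightly between basal
definitions); ties break to the lowest vertex index for determinism. The
axis is the unit vector apex → basal landmark.

PCA methods (PC1LV/PC1LRV) take the first principal component of the
region's point cloud. The PC sign is arbitrary, so it is oriented to have a
positive dot product with the same mesh's MVA direction (falling back to +z
when the mitral ring is absent), making all five definitions apex→base
comparable. PCA directions are invariant to rigid motion (equivariant) and
uniform scale by construction.

The sphericity index used for mesh QC is the ratio of the extents
(max − min of projections) along the second and first principal components
of the biventricular epicardial cloud — rotation- and scale-invariant, in
(0, 1], and low for the abnormally flattened reconstructions the rule is
meant to catch. Exclusion is strictly population-level: a mesh is dropped
only when its index is more than k·SD (default k = 3) from the cohort mean.

## Electrical axes

The Kors 3×8 regression matrix (rows X, Y, Z; columns I, II, V1–V6) ships
as a package data file (`cardaxes/data/kors_coefficients.csv`); a checksum
test pins the transcription, and any alternative lead-to-VCG transform with
the same layout can be supplied. The transform is purely linear — no
filtering — and the QRS window [onset, offset) (half-open, 0-based) is
carried through unchanged.

The QRS loop is the LPS-frame VCG restricted to the QRS window and
re-origined at the onset sample, so the first loop point is exactly (0,0,0).
Axis definitions:

* **maxQRS** — sample of largest Euclidean norm; earliest-sample tie-break.
* **meanQRS** — component-wise mean of loop points.
* **vavgQRS** — mean weighted by local dipole speed wᵢ = ‖p₍ᵢ₊₁₎ − p₍ᵢ₋₁₎‖/2·fs
  (one-sided at the ends), i.e. an arc-length-weighted mean. At constant
  sampling frequency the dipole moves slowly at the beginning and end of the
  QRS, oversampling those segments; speed weighting exactly compensates, and
  the estimator is invariant to resampling density (verified against
  high-resolution quadrature in tests). Weighting by *inverse* speed would do
  the opposite and contradicts the estimator's purpose.
* **eig1QRS** — first right singular vector of the mean-centred loop matrix,
  sign-oriented to the meanQRS side so repeated calls are bitwise identical.

For a straight-line loop all four definitions coincide. The QRS amplitude
used for ECG QC is the maximum absolute deflection from the isoelectric
baseline inside the window; the baseline defaults to the onset-sample value
(always available on a median beat), with a median-of-40-ms-before-onset
alternative exposed.

## Rotational alignment and pair ranking

The population rotation T mapping anatomical to electrical unit vectors
solves the orthogonal Procrustes problem min Σ‖eᵢ − T aᵢ‖²: with
H = Σ aᵢeᵢᵀ = AᵀE and SVD H = USVᵀ, T = V·diag(1, 1, det(VUᵀ))·Uᵀ. The
determinant factor (Kabsch correction) guards against reflective optima,
which arise for near-planar vector configurations and are physically
meaningless for an axis map; for well-conditioned, strongly correlated data
the guarded and unguarded solutions coincide. Collinear configurations
(rank-deficient H) are rejected rather than silently resolved.

Pair evaluation uses a single seeded subject-level 80/20 split shared by all
20 anatomical × electrical pairs, so their test MGDs are paired and directly
comparable; MGD is reported in radians. Subjects with any non-finite axis are
dropped with a recorded count. Vector-outlier exclusion is a per-spherical-
coordinate z-score rule (|Δθ| > k·SDθ or |Δϕ| > k·SDϕ, k = 3), with θ
deviations computed against the circular mean and wrapped — a plain linear
rule on θ would misbehave near ±180°.

## Statistics

* **Standardized regression**: OLS with each continuous predictor divided by
  its sample SD; the response stays on its native degree scale, so each
  coefficient reads "degrees per SD of predictor". Binary sex (0 female,
  1 male) is left unscaled so its coefficient reads "male vs female".
  VIFs come from auxiliary regressions on the design; perfectly collinear
  designs raise an error naming the predictors. Missing data: listwise
  deletion per analysis, with n reported.
* **Levene** uses mean centring (the classical variant, not
  Brown–Forsythe's median centring).
* **Mann-Whitney U** uses the exact permutation null for tie-free combined
  n ≤ 20 and the tie-corrected normal approximation otherwise, without
  continuity correction (so identical samples give p = 1 exactly).
* **Deconfounding** residualises each column against an intercept + age,
  sex, sex·age, height, weight design via least squares; residuals are
  exactly orthogonal to the confounders and the operation is idempotent.
* **Association scans** pre-clean phenotypes (drop a column when one value
  covers ≥ 95% of non-missing rows; greedily drop near-duplicates at
  |r| > 0.9999 keeping the first), then test each (metric, phenotype) pair
  with Pearson (continuous) or Spearman (binary diagnoses) correlation at
  the Bonferroni threshold α/(n_metrics × n_phenotypes), α = 0.05 by
  default and configurable. Pairs with < 10 complete rows or zero variance
  are flagged untestable instead of being returned with meaningless p-values.
* The generic ±3 SD z-score mask backs all QC rules; on Gaussian data it
  excludes ≈ 0.27% by construction.

## Synthetic generators

The generators plant statistical structure, not physiology:

* **Meshes** are schematic: a truncated prolate-ellipsoid LV endocardium
  (default semi-axes 25 × 25 × 45 mm, ≈ 5 mm wall — end-diastolic adult
  scale), an epicardial shell with an RV crescent (geometric scenery for the
  PC1LRV and sphericity computations), and four valve rings whose centres
  are placed on the long axis (mitral; aortic a few millimetres basally
  along it) or symmetrically about it (tricuspid/pulmonary). This placement
  makes the planted long axis the exact truth for MVA, MAVA *and* VPA
  simultaneously — the property recovery tests rely on; real mitral centres
  sit slightly off the VPA axis, so real-data method differences are larger
  than synthetic ones. An exact apex vertex is included so apex finding is
  not limited by sampling. Optional ring jitter (mm) probes landmark noise
  sensitivity.
* **QRS loops** are a sum of two windowed harmonic components that start
  and end at the origin: max_mag·sin²(πt) along the planted direction plus a
  0.4·loop_width·max_mag·sin(2πt) transverse component. The magnitude
  maximum is uniquely at t = ½, always a sampled point (even sample counts
  are bumped by one), so the maxQRS truth is exact. No repolarisation, no
  notching, no wavefront physics.
* **ECGs** are synthesized by the Moore–Penrose pseudoinverse of the Kors
  matrix, so the forward transform reproduces the source VCG to numerical
  precision. These are not realistic lead morphologies — they are the
  minimal 8-lead signals consistent with a chosen VCG.
* **Coupled cohorts** draw anatomical axes from a von Mises–Fisher
  distribution (the spherical analogue of an isotropic Gaussian; sampled via
  scipy's implementation of Wood's method) about a per-subject mean shifted
  in (θ, ϕ) by planted covariate effects, and electrical axes as a fixed
  rotation of the anatomical axis plus vMF noise at lower concentration
  (defaults κ_anat = 60, κ_elec = 12) — reproducing the qualitative pattern
  that electrical variability dominates. Default covariate distributions
  (age 63.3 ± 7.7 y, BMI 25.8 ± 4.2 kg/m², 44% male) and the default BMI
  frontal-plane effect of +4.3°/SD mirror the healthy-cohort scale such
  analyses report. The default coupling rotation turns the anatomical mean
  by 145° within a plane chosen so the rotated mean stays clear of the
  θ = ±180° wrap (wrap-adjacent means would inflate linear angle SDs
  spuriously).
* **Method-pair cohorts** add a latent per-subject orientation observed by
  each anatomical definition through vMF noise; the planted electrical
  definition couples to the planted anatomical definition's axis (κ = 80 by
  default) while the others couple to the latent orientation at 4× lower
  concentration (κ = 20), making the planted pair the expected arg-min of
  the test-MGD table.

Consequently, passing tests demonstrate correct recovery of planted
geometry and statistics — they do not validate segmentation quality, device
filtering, Frank-lead fidelity, or any physiologic claim about real
cohorts.

## Problem sizes and determinism

Default experiment sizes (mesh recovery over 10 rotations, rotation fitting
at n = 2000 pairs with κ = 50, pair discrimination at 400 subjects × 5
seeds, regression recovery at n = 20 000, QC tail at n = 10⁶) were chosen to
make Monte-Carlo error comfortably smaller than the tolerances being
checked while keeping a full run in tens of seconds. Every stochastic
component takes an explicit seed (numpy `default_rng`); repeated runs are
bit-identical, and `evaluate_method_pairs` is invariant to subject ordering
because the split permutes a sorted id list.

## Known limitations

* Mesh I/O is PLY (ASCII or binary) with an integer `region_label`
  property; VTK polydata is not parsed.
* The supplement-level conventions of the source datasets (exact Frank→LPS
  sign map, exact ϕ definition) vary between acquisition setups; both are
  configuration switches here, and the defaults are documented choices, not
  device ground truth.
* Phecode mapping of ICD-10 codes is out of scope: diagnosis columns are
  consumed as pre-made binary flags.
* The outlier rule for axis vectors treats θ and ϕ independently; a fully
  spherical rule (e.g. Mahalanobis on the tangent plane) would differ
  slightly for very dispersed populations.
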