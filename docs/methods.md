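# Methods

This note documents the models, estimators, defaults and numerical choices
behind `oculomorph`, and what the synthetic-data tests do and do not
establish about real ocular MRI.

## Coordinate conventions

Masks are 3-D boolean grids on an isotropic voxel lattice (default 0.7 mm,
the reconstructed resolution of volume-isotropic T2-weighted eye imaging).
Grid axes map to anatomy as +x = subject's right, +y = anterior,
+z = superior (RAS with anterior along +y); world coordinates are mm, and
NIfTI affines are diagonal (oblique acquisitions must be resampled upstream
and are rejected by `read_mask` with an explicit error). Left/right eyes
differ only by mirroring in the mediolateral axis.

## Phantom model

A phantom is an ellipsoid with semi-axes `(a_ml, a_ap, a_si)` rotated by
Euler angles and digitised by the voxel-centre rule: a voxel is foreground
iff its centre satisfies `|q| <= r_ell(q_hat) + A exp(-theta^2 / 2 w^2)`,
where `q` is the body-frame position, `r_ell` the ellipsoid radius along the
unit direction, and the Gaussian term adds a localised radial protrusion of
amplitude `A` (default 0.8 mm for glaucomatous eyes, width `w = 25 deg`)
along a bump direction (infero-nasal-posterior, mirrored per eye side). The
voxel-centre rule — no partial-volume weighting — matches the granularity of
threshold-contour segmentation tools. `A = 0` reproduces an exact ellipsoid,
and the generator refuses grids that cannot hold the shape with a 2-voxel
margin.

Digitisation accuracy at 0.7 mm (measured in the test suite): volume within
~0.1 % of `(4/3) pi a b c` on average (random shapes and sub-voxel centre
offsets); each length within half a voxel; the *ratio* of two lengths —
the anisotropy — carries up to ~1 % noise for a single mask because the two
axes sample independent staircase phases. Cohort-level anisotropy averages
are accurate to well under that (the study-scale SD of the ratio is 0.04).

## Morphometry estimators

- **Surface**: marching cubes at level 0.5 of the (zero-padded) binary grid;
  vertices in mm. Masks must be one 26-connected component away from the
  grid boundary; single-voxel masks have a volume (0.343 mm³ at 0.7 mm) but
  no valid surface.
- **Corneal apex**: surface point of maximal anterior coordinate; the tied
  set (the flat anterior voxel face) is reduced to its centroid. When a mask
  carries a known apex landmark (phantoms do), `measure_eye` prefers it: the
  real protocol marks the apex on the anatomy, and an anterior-extreme point
  is only a silhouette proxy whose tangent plane is perpendicular to the
  anterior axis by construction.
- **Optic disk**: supplied landmark if present; otherwise the posterior pole,
  i.e. the centroid of the surface points within half a voxel of the maximal
  Euclidean distance from the apex. A binary mask contains no disk anatomy,
  so this fallback is an explicit approximation; the distance field is flat
  near the antipode, which is why the near-maximal set is centroided rather
  than argmax'd (staircase bulges would otherwise dominate).
- **Eye axis**: normal of the total-least-squares plane fitted to surface
  points within 4.0 mm of the apex, oriented toward the mask centroid. The
  4 mm cap keeps the staircase-driven axis error at or below ~0.3 deg at
  0.7 mm voxels (a 3 mm cap leaves ~1.1 deg) while staying well inside the
  corneal cap (~11 mm chord).
- **Axial plane**: the plane through apex and disk whose normal is
  orthogonal to the left–right axis; a "horizontal plane through two points"
  is underdetermined, and this third constraint yields the tilted
  transverse-anatomical plane used in practice.
- **Axial length**: distance from the apex to the *last* 0.5-crossing of the
  posterior ray along the eye axis (robust to posterior concavities), with
  the crossing averaged over a 9-ray bundle within 0.3 mm of the axis to
  suppress half-voxel staircase noise (the posterior surface is locally
  orthogonal to the axis there).
- **Transverse length**: maximum over axis positions (0.35 mm steps) of the
  in-axial-plane chord orthogonal to the axis; chord ends are bisected to
  the interpolated 0.5 level, and the profile maximum is taken from a local
  least-squares parabola (window ±2.8 mm) rather than the raw max, which
  would be biased upward by the extreme value of per-chord noise. A
  `transverse_3d=True` flag sweeps the chord direction around the axis
  instead of confining it to the axial plane.
- **Volume**: foreground voxel count × voxel volume — deliberately the
  voxel-count volume, which is what contour tools report, not a mesh volume.
- Lengths are reported to 0.1 mm and volumes to 1 mm³ in pipeline CSVs;
  in-memory results keep full precision and `anisotropy` is exactly
  `axial/transverse` of the same call.

## Cohort generator

Per-group marginals are Gaussian with the means/SDs of the five study groups
(control, myopia, glaucoma, glaucoma+myopia, preperimetric glaucoma; 30, 13,
33, 51, 27 eyes), over nine variables: eye volume (mm³), axial and
transverse length (mm), age (yr), height (cm), eTIV (10³ mm³), spherical
equivalent SE (D), visual-field mean deviation MD (dB), IOP (mmHg). The PPG
transverse SD is taken as 1.3 mm (the published table carries an evident
misprint, 11.3). Variables are coupled by a Gaussian copula whose Spearman
targets are converted to Pearson via `r = 2 sin(pi rho / 6)`; the default
within-group targets echo the reported across-eye structure (volume–axial
and volume–transverse 0.80, volume–eTIV and volume–height 0.40, SE
negatively coupled to axial and volume) and are checked for positive
semidefiniteness at construction. Bounds (SE ≤ −8 D exclusion,
non-positive sizes) are enforced by redraw, not clipping, preserving the
distribution shape.

Eyes are paired into subjects (two per subject where group size allows, as
in the 154-eyes / 77-participants layout). Subject-level covariates (age,
height, eTIV, sex) are shared within a subject; the second eye's eye-level
variables are drawn from the exact Gaussian conditional given the shared
block, so every eye retains the full marginal and correlation structure.
Per-group and per-record random streams derive from the master seed by
fixed offsets, so any subset is reproducible and a fixed seed yields a
byte-identical table.

The synthetic "Stage" ordinal is 0 for eyes without glaucomatous field loss
(including PPG) and Hodapp-style MD bins otherwise (1: MD ≥ −6; 2: [−12,−6);
3: [−20,−12); 4: < −20 dB); the clinical staging used in the source data is
not defined there, so this is a declared stand-in. Myopia labelling is
strict (`SE < −3.00 D`; exactly −3.00 is non-myopic) and SE ≤ −8.00 D is
excluded. The Anderson–Patella visual-field classifier takes the 24-2
pattern-deviation categories (≥5 %, <5 %, <1 %) on a hemifield-split grid:
glaucomatous iff one hemifield holds a 4-connected cluster of ≥3 points
<5 % including a <1 % point, or ≥2 points <1 %, or either the hemifield-test
or PSD flag is set.

**What the generator does not emulate**: MR intensities and partial-volume
effects, motion, lens/cornea substructure, real segmentation error (rater
variability), non-Gaussian marginals, and any joint structure beyond the
single stated copula. Passing tests therefore validate the *measurement and
statistics chain*, not the biological effect sizes; see "Expected values"
below for a consequence.

## Template construction

Group-average eyes are built in two align-and-average passes: (1) all masks
are centroid-centred and averaged voxel-wise into a blurry initial template
(lightly smoothed); (2) each mask is rigidly aligned to it (rotation +
translation only — no scaling, because group size differences are the
signal), resampled with trilinear interpolation and re-averaged; (3) the
same align-and-average is repeated within each group against the refined
global template; (4) the group average is Gaussian-smoothed (σ = 0.7 mm =
one voxel; no kernel is prescribed by the source protocol) and thresholded
at 0.5, keeping the largest component. Left and right eyes are processed
independently, with no mirroring.

The registration metric is the mean template probability over the
transformed foreground voxel centres (for binary volumes, overlap fraction),
sampled from a σ = 1 voxel smoothed copy so Powell refinement has a usable
gradient; initialisation is centroid match plus the best proper-rotation
principal-axes assignment. If refinement fails to improve on the
initialisation, the initialisation is returned flagged. Known recovery
accuracy (tests): translations to < 0.5 voxel, 15-degree rotations to < 2
degrees, and N translated copies of one shape rebuild it with Dice ≥ 0.98.
Masks are canonically ordered by content digest before averaging, so the
template is bitwise independent of input order.

## Cohort statistics

- **Correlations**: pairwise-complete Spearman with average-rank ties and
  asymptotic p-values; constant variables are reported missing with a
  warning. Stratified variants take a boolean mask, query string or callable.
- **ANOVA**: glaucoma × myopia with interaction on the four non-PPG groups,
  type-II sums of squares (the design is unbalanced: 30/13/33/51); empty
  cells are an error. Post-hocs: Tukey HSD over all six group pairs and
  Dunnett versus control (matching where each test is used in the source
  analysis); both tables carry the matched unadjusted p of the same
  statistic for audit, so adjusted ≥ unadjusted holds by construction.
- **Bootstrapped ROC**: per replicate, one eye per subject uniformly at
  random, subjects split 50/50, predictors standardized on the fit half,
  logistic fit by maximum likelihood (ridge fallback λ = 1e−4 only on
  non-convergence, counted and reported), TPR interpolated onto a fixed
  101-point FPR grid from the held-out half; 200 replicates by default.
  The summary curve is the pointwise mean (vertical averaging), the
  dispersion band is half the pointwise SD, and the AUC is the trapezoid
  integral of the *mean* curve. `model_comparison` evaluates every candidate
  predictor set with identical resampling streams and reports the FPR at
  80 % sensitivity as the operating point.
- α = 0.05, two-sided, throughout; no multiplicity correction across
  outcomes beyond Tukey/Dunnett within comparisons.

## Expected values under the synthetic conditions

Two cohort-level quantities deserve explicit calibration statements, both
measured by the test suite and the acceptance script rather than asserted:

- The {volume, eTIV} glaucoma model's 200-split mean-curve AUC has
  expectation ≈ 0.77 (cohort-to-cohort SD ≈ 0.05 at 127 eyes) under the
  Gaussian-marginal cohort with within-group volume–eTIV Spearman 0.40; the
  population ceiling of the linear model under these exact marginals is
  0.794. Real-data joint structure beyond "Gaussian marginals plus one
  printed correlation" can support higher values. Because the per-cohort
  noise is large relative to the quantity, the acceptance script reports the
  mean over 96 cohort replicates.
- A single label permutation at 65 subjects has null-AUC SD ≈ 0.08, so null
  calibration is checked as an average over independent permutations, and
  the ANOVA interaction's type-I error is checked over 1000
  permuted-outcome replicates (expected 5 % ± 2 %).

## Problem sizes and determinism

Default problem sizes: 154-eye cohorts, ~45³-voxel masks (auto-sized to the
phantom plus margin), 200 ROC splits, two align-average template passes.
Tests run reduced versions (4–24 masks per template, 10–200 splits) chosen
so the full suite completes in a few minutes on one core. All randomness
flows from explicit seeds (master seed → per-group/per-record streams);
pipeline runs write a manifest with the seed, the serialized config and
SHA-256 hashes of every output. Geometry stages are bit-reproducible;
optimizer-dependent transforms are deterministic given identical inputs.

## Known limitations

- The optic-disk fallback is the posterior pole; on real masks the disk is
  off-pole (infero-nasal), so landmark-free frames on real data are tilted
  relative to the true clinical axis.
- Rigid-only registration by design; myopic posterior staphylomas or strong
  shape outliers are averaged, not modelled (no diffeomorphic averaging, no
  statistical shape model).
- The generator's independence assumptions (single copula, Gaussian
  marginals, one bump motif) are a lower bound on real-data structure;
  classifier AUCs measured here should be read as method calibration, not
  as clinical performance estimates.
- Voxel-count volume and subvoxel lengths are mixed deliberately (matching
  how contour tools report volume); mesh-based volume would differ by
  ~0.1 %.
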