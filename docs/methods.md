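# Methods

This note documents the models, conventions and numerical choices in
`lastrain`, and what the synthetic study conditions do and do not
establish about real gated-CT data.

## Strain model and conventions

Strain is **elemental area strain**: the percentage change of each
triangle's area relative to the end-diastolic (frame-0) reference
anatomy, positive for expansion. Element areas are half cross-product
magnitudes; faces whose reference area falls below 1e-12 mm² are
excluded from averaging and logged (the measurement is otherwise
undefined on them). Global and regional curves are **unweighted means**
of elemental strains — the mean-of-elements convention; an
area-weighted variant exists behind `area_weighted=True` but is off by
default. Region labels live on faces (strain is elemental); a face
straddling a region boundary is assigned by its centroid in the
parametric chart.

Chamber volumes use the divergence theorem on the closed surface,
returned positive regardless of winding. LA convention: EDV is the
frame-0 (minimum) volume, ESV the maximum, LAEF = 100·(ESV−EDV)/ESV;
LV convention is the usual EF = 100·(EDV−ESV)/EDV. Body surface area
uses the **Mosteller** formula √(h·w/3600) — the convention is not
dictated by the measurement itself, so it is documented here and
swappable (`mosteller_bsa`). Indexed volumes are volume/BSA (mL/m²).

## Phase segmentation

End-diastole is defined as the strain minimum. If the minimum is not at
frame 0 (tracking reference), all curves are cyclically rotated so the
minimum becomes t = 0 and re-zeroed there; the original ED frame index
is recorded. Peak reservoir strain is the sample maximum (a monotone
interpolant cannot exceed the sample values, so this is exact for the
curve family we fit).

The conduit–contractile boundary is the point where the curve *levels
off* after the sharp conduit downslope. Implemented on the discrete
inter-sample slopes: scanning forward from the peak while tracking the
steepest downslope seen so far, `t_cc` is the left endpoint of the
first interval whose downslope magnitude is ≤ α times that steepest
downslope (or which is flat/rising), with **α = 0.2** (configurable).
Working on discrete slopes rather than a continuous interpolant makes
the detector return the exact plateau onset on piecewise-linear curves
and stays within one sampling interval of the true boundary on smooth
transients at 10 and 20 frames. A curve with no positive peak, or with
no level-off before the cycle end (e.g. a single monotone bump), is
returned with `needs_correction` status and a reason — never a silent
default. The manual-correction hook (`t_cc_override`, snapped to the
nearest post-peak sample) mirrors the manual phase review of clinical
practice; the cohort generator uses the prescribed boundary as the
fallback when a noisy subject trips the detector, and flags the subject.

Phasic strains are differences of the re-zeroed curve at the global
boundaries (regional curves use the *global* phases), so
reservoir = conduit + contractile is an identity, not an approximation.
Strain rates are `np.gradient` central differences with respect to
normalized R-R time (one-sided at the curve ends); no spline smoothing
by default, so SRs are reproducible and the discrete fundamental
theorem (S[k+1] − S[k−1] = 2h·SR[k]) holds exactly. Conduit and
contractile SRs are stored signed (negative); a report layer can format
magnitudes.

## Synthetic study conditions

The generator emulates what the downstream measurement needs, with
known ground truth:

* **Anatomy** — a superellipsoid-deformed icosphere (default axes
  (1, 0.85, 1.15), exponent 2.5, radius set from the target LA EDV).
  Five contiguous wall patches plus an excluded superior cap
  (pulmonary-vein/appendage analogue) are defined in the parametric
  sphere chart. This preserves the regional-analysis structure without
  an atlas; it does not reproduce real atrial shape variation, veins,
  or the appendage.
* **Motion** — each vertex scales radially by
  s_v(t) = √(1 + m_v·S(t)/100), where S(t) is the prescribed global
  transient and m_v the vertex's regional modifier. A face whose
  vertices share modifier m has area strain exactly m·S(t), giving a
  machine-precision oracle for the mesh path. The transient rises from
  0 to the reservoir amplitude A at `t_peak` (default 0.40), falls to
  A·cf at `t_cc` (default 0.70; cf = contractile fraction), and
  returns to 0 at the cycle end, so reservoir = conduit + contractile
  by construction. Two shapes: **plateau** (monotone PCHIP with an
  exact plateau after t_cc — a well-defined detector target) and
  **smooth** (C² periodic spline with a gently sloped diastasis knot at
  t_cc + 0.35·(1−t_cc); the diastasis is what the detector finds, and
  its nonzero slope stresses the α-threshold). 10- vs 20-frame
  acquisitions sample the same transient at 10% vs 5% increments.
* **Noise** — isotropic Gaussian vertex displacement (default cohort
  0.05 mm) on every frame except the tracked reference, mimicking
  tracking jitter. Jitter biases mean area strain slightly upward
  (area is convex in vertex perturbations); the default amplitude keeps
  this below ~0.1% strain at the default mesh resolution.
* **Cohort** — per-subject motion parameters are drawn from truncated
  normals (reservoir 24 ± 9 %, contractile fraction 0.55 ± 0.12,
  t_peak 0.40 ± 0.03, t_cc 0.70 ± 0.035, regional modifiers 1 ± 0.12,
  LA EDV 82 ± 30 mL, LV EDV 184 ± 35 mL, LVEF 50 ± 6.8 %), with
  covariates for an AF pre-ablation population (age 61 ± 12, 39%
  female, comorbidity prevalences as in the defaults table;
  CHA2DS2-VASc computed from the sampled flags). Group-1 effects are
  additive mean shifts; the default
  {contractile_strain −6.6 %, reservoir_amplitude −4 %, LA EDV +28 mL}
  emulates a recurrence-vs-no-recurrence contrast in which active
  (contractile) function is the most reduced. The `contractile_strain`
  shift is applied jointly with the reservoir shift so the configured
  delta is exactly the induced contractile-strain delta.
* **Images** — frames are voxelized by z-ray parity counting on a
  shared world grid (half-voxel offset so rays avoid mesh vertices),
  blood pool 1 / background 0, optional Gaussian smoothing and noise.
  This is a binary-contrast phantom: it exercises geometry and
  registration, not CT photon statistics, beam hardening or
  wall/blood contrast.

What passing tests on these conditions show: the measurement chain is
exact on known motion, the phase detector is unbiased to within one
sampling interval, the statistics match their closed-form/enumerated
oracles, and the full pipeline is deterministic under a seed. What they
do not show: performance on real anatomies, real tracking error
structure, or real inter-patient covariance of features.

## Baseline tracker

Frame-to-frame motion is estimated with a multi-resolution B-spline
free-form deformation maximizing global normalized cross-correlation
(SimpleITK), LBFGSB, full regular sampling, one thread — deterministic
by contract. Consecutive-pair fields are composed back to frame 0 to
propagate the ED mesh (bounds per-pair motion; tested against direct
0→k registration to within half the control-grid spacing). Smoothness
comes from the control-grid spacing rather than an explicit
bending-energy penalty; the default spacing of **40 mm** is of the
order of the chamber radius, making each per-pair field near-affine.
Finer grids (16–24 mm) track volumes equally well but wrinkle the
propagated surface tangentially on the binary-contrast phantoms, which
inflates mean elemental area strain by ~15–20%; at 40 mm the end-to-end
phasic-strain error of the image path is 3–7% relative (the mesh path
is near-exact, and the property suite holds the image path to 15%).
Failure to improve on the identity initialization is flagged and
logged, never silently accepted. The tracker is an interface: an
externally tracked mesh sequence bypasses it entirely, and a
ground-truth tracker replays the generator's motion to isolate
downstream stages.

## Statistics

Group comparisons use the **pooled-variance two-sided Student t-test**
(df = n₁+n₂−2), from raw samples or from printed summary statistics
(identical formula; agreement tested to 1e-12 on moment-matched data).
Welch is available behind a flag. Zero pooled variance returns p = 1
for equal means and a flagged NaN otherwise. Categorical 2×2 tables use
Fisher's exact test whenever any expected count is below 5, otherwise
χ² with continuity correction. The mixed ANOVA (between group × within
region) is computed by pingouin; sphericity is assessed and
Greenhouse–Geisser-corrected p-values are reported alongside the
uncorrected ones (pingouin reports the GG correction for the within
factor; the same ε is applied to the interaction's F degrees of
freedom).

ROC analysis uses the midrank (Mann–Whitney) AUC with automatic
orientation so the reported AUC ≥ 0.5 (reduced strain predicting events
flips sign; the flip is recorded), a percentile bootstrap CI over
subject resampling **stratified by outcome** (default 2000 replicates,
seeded), and a Youden-J operating point with sensitivity, specificity,
PPV and F1. DeLong's test computes the covariance of paired AUCs from
placement values; identical or monotone-transformed scores give
ΔAUC = 0 and p = 1 exactly. Clustering z-scores the 36 features, runs
k-means (k-means++ with 10 restarts, seeded) over k = 2…6, selects k by
maximum mean silhouette, and applies the sole-member-cluster rule:
any cluster of size 1 is removed as an outlier, the remainder
re-standardized and re-clustered (iterated, removals logged). PCA on
the standardized features supplies 2-D coordinates and per-component
explained variance. Zero-variance feature columns are dropped with a
log message; subjects with missing features are excluded listwise per
analysis and logged.

**No multiple-testing correction is applied anywhere** (α = 0.05 per
test). This mirrors the analysis convention this package implements;
users running many features against an outcome should treat individual
p-values accordingly.

## Problem sizes and defaults

Defaults are chosen so a full desk-scale analysis runs in seconds:
icosphere subdivision 3 (642 vertices, 1280 faces) per subject, 20
frames, cohorts of 2 × 10 subjects; the acceptance script's frame-count
comparison uses exactly these conditions. Statistical simulations in
the test suite use 120–1000 replications depending on the Monte-Carlo
error each assertion needs. Registration demos use ~30 mm phantoms at
2 mm voxels.

## Known limitations

* The regional chart is a fixed parametric division of a star-convex
  surface; it does not implement universal atrial coordinates, and
  labels on strongly non-spherical anatomies should be supplied
  explicitly.
* The baseline tracker is a deliberately simple FFD over a
  binary-contrast phantom; it is a pluggable baseline, not a validated
  clinical tracker.
* LAEF of the synthetic cohort (~28%) sits below typical clinical
  values (~38%): pure radial scaling couples LAEF rigidly to reservoir
  strain, (1+S/100)^{3/2}-wise, whereas real atria empty more per unit
  strain.
* Strain-rate peaks depend on sampling density by construction
  (10-frame SRs are systematically smaller in magnitude than 20-frame
  SRs); SR values should only be compared at matched frame counts.
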