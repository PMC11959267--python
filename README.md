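# lastrain

3D left-atrial (LA) phasic strain analysis from 4D retrospective-gated
cardiac CT.

Reduced LA mechanical function accompanies atrial myopathy: fibrotic
stiffening impairs the passive phases of atrial motion, and electrical
remodelling impairs active contraction. Conventional 2D strain imaging
(speckle-tracking echo, cine MRI) suffers from atrial foreshortening and
misses the 3D character of LA motion. Gated CT reconstructs the full 3D
anatomy at 10 or 20 phases of the R-R interval at sub-millimetre
resolution, which makes a true 3D measurement possible. `lastrain` is
for imaging researchers who have (or want to simulate) a tracked 4D LA
endocardial surface and need reproducible phasic strain, strain-rate,
volumetric and cohort-level statistical analysis.

## What it measures

Given one closed triangulated endocardial surface per cardiac frame with
fixed vertex correspondence (frame 0 = ventricular end-diastole, ED),
the **area strain** of each surface element *e* at normalized R-R time
*t* is

```
ε_e(t) = 100 · (A_e(t) − A_e(0)) / A_e(0)      [%]
```

positive for endocardial expansion. Global and regional curves are the
unweighted means of ε_e over the LA body and over the five wall regions
(septum, lateral, posterior, anterior, inferior; pulmonary-vein and
appendage elements excluded). From the global curve the three atrial
phases are segmented automatically:

* **end-diastole** `t_ed` — the strain minimum (curves are cyclically
  re-referenced if the minimum is not at frame 0);
* **peak reservoir strain** `t_peak` — the curve maximum;
* **conduit–contractile boundary** `t_cc` — where the curve levels off
  after the sharp conduit downslope (first post-peak interval whose
  downslope magnitude falls below α = 0.2 of the steepest conduit
  downslope; manually correctable).

Phasic strains follow as reservoir = S(t_peak), conduit = S(t_peak) −
S(t_cc), contractile = S(t_cc), so **reservoir = conduit + contractile**
holds exactly, per subject and per region. Strain rates (SR, % per
normalized R-R time) are central differences of the curves; peak
reservoir/conduit/contractile SRs are extracted on the same phase
windows. Per subject this yields the 36-feature vector
(3 phases × {strain, SR} × {global + 5 regions}) plus chamber
volumetrics (LA/LV EDV, ESV, SV, BSA-indexed volumes, LAEF, LVEF).

The package also provides:

* a **synthetic 4D cohort generator** (superellipsoid LA-like surfaces
  deforming through a prescribed reservoir/conduit/contractile
  transient, with regional modifiers, tracking jitter, 10/20-frame
  sampling, CT-like voxelization, and two-group cohorts with
  configurable effects) — every stage is testable with known ground
  truth;
* a **baseline 3D feature tracker** (multi-resolution B-spline FFD over
  normalized cross-correlation, deterministic, pluggable) that
  propagates the ED mesh through the cycle from image frames;
* the **cohort statistics** used in this setting: pooled Student's
  t-tests (raw or from printed summary statistics), χ²/Fisher tests,
  mixed ANOVA for region-by-group interactions, ROC with stratified
  bootstrap CIs and Youden operating points, DeLong's test for paired
  AUCs, and silhouette-selected k-means phenotype clustering with PCA
  projection.

## Worked example

```python
import lastrain as ls

mods = {r: 1.0 for r in ls.REGIONS}
mods.update(anterior=1.30, septum=0.85)       # regional heterogeneity
params = ls.MotionModelParams(
    reservoir_amplitude=28.0, contractile_fraction=0.55,
    t_peak=0.40, t_cc=0.70, regional_modifiers=mods,
    noise_sd=0.05, n_frames=20, transient_mode="smooth", seed=7)
seq = ls.generate_mesh_sequence(params)

res = ls.PhasicStrainModel(seq, height_cm=175, weight_kg=82).fit()
print(res.summary())
```

```
Phasic 3D LA strain analysis
============================================================
frames: 20   phase detection: automatic (ok)
t_ed = 0.00   t_peak = 0.40   t_cc = 0.70  (normalized R-R)

Strain [%] and peak SR [% per normalized time]:
           reservoir_strain  conduit_strain  contractile_strain  reservoir_sr  conduit_sr  contractile_sr
global                29.40           13.31               16.10        113.09      -61.15          -94.29
septum                25.53           11.70               13.82         97.98      -55.29          -82.70
lateral               28.58           12.87               15.70        109.92      -59.74          -91.59
posterior             28.09           12.62               15.46        108.04      -57.27          -89.61
anterior              37.19           17.00               20.19        142.45      -78.19         -117.62
inferior              28.12           12.58               15.53        108.73      -56.74          -91.17

Volumetrics:
  bsa_m2                 2.00
  la_edv_ml            132.59
  la_esv_ml            194.25
  ...
```

The detector found the prescribed boundaries (t_peak 0.40, t_cc 0.70)
exactly; the global reservoir strain of 29.4% reflects the prescribed
28% plus the small positive bias of vertex jitter, and the anterior
wall reads ≈1.3× the other regions, as prescribed. Reservoir = conduit
+ contractile in every row.

Cohort-level runs (simulate → strain → statistics, with a per-subject
metrics table, curve CSVs, a JSON stat report and a reproducibility
manifest) are available from Python (`lastrain.pipeline.run_pipeline`)
or the CLI:

```bash
lastrain run --seed 1 --out results/
lastrain roc --seed 1 --feature contractile_sr_global
```

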