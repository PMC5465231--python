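# Methods

`batlas` implements an automated multi-atlas segmentation (MAS) pipeline
for cervical-supraclavicular adipose tissue (sBAT — adipose tissue
*suspected* to contain brown fat, defined anatomically) in quantitative
water-fat MRI, together with the automated stage of a semi-automated
reference (REF) method and the evaluation statistics used to compare the
two.  This note records the model, the parameters that matter, the
synthetic phantoms used for validation, and the design decisions taken
where the design was genuinely open.

## The segmentation model

Each subject contributes four inherently co-registered 3D maps on a
common grid (default 1.0 × 1.0 × 2.0 mm voxels, axial slices): water and
fat signal magnitudes, the fat fraction FF = fat/(water+fat) ∈ [0, 1],
and the effective transverse relaxation rate R2* (s⁻¹).  Tissue classes
separate in (FF, R2*): adipose tissue has high FF and low R2*, muscle has
low FF and low-moderate R2*, skin has low FF and high R2*, and R2* is
elevated near bone and air.

**Preprocessing** turns the maps into registration inputs:

1. WF = 1 − FF (water fraction).
2. Background removal: voxels with water+fat at or below a threshold are
   air/cortical bone.  The threshold default is scale-free, `0.05 ×` the
   99th percentile of the sum signal, overridable numerically.
3. Skin stripping: iterated constrained peeling.  Per axial slice, the
   boundary layer of the current body mask (voxels removable by one 2D
   erosion with the 4-neighbourhood structuring element) is computed from
   the mask state at iteration start, and only boundary voxels with
   FF ≤ 30 % **and** R2* ≥ 80 s⁻¹ are removed — one voxel layer of skin
   per iteration, simultaneously over the layer, so the result is
   independent of voxel visit order.  Iteration stops at a fixpoint (a
   `max_iterations = 50` safeguard guarantees termination on adversarial
   inputs).  Then: largest 3D 26-connected component; per-slice 2D
   closing (5 × 5 square) with hole filling; per-slice unconstrained 2D
   erosion (7 × 7 square).
4. The WF map zeroed outside this support is the "apparent lean-tissue
   body" (adipose tissue has low WF and reads as background); the R2*
   map on the same support is median filtered (3 × 3 × 3).

**Registration** maps each atlas onto the target in two stages: an affine
alignment of the WF channels under the normalized-correlation metric
(4 resolutions, up to 3000 iterations), then a b-spline refinement with
final control-grid spacing 20 mm (4 resolutions, up to 7000 iterations)
driven by the WF and R2* channels with equal weight.  The output is a
dense displacement field on the target grid, in mm.

**Propagation and fusion.**  Each atlas's crude sBAT VOI (a generous
manual delineation that intentionally includes adjacent lean tissue) is
propagated through its deformation field with linear interpolation,
preserving fractional coverage.  Because the imaged volume covers the
depot only partially and sits at slightly different anatomical positions
per subject, a target voxel may map outside an atlas's imaged volume;
such atlases do not vote at that voxel.  A voxel is labelled when
strictly more than half of the representing atlases vote for it (a
per-atlas vote is coverage ≥ 0.5; both thresholds configurable).  Voxels
represented by no atlas are left unlabelled and excluded from evaluation
via the fusion field-of-view mask.

**Fine adjustment** (shared by MAS and REF): inside the crude VOI keep
voxels with FF ≥ 40 %, erode one 2D 4-neighbourhood layer per slice
(removes probable partial-volume border voxels), keep voxels with
R2* ≤ 50 s⁻¹.  **Refinement** (MAS only): low-signal voxels inside the
segmentation (water+fat at or below the background threshold) are
consolidated per slice by 3 × 3 dilation, hole filling and 3 × 3 erosion
and removed; refinement never adds voxels.  The REF path applies the
fine adjustment directly to the manually drawn crude VOI and skips
refinement, as manual delineation is assumed to avoid air and bone.

**Evaluation.**  With TP/FP/FN voxel counts of the MAS mask against the
REF mask inside an evaluation domain (fusion FOV ∩ selected slices,
even-numbered slices by default, 1-based):

    Dice  = 2·n_TP / (2·n_TP + n_FP + n_FN)
    V_REF = (n_TP + n_FN) · voxel volume
    V_MAS = (n_TP + n_FP) · voxel volume

Reference voxels outside the domain are discarded, not counted as false
negatives.  Mean FF and R2* are averaged over each segmentation
restricted to the selected slices.  Cohort statistics are Pearson r and
a two-tailed paired t-test over per-subject values.

## Registration backend

The optimization engine is not re-implemented; the backend adapts
SimpleITK's ITK registration framework to the protocol above.  Three
engine-level choices differ from a literal Elastix transcription and are
deliberate:

* **Elastic optimizer.**  The protocol's named optimizer, Elastix's
  adaptive stochastic gradient descent, has no SimpleITK equivalent.  ITK's
  generic gradient descent with estimated step length stalled far from
  the correlation optimum on the b-spline problem, so the elastic stage
  uses L-BFGS-B over a dense in-mask sample (deterministic, quasi-Newton;
  converges to the same optimum from every pyramid schedule tried).  The
  affine stage keeps seeded stochastic gradient descent with 25 % random
  sampling.
* **Two-channel metric.**  SimpleITK's registration evaluates one
  fixed/moving image pair, so the elastic stage's equal-weight two-channel
  normalized correlation is realised by fusing the per-channel z-scored
  WF and R2* maps into one scalar image before registration.  The exact
  two-channel metric is implemented separately
  (`two_channel_correlation`) for monitoring.
* **Multi-start.**  The b-spline refinement is run from both the affine
  result and the identity, keeping the better final metric.  The affine
  basin is right for genuine inter-subject pose/size differences but can
  trap the refinement when the pair differs by a pure elastic
  deformation.  Chosen on aggregate field-recovery accuracy across
  several synthetic warps.

The metric mask for the elastic stage is the dilated target support with
enclosed holes filled: adipose regions appear as dark holes in the
lean-body image, and their shape is informative.  The backend runs
single-threaded so repeated runs are bit-reproducible.  Elastix-style
parameter values (metric, resolutions, iterations, grid spacing, seed)
are carried in the configuration and written into provenance reports.

A second backend (`SyntheticBackend`) returns externally supplied
deformation fields.  Pipeline tests feed it ground-truth fields so that
fusion, fine adjustment and evaluation are exercised bit-reproducibly,
independent of optimizer behaviour.

## Parameters

| Parameter | Default | Unit | Role |
|---|---|---|---|
| skin strip `ff_max` / `r2s_min` | 0.30 / 80 | – / s⁻¹ | constrained peeling: only skin-like boundary voxels are removed |
| skin closing / final erosion SE | 5 / 7 | voxels (square side) | repair under-skin erosion; trim residual skin |
| background threshold | auto (0.05 × p99) | signal | air/bone removal |
| fine adjust `ff_min` / `r2s_max` | 0.40 / 50 | – / s⁻¹ | adipose extraction inside the crude VOI |
| refine dilation/erosion SE | 3 / 3 | voxels | consolidate residual air/bone before removal |
| vote binarization / majority rule | 0.5 / strict | – | per-atlas vote; "more than half" (exact half fails) |
| affine: resolutions / iterations | 4 / 3000 | – | WF-channel alignment |
| elastic: resolutions / iterations / grid | 4 / 7000 / 20 | – / – / mm | b-spline refinement, both channels 1:1 |
| registration seed | 20170608 | – | seeds the stochastic affine sampling |
| evaluation slices | even (1-based) | – | matches a protocol where reference delineation exists on even slices only |

FF thresholds are written in percent in configuration files and converted
to fractions when parsed.  Clipping of out-of-range FF/WF input to [0, 1]
on construction is this package's choice; reconstruction noise can
produce values slightly outside the physical range.

## Synthetic phantoms

Real cervical-supraclavicular MRI is not redistributable, so validation
runs on phantoms that reproduce the tissue structure the pipeline relies
on: an elliptical body wrapped in 2 voxels of skin (FF 0.10, R2*
100 s⁻¹), a 3-voxel subcutaneous fat ring and a deep adipose pocket
(FF 0.90, R2* 20 s⁻¹) between two near-signal-free bone bars emulating
clavicula and scapula, lean tissue (FF 0.10, R2* 30 s⁻¹), and low-signal
lungs.  Tissue parameters sit clearly on the correct side of every
pipeline threshold — the thresholds are the object under test, not
tissue realism.  R2* is elevated by 40 s⁻¹ in a two-voxel lean-tissue
halo around bone and air (the susceptibility cue the registration's R2*
channel exploits); adipose compartments keep nominal R2* so threshold
behaviour stays unambiguous.

Signals are built per compartment: water = A·(1−FF) + ε, fat = A·FF + ε
with Gaussian ε (SD 0.02 of the tissue amplitude), both clipped at zero,
and FF recomputed from the noisy channels — FF noise is therefore
signal-dependent, as in magnitude data.  A smooth anatomy-anchored
texture (SD 0.04 in FF, 4 s⁻¹ in R2*, 3-voxel correlation length,
clipped at 2.5 SD) rides on the compartment means; unlike the voxel
noise it deforms with the subject and carries the information deformable
registration exploits in real maps (muscle substructure, fascia,
vasculature).  No Rician noise, coil profile or field inhomogeneity is
modelled.

Cohorts derive subjects from one base phantom by smooth random b-spline
deformations (default max amplitude 6 mm, 32 mm control spacing, ±2 mm
translation jitter — folding fields are regenerated at reduced
amplitude), re-synthesizing noise per subject, and shifting the imaged
volume by up to ±1 slice to emulate positioning differences.  Each
subject's true deformation to base space is stored, so ground-truth
atlas→target fields can be composed (via fixed-point field inversion)
and fed to the synthetic backend.  Crude VOIs are the true pocket
dilated by 3 voxels, restricted to adipose+lean tissue, emulating the
manual delineation protocol.

Phantom truth carries two sBAT masks.  `sbat` is the raw anatomical
pocket.  `sbat_ref` is the pocket after the *ideal* fine adjustment (one
in-plane erosion; the thresholds pass everywhere inside the pocket by
construction): the segmentation protocol deliberately excludes the
partial-volume border layer, so a segmentation can match `sbat_ref`
exactly but is geometrically bounded near Dice ≈ 0.9 against the raw
pocket.  Segmentations are therefore judged against `sbat_ref`, the
phantom analogue of a reference-method segmentation; raw-pocket Dice is
reported alongside for transparency.

What passing phantom tests does *not* show: performance under real
anatomical variability (body-composition range, motion artefacts,
reconstruction bias), robustness of the empirical FF/R2* thresholds on
real tissue, or operator variability in crude delineation.  The phantom
validates the pipeline's mechanics — morphology, voting, registration
recovery, protocol identities — not clinical accuracy.

## Numerical choices and degenerate inputs

* Background threshold comparison is strict (`>`); the vote threshold and
  both FF thresholds are inclusive (`≥`), R2* limits inclusive (`≤`/`≥`),
  matching how the clinical limits are quoted ("≥ 40 %").
* A tied vote (exactly half of representing atlases) does **not** label
  the voxel ("more than half", taken literally).
* Physical positions are `index × spacing`; scanner origin/orientation
  are not modelled (all maps of a subject are inherently co-registered,
  and inter-subject alignment is the registration's job).  Deformation
  fields are dense displacement fields in mm on the target grid; mapped
  positions outside the source grid (or outside the source's imaged
  volume) mark the voxel as not represented rather than reading zero.
* Field inversion (needed only for composing ground-truth phantom
  fields) uses 30 fixed-point iterations; residual < 0.25 voxel for the
  fold-free fields the generator produces.
* Empty masks: background removal warns on an all-false body mask; fine
  adjustment warns on an empty VOI and returns empty; Dice on two empty
  masks raises (undefined) rather than returning 0; region means over an
  empty mask raise.
* Masks are stored as uint8 {0,1} NIfTI-1; maps as float32 (round-trip
  error ≤ 1e-6).

## Problem sizes

Default phantom grids are 96 × 64 × 12 voxels (1 × 1 × 2 mm).  The test
suite and the acceptance script run registrations at reduced iteration
counts (affine 200, elastic 100–300) — on these phantoms both optimizers
converge well before the clinical defaults (3000/7000), which remain the
configuration defaults.  End-to-end cohorts use 9 atlases with 4 targets
under the synthetic backend and one target under the full registration
backend (9 pairwise registrations).

## Known limitations

* The elastic stage optimizes a fused-channel correlation, an
  approximation of the weighted sum of per-channel correlations (exact
  only for equal per-channel variances over the support).
* Warp-recovery accuracy is edge-limited: inside homogeneous tissue the
  correlation metric cannot pin the field, and the propagated-mask Dice
  of a small high-surface structure saturates around 0.95 even with
  sub-voxel mean field error (~0.3 mm in the pocket).
* The phantom's inter-subject model (warps of one base anatomy) cannot
  represent topology differences between subjects.
* No weighted or similarity-adaptive voting; the fusion rule weighs all
  representing atlases equally.
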