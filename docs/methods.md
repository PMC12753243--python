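# Methods

`mrbodycomp` re-creates, at desk scale, an automated body-composition (BC)
monitoring workflow for pelvic MR-guided radiotherapy: multi-class
segmentation of skeletal muscle and subcutaneous adipose tissue (SAT) on axial
T2-weighted slices at the S1 (sacral base) level, rigid registration of every
on-treatment scan to the patient's first fraction, intramuscular adipose
tissue (IMAT) extraction by intensity thresholding, and longitudinal analysis
of relative area changes across treatment groups. Because on-treatment
patient images are not publicly available, the package ships a synthetic
pelvic-phantom cohort generator with fully programmed ground truth, so every
stage is testable against known answers.

## Synthetic pelvic phantom

**Continuous anatomy.** A phantom is a set of parametric shapes in physical
(mm) coordinates: an elliptical body outline, a SAT ring of configurable
thickness just inside it, six muscle compartments (paired paraspinal ellipses,
gluteal ellipses, psoas disks; ≈85 cm² total, a plausible S1-level
cross-section), a sacral trapezoid with bright marrow and a dark cortical rim,
and an anterior bowel ellipse containing 3–6 randomly placed gas pockets.
`resolve_spec` freezes all random choices (gas-pocket geometry, per-slice
boundary jitter) so the same *continuous* anatomy can be rasterized
repeatedly. Rasterization evaluates shape membership at pixel centers;
a rigid setup error is applied by inverse-mapping the pixel grid before the
membership tests, so inter-fraction motion is realized with sub-pixel
fidelity, exactly as a scanner samples a displaced patient. A multi-slice scan
is three adjacent slices (S1−1, S1, S1+1): the same anatomy with small,
slice-specific boundary jitter (±1 mm center, ±2% axes), fixed over time.

**Intensities.** Each pixel draws from its tissue's Normal(mean, SD) in
arbitrary units with T2w-like ordering — fat and marrow bright (85, 78),
bowel/viscera intermediate (55), muscle lower (45), cortical bone and gas dark
(16, 8) — plus optional global additive noise (σ = 2) and an optional smooth
multiplicative bias field (off by default). Only the ordering and separation
of the distributions are contracted; the muscle/viscera overlap is deliberate,
since the difficulty of separating muscle from bowel on T2w drives the design
of the segmentation model. IMAT is rendered as small fat-intensity clusters
(radius 4 mm) inside muscle at stable per-patient sites.

**Programmed atrophy.** Per-ROI daily fractional change rates (linear in
days) are drawn per patient from the group preset. Area — the measured
endpoint — is the controlled quantity: at elapsed day *d* each compartment is
eroded or dilated to exactly `round(n0 · (1 + rate/100 · d))` pixels by
ranking pixels on the signed Euclidean distance to the boundary (muscle
resizes against the viscera, SAT at the skin), and the IMAT cluster pixel
count is re-selected to its own exact target. Rounding error is ≤ 0.5 px, so
at the default cohort grid (256 px, 1.875 mm pixels; IMAT pool ≈ 290 px) the
realized trajectory matches the programmed one within 0.2 percentage points
for every ROI. A request that would empty a compartment raises a
degenerate-anatomy error.

**Cohort presets.** Three treatment groups are built in, five scans each:
20 fractions + androgen deprivation therapy (ADT) — n = 27, weekly imaging
over 27 days; 5 fractions + ADT — n = 21; 5 fractions without ADT — n = 22,
both imaged over 10 days. End-of-schedule group means follow the changes
reported for these regimens (20#+ADT: muscle −1.0%, SAT −1.9%, IMAT −1.8%;
5#+noADT muscle +0.2%); patient-level SDs are reconstructed as SEM·√n from
the reported mean ± SEM (e.g. muscle 0.4·√27 ≈ 2.1%). Quantities not reported
for the 5-fraction arms (their SAT/IMAT means) are set to small plausible
values and are not used as recovery targets. Per-fraction setup error is
uniform in ±5 mm per axis and ±3°; fraction 1 is the reference and carries
none. Identical seeds give bitwise-identical cohorts (all randomness flows
from one `SeedSequence`).

## Mask algebra

The bowel-and-bone (BB) mask is `convex_hull(SAT) \ SAT \ muscle`, with the
hull taken over SAT pixel centers and membership inclusive at the hull
boundary. IMAT is `{p ∈ muscle : I(p) > mean + 1·SD}` where mean and
*population* SD are computed over the muscle pixels of the current image
(strict inequality, per-image threshold); lean muscle is `muscle \ IMAT`.
Areas are `pixels · spacing² / 100` cm², averaged over the three S1±1 slices.

## Segmentation model

A five-level encoder–decoder with skip connections, built on a small
self-contained numpy layer library (im2col convolutions with BLAS matmuls,
hand-derived backward passes, gradient-checked in the tests). Each block is
3×3 conv → instance normalization → ReLU, two per block; channel widths
(8, 16, 24, 32, 48); 2×2 max-pool down, nearest-neighbor ×2 up, 1×1 output
head. Variant A predicts four classes (background, muscle, SAT, BB) so the
intensity-ambiguous internal structures have their own output; variant B
drops BB. An ablation mode can feed the ground-truth BB mask as an extra
input channel during training. IMAT is never a training class.

Training: Adam at a constant 3×10⁻⁴ (a cosine decay was evaluated and
consistently hurt final boundary accuracy), batch size 2, combined loss
`CE + (1 − mean multiclass soft-Dice)` with smoothing 10⁻⁶, early stopping on
validation mean Dice (patience 10, max 200 epochs by default). Augmentation:
horizontal flips (p = 0.5) and random rotations within ±3°. The rotation
range matches the inter-fraction setup-rotation scale; wider ranges
measurably reduced muscle Dice on this orientation-fixed anatomy. Rotations
use one shared nearest-neighbor coordinate map for image and labels — phantom
boundaries are pixel-crisp, and linear interpolation would create blended
boundary intensities that no real sample shows at evaluation time. Per-image
z-score normalization; He initialization; fixed seeds make two runs
bitwise-identical on the same machine.

Cross-validation follows the rotated 5-fold scheme: images are shuffled into
five folds; rotation *r* evaluates fold *r*, validates fold *r*+1, trains on
the remaining three, so each image is evaluated exactly once. The desk-scale
experiment (30 slices at 96×96, 110 epochs per rotation, ≈12 CPU-minutes
total) is the package's standard benchmark; 480×480 remains available as the
faithful-geometry configuration.

## Metrics

Dice `2|A∩B|/(|A|+|B|)` (1.0 for two empty masks); boundary pixels are mask
pixels with a 4-neighbor outside the mask (grid border counts as outside);
MSD averages the two directed mean boundary distances; HD95 is the
linear-interpolation 95th percentile of the *pooled* directed distances. An
empty mask makes surface distances undefined and is reported as a
segmentation failure, never as an infinite distance. Cross-fold summaries are
means with t-distribution 95% CIs (df = folds − 1). All three metrics equal
brute-force oracles (all-pairs distances, exhaustive hull membership) on
randomized masks in the test suite.

## Registration

In-plane rigid (3 DOF) registration maximizing normalized cross-correlation:
an FFT cross-correlation translation initializer and multi-start Powell at
half resolution, then a short full-resolution Powell polish. The problem is
mono-modal, so NCC suffices; 3 DOF matches the fixed three-slice axial
measurement window. Scans whose similarity stays below 0.70 are excluded with
a failure flag rather than measured badly. On default cohorts ≥95% of scans
recover the programmed transform within 0.5 mm / 0.5°.

Masks and the IMAT threshold are evaluated in each scan's **native frame**:
the registration transform propagates the S1 level and gates quality, but
in-plane areas are rigid-invariant, and intensity statistics computed after
interpolation are systematically inflated (a crisp baseline compared against
interpolation-blurred follow-ups biased the measured IMAT trajectory by
several percentage points) — the same reason radiomics pipelines compute
intensity features in native space. `measure_cohort(...,
resample_for_measurement=True)` restores measurement on the registered grids.

## Longitudinal statistics

Relative changes are percentage differences from the first fraction. Any
single measurement with |change| > 10% is excluded (strict inequality,
measurement-level — not whole-patient — exclusion; the exclusion count is
reported). Group trajectories are means with normal-approximation 95% CIs
(±1.96·SEM); end of treatment is the fifth (last) scan. Group and ROI
distributions are compared with two-sided Mann–Whitney U tests
(U = min(U₁, U₂); exact enumeration when n₁+n₂ ≤ 16 without ties, otherwise
normal approximation with tie and continuity corrections). Raw p-values are
reported by default, matching common practice for exploratory monitoring; a
Benjamini–Hochberg adjustment is available as an option.

## What the phantoms do and do not show

Passing tests demonstrate that the *measurement chain* is unbiased and
correctly calibrated on images whose ground truth is known exactly:
registration recovers programmed motion, areas track programmed atrophy to
fractions of a percentage point, the IMAT threshold tracks programmed fat
fractions, the network reaches clinical-grade Dice on the phantom contrast,
and zero-signal cohorts produce the nominal false-positive rate. Phantoms do
not emulate MR physics (no k-space, coil bias by default, partial volume,
motion artifacts), out-of-plane anatomy changes, elastic deformation, or the
inter-observer variability of manual contours — so they validate the
software, not clinical performance on patient data.

## Numerical choices and limitations

* Exact-count atrophy needs an IMAT pool ≥ 250 px for the 0.2 pp tolerance;
  at grids coarser than ~220 px the IMAT rounding granularity exceeds it.
* Ties in the distance-ranked erosion/dilation and IMAT truncation break
  lexicographically (row, then column) for determinism.
* The Rician noise floor of magnitude MR is approximated as Gaussian;
  downstream measurements use only relative intensities.
* Intensity units are arbitrary; nothing downstream depends on their scale
  (the IMAT rule is invariant to affine intensity maps, which is tested).
* The 200-replicate zero-signal calibration draws end-of-treatment changes
  from the zero-signal noise distribution and runs the package's comparison
  path; generating 200 full imaging cohorts would add nothing to the
  statistical content at ~1000× the cost. A full zero-rate cohort runs
  through the entire pipeline once in the test suite.
* With five folds the t-based CIs are wide; the reported means are the
  primary quantities.
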