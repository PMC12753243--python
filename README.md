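# mrbodycomp

Body-composition monitoring on MR-guided radiotherapy images, exercised end to
end on synthetic pelvic phantoms with programmed ground truth.

Patients on an MR-linac are imaged at every treatment fraction, which makes it
possible to track skeletal-muscle and adipose-tissue changes *during*
radiotherapy — an early-warning signal for sarcopenia and treatment-related
deterioration. This package implements that workflow for axial T2-weighted
slices at the S1 (sacral base) level:

* **Segmentation** — a five-level U-Net (self-contained numpy implementation,
  manually differentiated and gradient-checked) predicting background, muscle,
  subcutaneous adipose tissue (SAT), and optionally a bowel-and-bone (BB)
  class that absorbs the internal structures whose T2w intensities overlap
  muscle. Trained with Adam (lr 3·10⁻⁴) on a combined cross-entropy +
  multiclass soft-Dice loss under rotated 5-fold cross-validation, in two
  variants (A: with BB class, B: without).
* **Mask algebra** — BB = convex_hull(SAT) \ SAT \ muscle; intramuscular
  adipose tissue IMAT = muscle pixels brighter than the per-image
  mean + 1 SD of muscle intensities; lean muscle = muscle \ IMAT; areas in cm²
  averaged over the three S1±1 slices.
* **Rigid registration** of every on-treatment scan to the patient's first
  fraction (3 DOF, normalized cross-correlation, multi-start Powell), with
  similarity-floor exclusion of failed scans.
* **Longitudinal statistics** — relative changes vs fraction 1, exclusion of
  measurements with |change| > 10%, group mean trajectories with 95% CIs, and
  two-sided Mann–Whitney U comparisons (exact for small tie-free samples).
* **Evaluation metrics** — Dice, mean surface distance (MSD) and
  95th-percentile Hausdorff distance (HD95), all verified against brute-force
  oracles, summarized across folds with t-distribution CIs.
* **Synthetic cohorts** — since the clinical images are not public, a phantom
  generator simulates three treatment groups (20 fractions + ADT, n = 27 over
  27 days; 5 fractions ± ADT, n = 21/22 over 10 days; five scans each) with
  per-patient atrophy rates, exact programmed compartment areas, and rigid
  inter-fraction setup errors — so every pipeline stage can be validated
  against known truth.

See `docs/methods.md` for the full model description and design rationale.

## Worked example

```python
from mrbodycomp.pipeline import run_parameter_recovery

res = run_parameter_recovery(("20adt",), grid_size=256, seed=1)
for (group, roi), (mean, sem, n) in sorted(res["end_means"].items()):
    print(f"{group} {roi:12s} {mean:+.2f} % ± {sem:.2f} (n={n})")
```

This simulates the 20-fraction + ADT cohort (27 patients, five scans over 27
days, default noise and setup error), registers every scan to fraction 1,
measures 3-slice mean areas from the ground-truth masks with IMAT thresholded
per image, filters |change| > 10% outliers, and prints the group-mean
end-of-treatment changes:

```
20adt imat         -1.85 % ± 0.97 (n=26)
20adt lean_muscle  -0.53 % ± 0.52 (n=27)
20adt muscle       -0.73 % ± 0.42 (n=27)
20adt sat          -1.73 % ± 0.64 (n=26)
```

The programmed group means are muscle −1.0%, SAT −1.9%, IMAT −1.8%; each
recovered mean lands within twice its standard error — the pipeline is
unbiased, and the residual deviation is patient-sampling noise (n = 27 rates
drawn per patient). One IMAT and one SAT endpoint were excluded by the >10%
outlier rule (n = 26).

The same workflow is available from the shell:

```
mrbodycomp simulate --preset 20adt --grid 256 --seed 1 --out cohort/
mrbodycomp register --cohort cohort/manifest.csv --out transforms.json
mrbodycomp run-all --config config.yaml --out results/
mrbodycomp evaluate --variant A --n-slices 30 --grid 96 --out metrics.csv
```

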