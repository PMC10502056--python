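# submem

A desk-scale toolkit for analysing the neurofunctional correlates of
individual differences in episodic memory with task fMRI.  It covers the
whole chain of a picture-encoding / free-recall study:

- **Synthetic cohorts** — event schedules (2.5 s pictures after a 0.5 s
  fixation cross, 9–12 s jittered intertrial periods, scrambled
  geometrical-figure control trials, primacy/recency buffers), a
  Rasch-like recall model `P(recall_si) = logistic(ability_s + easiness_i)`,
  and 4-D BOLD volumes with planted encoding, subsequent-memory,
  individual-difference and network signals, AR(1) noise and drift.
- **First-level GLMs** — canonical double-gamma HRF convolution, parametric
  modulators with serial orthogonalization (each modulator residualized
  against the unmodulated regressor and all earlier modulators), a 128 s
  discrete-cosine high-pass basis, six motion nuisance regressors, AR(1)
  prewhitening, and contrast images such as
  *pictures recalled − not recalled* and *pictures − scrambled figures*.
- **Group inference** — voxel-wise linear models of the mean effect or of
  the brain–behavior slope (recall count, adjusting for age, sex and batch
  factors), family-wise error control by the permutation distribution of
  the maximum |t| (Freedman–Lane scheme), and a 20-voxel cluster-extent
  filter.
- **Effect-size reproducibility** — the standardized effect size
  `r = sign(b) · |t| / sqrt(t² + df)` of ROI-mean activation on recall,
  resampled over log-spaced sample sizes (n = 26 … 1000), plus the
  whole-brain t-on-t regression comparing subsequent-memory and
  brain–behavior maps through its residuals.
- **Network arm** — group spatial ICA (fixed-point negentropy contrast,
  PCA whitening, symmetric decorrelation) on temporally concatenated runs,
  split-half replicability matching (|r|max ≥ 0.7), stage-1 dual
  regression, per-component task responsivity (standardized beta of
  pictures minus figures) and Bonferroni-corrected responsivity–recall
  models (p < 0.05/K; 0.05/60 ≈ 8.33e-4 at study scale).

## Worked example

```python
import numpy as np
from submem import (CohortSpec, generate_cohort, build_first_level_design,
                    fit_first_level, compute_contrast, build_group_design,
                    fwe_correct)

spec = CohortSpec(n_subjects=30, n_items=24, n_scrambled=8,
                  grid_shape=(12, 12, 8), seed=7)
cohort = generate_cohort(spec)

stack = []
for s, (events, run) in enumerate(zip(cohort.events, cohort.runs)):
    X = build_first_level_design(events, run.n_volumes, spec.tr,
                                 scheme="picture_encoding", motion=run.motion)
    fit = fit_first_level(run, X)
    con = compute_contrast(fit, {"pictures": 1.0, "figures": -1.0})
    stack.append(con.values)
stack = np.stack(stack)

design = build_group_design(cohort.phenotype, predictor="intercept")
mask = np.ones(spec.grid_shape, dtype=bool)
result = fwe_correct(stack, design, mask, n_perm=500, seed=0)
print(f"corrected |t| threshold: {result.t_threshold:.3f}")
print(result.clusters)
```

Output:

```
corrected |t| threshold: 4.616
   cluster_id  sign  n_voxels     peak_t  i  j  k
0           1     1        72  29.440024  4  3  3
```

The corrected threshold (4.616) is the 95th percentile of the null
distribution of the maximum |t| over the 1152-voxel grid — far above any
pointwise two-sided t cutoff, as whole-brain correction demands.  The one
surviving cluster (72 voxels, peak t = 29.4 at voxel 4, 3, 3) is the
planted picture-encoding region: the generator centres that blob at
fractional grid position (0.25, 0.25, 0.4), i.e. around voxel (3, 3, 3)
on a 12 × 12 × 8 grid, and the cluster spreads over the blob's extent.

## Command-line pipeline

Each stage is a subcommand writing into a shared output directory and
reading upstream results by manifest:

```bash
submem simulate    --out out --profile desk --seed 7
submem firstlevel  --out out
submem group       --out out
submem resample    --out out
submem compare-maps --out out
submem ica         --out out
submem dualreg     --out out
submem responsivity --out out
submem report      --out out
# or: submem run --out out --profile desk --seed 7
```

`--profile desk` (default) runs a small cohort in minutes; `--profile
paper` switches to study-scale settings (72 + 24 + 4 pictures, 420-volume
runs, K = 60 components, 5000 permutations and resampling replicates).

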