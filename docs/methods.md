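# Methods

`restnh` implements a complete resting-state fMRI group analysis restricted to
a small labeled network mask, together with a synthetic cohort generator that
implants known effects so every stage of the pipeline can be validated
end-to-end. This document describes the statistical model of each stage, the
generator, and the numerical choices. All problem sizes (grid shapes, subject
counts, simulation counts) are this package's own defaults and can be changed
through the configuration dataclasses.

## 1. Data model

- **BOLD series**: 4D array (x, y, z, t) with an affine and a repetition time
  (TR). NIfTI-1 on disk; `scl_slope`/`scl_inter` scaling is applied on read.
- **Network mask**: 3D integer label image. Label 0 is background; each
  positive label is a named region. All feature and inference computations
  are restricted to mask voxels.
- **Subject record**: group (`patient`/`control`), demographics, clinical
  scores, mean framewise displacement, optional file paths. Stored as a TSV
  manifest.

## 2. Synthetic cohort generator

Each region is a voxel-radius sphere on a regular grid (defaults: 16 x 16 x 12
grid, 3 mm isotropic voxels, four non-overlapping spheres of radius 3 named
`right_frontal`, `left_frontal`, `right_striatum`, `limbic`; 40 patients and
38 controls; TR 2 s; 240 volumes).

Per voxel v in region R of subject s, the generated series is

```
x_v(t) = baseline + noise_sd * e_v(t) + a_s,R * [ sqrt(f_s,R) * C_R(t) + sqrt(1 - f_s,R) * U_v(t) ]
```

- `e_v` is AR(1) noise (coefficient 0.3), independent per voxel.
- `C_R` (one per region) and `U_v` (one per voxel) are unit-variance
  low-frequency signals built in the frequency domain with support only in
  the analysis band (0.01-0.08 Hz), so the structured component is spectrally
  confined by construction.
- `f_s,R` is the **shared fraction**: the proportion of structured variance
  every voxel of the region draws from the common source `C_R`. Because the
  two components are independent and unit variance, the expected pairwise
  correlation of the structured part between two voxels equals `f`, which is
  what the network-homogeneity (NH) metric measures. The defaults implant a
  patient-vs-control gap of +-0.2 around a baseline of 0.3
  (`left_frontal`: 0.5 vs 0.3 up; `right_striatum`: 0.1 vs 0.3 down).
- `a_s,R` is the in-band amplitude (default 1.0). For the fALFF effect
  region (`right_frontal`) patients get amplitude multiplied by the
  configured ratio (default 1.5).
- A per-patient latent scalar shifts that patient's shared fractions by
  `latent_fraction_scale` times the latent value, and the same latent value
  is mixed into the Y-BOCS scores to produce a target feature-symptom
  Pearson correlation (default -0.33) in the NH-linked region.
- Structured signal exists **only inside the mask**; outside voxels contain
  baseline plus noise. Motion parameters are smooth random walks scaled to
  produce realistic sub-threshold framewise displacement.

All randomness derives deterministically from the configuration seed and the
subject identifier, so any subject can be regenerated in isolation and
cohort writes are byte-identical across runs.

### Known generator/pipeline interactions

Two deliberate consequences of this model are worth knowing:

- **Coherence gain ("leak") of shared-fraction effects into amplitude
  maps.** Spatial smoothing averages neighboring series; coherent
  (shared) components add constructively while independent components
  cancel, so the smoothed in-band amplitude of a region grows with its
  shared fraction. NH effect regions therefore also show (same-signed)
  fALFF group differences after 8 mm smoothing. Recovery checks are
  consequently phrased per effect and per tail ("the fALFF table contains a
  positive cluster peaking in the amplitude-effect region"), not as "no
  other clusters exist".
- **Within-mask z-standardization couples regions.** Standardizing each
  subject map to zero mean/unit SD inside the mask makes every region's
  z-value depend on the mask mean, so a strong effect in one region induces
  opposite-signed apparent effects elsewhere. This mirrors the behavior of
  the standard mZALFF/mNH practice and is kept; it is the reason the
  classifier validation (below) uses raw NH region means.

## 3. Temporal preprocessing

Per subject, in order:

1. **Discard** the first `n_discard` volumes (default 10).
2. **Framewise displacement** (Power): sum of absolute backward differences
   of the six motion parameters, rotations converted to arc length on a
   50 mm sphere; FD of the first retained volume is 0.
3. **Scrubbing** at `fd_threshold_mm` (default 0.2 mm). `delete` mode drops
   censored volumes after nuisance regression; `censor-in-regression` mode
   adds one-hot spike regressors instead and keeps all volumes. A subject
   retaining fewer than half the volumes is flagged for exclusion.
4. **Nuisance regression**: per-voxel OLS residuals against intercept,
   linear trend, the Friston-24 motion expansion (6 parameters, their
   one-volume lags, and both sets squared), and mean white-matter and CSF
   signals. All-zero regressors (e.g. a motionless run) are dropped; a
   genuinely rank-deficient design is an error.
5. **Band-pass** 0.01-0.08 Hz: an ideal (hard) DFT-domain filter that zeroes
   out-of-band coefficients and always removes DC. It is linear and
   idempotent.
6. **Smoothing**: Gaussian, FWHM 8 mm, **fALFF branch only**, with mask
   renormalization (the kernel is re-normalized over in-mask voxels so
   values never bleed across the mask boundary). The NH branch stays
   unsmoothed so homogeneity is not manufactured by the kernel.

Because every temporal operator here is a fixed linear map applied
identically to all voxels (and smoothing is purely spatial), the two branch
orders commute; computing both branches from one regression/filtering pass
is exact, not an approximation.

## 4. Feature maps

- **fALFF**: with `A_k` the positive-frequency DFT amplitudes of the voxel
  series (DC excluded), fALFF = sum of `A_k` over 0.01-0.08 Hz divided by
  the sum over all positive frequencies. Bounded in [0, 1]; zero-variance
  voxels yield 0 with a warning.
- **NH**: per voxel, the mean Pearson correlation with every other mask
  voxel. Computed exactly via unit-normalized rows and a row-sum identity
  (chunked), which is O(V * T) memory instead of forming the V x V
  correlation matrix.
- NH maps are then lightly smoothed (FWHM 4 mm, one pass, mask-renormalized)
  to mimic the usual NH post-smoothing.
- Both maps are z-standardized within the mask before group inference.

Note the fALFF ceiling: fALFF compares in-band to total amplitude, so when
broadband noise is weak (or heavily averaged away by smoothing) both groups
saturate near 1 and an amplitude ratio no longer moves the statistic. The
default noise level (SD 1.0 against in-band amplitude 1.0) keeps the metric
in its sensitive range.

## 5. Group inference

- **Voxelwise GLM**: per voxel, OLS of the feature on intercept, group
  indicator (patient = 1), and mean-centered covariates (default: age, sex,
  mean FD); the group-coefficient t-statistic is reported
  (df = n - p).
- **Smoothness estimation**: each residual map is scaled to unit within-mask
  variance; `lambda_i` is the mean squared forward difference along axis i
  over in-mask voxel pairs, averaged over subjects, giving
  `FWHM_i = sqrt(4 ln 2 / lambda_i)` voxels. Unsmoothed white noise yields
  about 1.18 voxels.
- **GRF cluster-extent threshold**: with voxel threshold
  `u = Phi^-1(1 - voxel_p_per_tail)` and resels
  `S / prod(FWHM_i in voxels)`, the expected cluster count is
  `E[m] = resels * (4 ln 2)^(3/2) (2 pi)^-2 u^2 exp(-u^2/2)`, and the
  cluster-size distribution uses
  `P(n >= k) = exp(-beta k^(2/3))` with
  `beta = (Gamma(5/2) E[m] / (S Phi(-u)))^(2/3)`. The familywise
  probability of any cluster of size >= k is `1 - exp(-E[m] P(n >= k))`;
  the threshold `k_min` is the smallest k bringing it under the cluster
  threshold.
- **Two-tailed searches halve both thresholds**: the voxel p *and* the
  cluster p are each split across the two tails (0.0005 and 0.025 by
  default), i.e. a Bonferroni split over tails, keeping the total
  cluster-level FWER at the nominal 0.05. Measured FWER of the full
  estimate-then-threshold procedure on 500 pure-noise study-size
  simulations is about 0.03.
- A group-label **permutation** alternative (max-cluster-size null) is
  provided as an internal oracle for the analytic threshold.
- Clusters are connected components (default 18-connectivity) per tail with
  size >= `k_min`; each reports peak coordinate (mm), extent, peak t, sign,
  and the mask region containing the peak. Peak ties break on the lowest
  C-order voxel index.

## 6. Clinical correlations

Per significant cluster, the mean (standardized) feature value over the
cluster's voxels is correlated (Pearson) with each clinical score across
patients only. Missing scores are dropped pairwise, never imputed; fewer
than 4 complete pairs is an error. Two-tailed p comes from
`t = r sqrt(n-2)/sqrt(1-r^2)`; Bonferroni correction multiplies by the whole
family size (features x scores) by default.

## 7. Classification

Cluster-mean features feed an RBF-kernel SVM evaluated by leave-one-out
cross-validation over every single feature and every unordered pair. Feature
standardization is always fit on the training fold only.

- `paper_loocv` (default) replicates the common single-loop procedure: a
  `(C, gamma)` grid search (defaults `log2 C` in -5..15 step 2, `log2 gamma`
  in -15..3 step 2) where each grid point is scored by whole-set LOOCV
  accuracy and the winner's predictions are reported. Because the
  hyperparameters see every fold, the estimate is optimistically biased —
  including under permuted labels, where grid-maximizing pushes "chance"
  accuracy several points above 50%. A permutation null therefore has to be
  computed at a fixed hyperparameter point.
- `nested_loocv` selects `(C, gamma)` inside each outer training fold and is
  the unbiased variant.

Ranking ties break on higher sensitivity, then fewer features, then input
order.

## 8. Numerical choices and determinism

- DFT operations use real FFTs; band membership uses half-open tolerance
  `1e-12` so exact band-edge bins are included.
- All random streams are `numpy.random.Generator` (PCG64) seeded
  deterministically from configuration seed plus subject id; no global RNG
  state is used.
- NIfTI writes contain no timestamps; repeated runs are byte-identical,
  which the pipeline uses for content-hash-based stage resumption.
- Default problem sizes: study scale is 78 subjects on a 16 x 16 x 12 grid
  (492 mask voxels), about 7-8 s per cohort for simulation through feature
  maps on one CPU core; group inference adds well under a second. Unit
  tests run on much smaller grids; calibration checks use 500 noise
  simulations at study size (~15 s).
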