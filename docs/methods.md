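# Methods notes

This document records the statistical model, the defaults and the design
choices made where the design was genuinely open, in enough detail to
reproduce or audit any stage. No empirical claim is made here that the test
suite or `scripts/acceptance.py` does not itself compute.

## Normative model

Per voxel v, control GMV is modelled as a zero-mean Gaussian process over
covariates x = (standardized age, sex ∈ {0, 1}) after centring the training
values:

    y_v ~ N(0, τ_v · M),   M = w_rbf K_rbf(age; ℓ) + w_lin K_lin + r I

with an RBF kernel on standardized age, a linear kernel on the standardized
sex code (optionally plus extra linear covariates such as TIV via
`extra_linear`), and white noise. The weights (w_rbf, w_lin, r) are a
convex split of the unit marginal variance and τ_v is a per-voxel scale.

*Fitting.* All voxels share the covariates, so one Cholesky factor of M
serves every voxel for a given hyperparameter setting, and the profile
maximum-likelihood scale is closed-form (τ̂ = yᵀM⁻¹y / n). Hyperparameters
are selected per voxel by exact log-marginal-likelihood maximization over a
bounded log-space candidate set: a deterministic grid (ℓ ∈ [0.25, 2] in
standardized-age units, noise fractions 0.02–0.99, four RBF/linear splits)
plus seeded random candidates playing the role of random restarts
(`n_restarts`, default 3, contributing 4·n_restarts draws). This keeps
per-voxel fits independent and deterministic under a fixed seed while
remaining fast enough for thousands of voxels on one CPU.

*Scoring.* Z = (y − μ*)/σ*, where σ*² is the latent predictive variance
plus the fitted noise variance — so a subject exactly on the predictive
mean scores 0 and a well-specified model yields Z ≈ N(0, 1) on held-out
controls (verified empirically: |mean| < 0.05, SD within 10% of 1, 95%
interval coverage 90–98%). Ages outside the training range trigger an
extrapolation warning but are scored. Voxels with control variance below
1e-8 are fitted as intercept-only with a machine-epsilon noise floor and
flagged; they should be excluded from decomposition.

*Evaluation.* Standardized MSE = pooled squared prediction error divided by
the variance of the held-out truths; 1.0 corresponds to predicting the
held-out mean (uninformative covariates give ≈ 1 by construction), smaller
is better. Reported per fold and pooled over a seeded 10-fold split;
`transfer_fit_check` applies a fitted model to an independent control
cohort without refolding.

## Sign splitting and factorization

Deviations are split exactly as D⁺ = max(Z, 0), D⁻ = max(−Z, 0) (so
D⁺ − D⁻ = Z bit-exactly) and the two parts are processed fully
independently, including rank selection.

Single NMF runs minimize squared Frobenius error with multiplicative
updates from seeded random nonnegative initialization (scikit-learn's
`solver="mu"`), capped at 500 iterations with relative tolerance 1e-5. The
scale indeterminacy is resolved by rescaling H rows to unit Euclidean norm
with the compensating scale absorbed into W; all reported loadings live on
this scale. A plain multiplicative-update reference implementation with a
per-iteration objective trace backs the monotonicity property test and
cross-checks the production solver on small problems.

*Stability value.* For each K, R restarts are pairwise aligned with the
Hungarian algorithm on cost 1 − Pearson r between factor maps; the R × R
matched-mean-correlation matrix is averaged (diagonal included by default —
inclusion shifts every K equally and cannot change the argmax at fixed R;
the exclusive mean is available). K is chosen as the argmax over the search
range (default 2–10), ties toward smaller K.

*A caveat on rank selection.* Restart agreement is near-perfect not only at
the true factor count but at every K below it: the merged (under-K)
factorization occupies a single dominant optimization basin, so restarts
agree almost exactly, while K above the truth splits noise arbitrarily and
destabilizes. The stability profile therefore looks like a high plateau
ending at the true K followed by a decline, and the argmax typically sits
at the low end of the plateau. In practice this means the selected K equals
`k_min` whenever `k_min` does not exceed the data's true rank; the full
profile is always returned so the plateau and its knee can be inspected.
Synthetic experiments in the test suite document this: a planted rank equal
to `k_min` is selected essentially always, a planted rank strictly inside
the range is not. Knee- and plateau-threshold variants were evaluated and
found unreliable on the same fixtures (the profiles of adjacent true ranks
overlap), so no alternative rule is shipped.

*Consensus.* The reference run has the highest mean agreement with all
others (ties → earliest run); every run's H rows and W columns are permuted
to the reference and averaged elementwise, then renormalized. Both W and H
enter the average, aligned by the same permutations.

*Variance explained.* Per patient, the deviation row is regressed on the k
factor maps without intercept; R² is uncentered
(1 − ‖resid‖²/‖row‖² ∈ [0, 1]), consistent with the intercept-free bilinear
model. A centered alternative sits behind a flag and is recorded in the
result.

## Permutation significance

The null shuffles each patient's voxel values independently (distinct
sub-seeds per row), preserving every patient's deviation distribution while
destroying shared spatial structure; shuffling patients within voxels is
available behind `axis="subjects"`. For every permutation the stability at
the selected K and the per-patient variance explained (from that
permutation's consensus factors) are recomputed; p values use the add-one
estimator (1 + #{null ≥ obs}) / (1 + n_perm), never 0; per-patient p values
are BH-FDR adjusted. For tractability the null uses a reduced protocol
(default 20 restarts, capped iterations), applied identically to the
observed value entering the comparison; a full-protocol observed stability
can be reported separately.

Two practical findings from the synthetic calibration, relevant to real
use: (i) the test is exactly calibrated only insofar as deviations are
voxel-exchangeable under the null — normative *estimation error* (per-voxel
σ̂ heterogeneity, shared mean-error modes) is real structure shared across
patients and inflates rejections when the control sample is small; with a
few hundred controls it is negligible. (ii) The stability statistic
saturates near 1 when very few restarts are used, for observed and null
alike, destroying discrimination; ~8+ restarts per permutation restore it.
The packaged calibration experiments use a 400-control null cohort and an
8-restart power fixture accordingly.

## Robustness, transfer, bridge

*Robustness.* Factors are refitted (consensus over 20 restarts by default)
on repeated random ⌈0.9 n⌉-patient subsamples with K held fixed, matched to
the full-sample factors, and summarized by per-factor Spearman correlations
of matched H rows (over voxels; the headline) and matched W columns (over
the sampled patients) — both are reported because map- and
composition-level stability can differ. Failed repeats are flagged, never
dropped.

*Transfer.* New-cohort compositions are predicted as intercept-free
least-squares coefficients of each deviation row on the discovery factor
maps, unclipped (an NNLS option exists and is recorded). Evaluation refits
consensus factors on the new cohort at the discovery K and Hungarian-
matches predicted to independent compositions on W-column Spearman (cost
1 − ρ); the H-map match is reported as a cross-check.

*Bridge.* The group map is a per-voxel OLS of GMV on
[intercept, patient indicator, age, sex, education, TIV]; t is the group
coefficient over its standard error, with a BH-FDR display mask — the
regression on factors always consumes the unthresholded map. The bridge fit
itself is intercept-free (an intercept option is recorded in the result);
F = (R²/k)/((1 − R²)/(m − k)) with m the voxel count. Voxels are spatially
autocorrelated in real data, so the bridge F and p are anti-conservative;
they are reported as-is and should be read descriptively. The bridge
coefficients, whose scale is arbitrary, are standardized with the patients'
per-column constants before joining the t-SNE embedding
(perplexity min(30, ⌊n/4⌋), PCA initialization, seeded).

## Clinical association and annotation

Spearman correlations are computed pairwise-complete per (factor, measure)
cell with ≥ 5 pairs required, BH-FDR over the full grid (the stricter family
choice). Contrasts use the pooled-variance two-sample t with
Cohen's d = (mean₁ − mean₂)/pooled SD; zero-variance groups fall back to
Welch with a flag. Onset splits at 18 years (≤ 18 adolescent, > 18 adult)
and is FDR-corrected across factors; the sex contrast is reported with raw
p values, matching the convention of reporting uncorrected sex t tests.

Annotation reduces a factor to its top 5% of in-mask voxels (ties broken
toward the lower voxel index; the fraction is of in-mask voxels) and scores
each term map by its mean activation over that set against a null of
equal-size uniformly random in-mask voxel sets, one draw serving all terms
per permutation; add-one p, BH-FDR across terms, and a word-cloud weight of
1/p are reported. The random-voxel null ignores spatial autocorrelation of
term maps, so p values for spatially smooth terms are somewhat liberal; a
spatially-structured null would need a geometry (surface rotation or
volumetric block permutation) that the synthetic lattice mask does not
meaningfully support, and is left to the caller's term-map preprocessing.

## Synthetic cohorts

The generator emulates exactly the structure the framework assumes:

- **Mask**: the ⌈fraction · grid⌉ voxels closest (in ellipsoid-normalized
  distance) to the grid centre, 1.5 mm isotropic affine.
- **Controls**: GMV = smooth baseline + monotone-decreasing per-voxel
  quadratic in age (−c₁u − c₂u², u ∈ [0, 1] over the age range, c₁, c₂ ≥ 0
  spatially smooth — something genuinely nonlinear for the GP to learn) +
  smooth sex offset + i.i.d. Gaussian noise (default SD 0.2); values are
  clipped at 0 and the clip fraction recorded.
- **Patients**: controls' model plus `W⁺H⁺ − W⁻H⁻` with gamma-distributed
  loadings (shape 4, mean `loading_scale`; `loading_scale=0` gives an exact
  null cohort) and factor maps built from 2–4 Gaussian blobs at random
  in-mask sites, unit maximum, resampled until pairwise correlation ≤ 0.3
  *across all factors of both signs* — opposite-sign factors cancel where
  they coincide, which is a property of the rectification, not of the
  estimator, so planted factors are kept spatially distinct. Default blob
  radius 1.5 voxels gives factor supports of roughly 5–15% of the mask,
  like focal anatomical patterns.
- **Clinical scores**: HAMD factor-score marginals typical of first-episode
  outpatients; the i-th subscale can be coupled to the i-th factor's
  loading through a Gaussian copula on ranks, hitting a target rank
  correlation without distorting the marginals. Education, TIV and image
  quality are independent draws; onset age = age − gamma-distributed
  duration.
- **Seeding**: `seed` drives subject-level draws; `structure_seed`
  (defaulting to `seed`) drives the spatial truth, so two specs sharing
  `structure_seed` yield independent cohorts from one generative process
  (paired discovery/validation designs). Identical specs are bit-identical.

What the generator does **not** emulate — and hence what green tests do not
certify about real data: spatial autocorrelation of the noise (smoothing),
site and scanner effects, non-Gaussian residuals, registration error,
partial-volume artifacts, and any coupling between symptoms and factors
beyond monotone rank association.

## Problem sizes and numerical conventions

The heavier synthetic experiments use a 60-patient, ~3200-voxel standard
cohort (20 NMF restarts) for recovery checks; normative calibration uses
120 training and 120 held-out controls over ~500 voxels; permutation
calibration uses 20 replicate null cohorts at 200 permutations with 3
restarts each. These sizes were chosen once as the smallest that leave
comfortable margins on the quantities being estimated. Other conventions:
affine agreement tolerance 1e-4 (images are never resampled); top-fraction
ties break toward the lower linear voxel index; stability ties toward
smaller K; add-one permutation p values; BH-FDR everywhere an FDR is named;
all randomized operations take explicit integer seeds, and the pipeline
fans a single global seed into per-stage seeds via `SeedSequence` spawning.

## Known limitations

- Rank selection by restart-stability argmax effectively returns the
  smallest K of the search plateau (see the caveat above); treat the
  reported profile, not the single argmax, as the evidence about K.
- Per-voxel GPs are independent (no spatial pooling), and the candidate-set
  hyperparameter search trades a little likelihood for determinism and
  speed; σ_pred inherits grid granularity.
- The bridge and annotation inferences ignore spatial autocorrelation.
- The permutation null assumes voxel exchangeability of deviations within
  patients; normative misfit violates it slightly, in proportion to
  1/√(control sample size).
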