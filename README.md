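# normfactor

Parse individual-level gray-matter abnormalities into overlapping latent
**disease factors**.

Case–control neuroimaging in heterogeneous disorders such as depression
describes an "average patient" that few real patients resemble. `normfactor`
implements a dimensional alternative for voxel-based morphometry (VBM):

1. **Normative modelling.** For every voxel, a Gaussian-process regression of
   gray matter volume (GMV) on age and sex is fitted in healthy controls.
   Each patient is scored by the signed deviation
   `Z[s, v] = (y[s, v] − μ_pred) / σ_pred` from that norm (Z > 0 = more
   volume than expected). Model quality is assessed by 10-fold
   cross-validated standardized MSE.
2. **Sign-split NMF.** Deviations are split into a positive part
   `D⁺ = max(Z, 0)` and a rectified negative part `D⁻ = max(−Z, 0)`, and each
   is factorized as `D ≈ W H` with `W, H ≥ 0`: rows of `H` are spatial
   disease factors, rows of `W` are per-patient factor compositions.
3. **Stability rank selection.** For each candidate K, NMF is restarted many
   times from random initializations; factors are aligned across every run
   pair with the Hungarian algorithm on Pearson correlations, and the mean
   pairwise agreement (the *stability value*) is maximized over K. Aligned
   runs are averaged into consensus factors.
4. **Inference and validation.** Permutation tests (voxel-shuffled patients)
   for stability and per-patient variance explained; 90%-subsample
   robustness; transfer of factor compositions to unseen cohorts by
   intercept-free regression of new deviation maps on the discovery factors;
   Spearman screens against clinical scores (HAMD factor scores, onset age,
   duration, education) with BH-FDR; functional annotation of each factor's
   top-5% voxels against probabilistic term maps.
5. **Subject-to-group bridge.** The conventional covariate-adjusted
   case–control t map is regressed (no intercept) on all factors; the signed
   coefficients are the factor composition of an "average patient", which can
   be embedded with t-SNE among the real patients.

Because suitable public voxelwise datasets ship no ground truth, the package
includes a first-class synthetic-cohort generator (`normfactor.synthetic`)
that plants known factor maps, loadings, age/sex effects and
clinically-coupled scores, so every stage is testable end to end.

## Worked example

`examples/03_factor_discovery.py` generates a cohort with two planted
positive factors, scores deviations, selects K by stability and checks the
recovery:

```text
stability by K: {2: 1.0, 3: 0.986, 4: 0.926, 5: 0.903}
selected K = 2 (two positive factors were planted)
consensus vs planted maps: matched Pearson r = 0.935
  factor 1: loading Spearman rho = 0.939
  factor 2: loading Spearman rho = 0.934
variance explained per patient: median R^2 = 0.742
```

The stability profile peaks at the planted K; the consensus maps correlate
0.94 with the planted maps after matching, the per-patient loadings rank-
correlate 0.93+, and the two factors explain ~74% of the median patient's
(uncentered) deviation variance. The other examples cover simulation and
I/O (01), normative calibration (02), permutation significance and
robustness (04), transfer and the group-level bridge (05), and clinical
association plus term annotation (06).

A thin CLI wraps the library for shell use:

```bash
normfactor simulate cohort_dir --n-controls 60 --n-patients 40 --seed 1
normfactor run --input-dir cohort_dir --output-dir results_dir --seed 1
```

`run` executes the full pipeline (normative → factors → significance →
robustness → transfer → bridge → clinical → annotation) with a JSON manifest
recording config, seeds and stage timings; `--stages` reruns any subset from
its serialized inputs.

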