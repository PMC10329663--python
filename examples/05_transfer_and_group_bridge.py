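"""Transfer factors to an unseen cohort and bridge to the group-level t map.

Transfer: new patients' compositions are predicted by regressing their
deviation maps on the discovery factors, then compared (after Hungarian
matching) with compositions from an independent factorization of the new
cohort.  Bridge: the conventional covariate-adjusted case-control t map is
regressed on all factors; its coefficients are the factor composition of an
"average patient".
"""

import warnings

import numpy as np

from normfactor import CohortSpec, consensus_factors, embed_compositions, evaluate_transfer, \
    fit_normative, generate_cohort, grouplevel_tmap, predict_composition, \
    regress_tmap_on_factors, score_deviations, split_signed, stability_value

def deviations(bundle, seed=0):
    fit = fit_normative(bundle.control_matrix, bundle.covariates("control"), seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dev = score_deviations(fit, bundle.patient_matrix, bundle.covariates("patient"))
    return split_signed(dev)

# discovery and validation cohorts drawn from one generative process
common = dict(grid_shape=(12, 12, 12), mask_fraction=0.5, structure_seed=9)
disc = generate_cohort(CohortSpec(n_controls=60, n_patients=60, seed=1, **common))
val = generate_cohort(CohortSpec(n_controls=40, n_patients=40, seed=2, **common))

parts = deviations(disc)
cons = {}
for sign, D in (("pos", parts.D_pos), ("neg", parts.D_neg)):
    _, runs = stability_value(D, 2, n_runs=15, seed=3)
    cons[sign] = consensus_factors(runs, sign_part=sign)

val_parts = deviations(val)
W_pred = predict_composition(cons["pos"][0], val_parts.D_pos)
res = evaluate_transfer(W_pred, val_parts.D_pos, k_opt=2, seed=0, n_runs=10)
print("transfer of positive factors to the unseen cohort:")
for j, (r, p) in enumerate(zip(res.spearman_r, res.spearman_p)):
    print(f"  factor {j + 1}: Spearman rho = {r:.3f} (p = {p:.2g})")

gm = grouplevel_tmap(disc.gmv, disc.table)
fit = regress_tmap_on_factors(gm, cons["pos"][0], cons["neg"][0])
print(f"group t map on factors: R^2 = {fit.r_squared:.3f}, "
      f"coefficients = {np.round(fit.coefficients, 2).tolist()}")
W_all = np.hstack([cons["pos"][1].W, cons["neg"][1].W])
coords, avg = embed_compositions(W_all, fit.coefficients, seed=0)
print(f"t-SNE embedding: {coords.shape[0] - 1} patients + 1 'average patient' "
      f"at ({coords[avg, 0]:.1f}, {coords[avg, 1]:.1f})")
# Positive coefficients for volume-adding factors and negative for
# volume-removing ones show the group map is a signed blend of the factors.
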