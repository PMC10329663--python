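"""Group-level t map, its regression on factors, and the t-SNE embedding."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import normfactor as nf


def _table(n_ctrl, n_pat, rng, age=None):
    n = n_ctrl + n_pat
    return pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "group": ["control"] * n_ctrl + ["patient"] * n_pat,
            "age": rng.uniform(15, 35, n) if age is None else age,
            "sex": rng.integers(0, 2, n).astype(float),
            "education_years": rng.normal(13, 3, n),
            "tiv": rng.normal(1450, 100, n),
        }
    )


class TestGroupTmap:
    def test_matches_textbook_two_sample_t_without_covariates(self):
        rng = np.random.default_rng(0)
        table = _table(20, 25, rng)
        gmv = rng.normal(size=(45, 30))
        gm = nf.grouplevel_tmap(gmv, table, covariates=())
        pat = (table["group"] == "patient").to_numpy()
        t_ref, p_ref = stats.ttest_ind(gmv[pat], gmv[~pat], axis=0)
        assert np.allclose(gm.t, t_ref, atol=1e-10)
        assert np.allclose(gm.p, p_ref, atol=1e-10)
        assert gm.df == 45 - 2

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(1)
        table = _table(40, 40, rng)
        gmv = rng.normal(size=(80, 2000))
        gm = nf.grouplevel_tmap(gmv, table)
        frac = np.mean(gm.p < 0.05)
        assert abs(frac - 0.05) < 2 * np.sqrt(0.05 * 0.95 / 2000) + 0.01

    def test_planted_single_voxel_effect_detected_with_matching_sign(self):
        rng = np.random.default_rng(2)
        table = _table(40, 40, rng)
        gmv = rng.normal(size=(80, 50))
        pat = (table["group"] == "patient").to_numpy()
        gmv[pat, 7] += 2.0
        gm = nf.grouplevel_tmap(gmv, table)
        assert gm.t[7] > 5 and gm.fdr_mask[7]
        assert np.mean(np.abs(np.delete(gm.t, 7)) > 3) < 0.05

    def test_covariate_adjustment_removes_age_confound(self):
        rng = np.random.default_rng(3)
        n = 120
        # patients systematically older; GMV declines with age; no group effect
        age = np.concatenate([rng.uniform(15, 25, 60), rng.uniform(25, 35, 60)])
        table = _table(60, 60, rng, age=age)
        gmv = (-0.1 * age[:, None]) + rng.normal(0, 0.5, (n, 40))
        gm_adj = nf.grouplevel_tmap(gmv, table, covariates=("age",))
        gm_raw = nf.grouplevel_tmap(gmv, table, covariates=())
        assert np.mean(np.abs(gm_adj.t)) < np.mean(np.abs(gm_raw.t))
        assert np.mean(gm_adj.p < 0.05) < 0.1

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(4)
        table = _table(10, 10, rng)
        table["tiv"] = 2.0 * table["age"]  # exact collinearity
        with pytest.raises(ValueError, match="collinear"):
            nf.grouplevel_tmap(rng.normal(size=(20, 5)), table)


class TestBridgeRegression:
    def test_exact_signed_combination_recovered(self):
        rng = np.random.default_rng(5)
        Hp = np.abs(rng.normal(size=(2, 500)))
        Hn = np.abs(rng.normal(size=(2, 500)))
        t = 3.0 * Hp[0] + 1.5 * Hp[1] - 2.0 * Hn[0] - 0.5 * Hn[1]
        fit = nf.regress_tmap_on_factors(t, Hp, Hn)
        assert np.allclose(fit.coefficients, [3.0, 1.5, -2.0, -0.5], atol=1e-8)
        assert fit.r_squared == pytest.approx(1.0)

    def test_noise_tmap_explains_almost_nothing(self):
        rng = np.random.default_rng(6)
        Hp = np.abs(rng.normal(size=(2, 3000)))
        Hn = np.abs(rng.normal(size=(2, 3000)))
        fit = nf.regress_tmap_on_factors(rng.normal(size=3000), Hp, Hn)
        assert fit.r_squared < 0.05

    def test_r2_invariant_to_factor_rescaling(self):
        rng = np.random.default_rng(7)
        Hp = np.abs(rng.normal(size=(2, 300)))
        Hn = np.abs(rng.normal(size=(2, 300)))
        t = rng.normal(size=300)
        f1 = nf.regress_tmap_on_factors(t, Hp, Hn)
        Hp2 = Hp.copy()
        Hp2[0] *= 10.0
        f2 = nf.regress_tmap_on_factors(t, Hp2, Hn)
        assert np.isclose(f1.r_squared, f2.r_squared, atol=1e-12)
        assert np.isclose(f2.coefficients[0], f1.coefficients[0] / 10.0)

    def test_rank_deficiency_rejected(self):
        H = np.ones((2, 100))
        with pytest.raises(np.linalg.LinAlgError):
            nf.regress_tmap_on_factors(np.ones(100), H, H)


class TestEmbedding:
    def test_same_seed_same_coordinates(self):
        rng = np.random.default_rng(8)
        W = rng.gamma(4, 0.5, (40, 4))
        c1, _ = nf.embed_compositions(W, seed=3)
        c2, _ = nf.embed_compositions(W, seed=3)
        assert np.array_equal(c1, c2)

    def test_duplicate_rows_land_together(self):
        rng = np.random.default_rng(9)
        W = rng.gamma(4, 0.5, (60, 4))
        W[17] = W[3]
        coords, _ = nf.embed_compositions(W, seed=0)
        # the duplicated pair must be mutual nearest neighbours, much closer
        # than typical points
        dists = np.linalg.norm(coords - coords[3], axis=1)
        dists[3] = np.inf
        assert np.argmin(dists) == 17
        diam = np.ptp(coords, axis=0).max()
        assert np.linalg.norm(coords[17] - coords[3]) < 0.05 * diam

    def test_separated_clusters_stay_separated(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(10)
        W = np.vstack(
            [rng.normal(0, 0.1, (25, 3)) + [5, 0, 0], rng.normal(0, 0.1, (25, 3)) + [0, 5, 0]]
        )
        coords, _ = nf.embed_compositions(np.abs(W), seed=1)
        labels = np.repeat([0, 1], 25)
        assert silhouette_score(coords, labels) > 0.5

    def test_average_patient_row_appended_and_flagged(self):
        rng = np.random.default_rng(11)
        W = rng.gamma(4, 0.5, (20, 4))
        coords, avg_idx = nf.embed_compositions(W, np.array([1.0, -2.0, 0.5, 0.1]), seed=0)
        assert coords.shape == (21, 2) and avg_idx == 20

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError):
            nf.embed_compositions(np.ones((4, 3)))
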