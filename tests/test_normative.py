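"""Normative GP: calibration, standardized MSE behaviour, signed splitting."""

import warnings

import numpy as np
import pandas as pd
import pytest

import normfactor as nf
from normfactor.normative import _smse, predict


def _cov(rng, n, age_lo=10, age_hi=40):
    return pd.DataFrame(
        {"age": rng.uniform(age_lo, age_hi, n), "sex": rng.integers(0, 2, n).astype(float)}
    )


def test_no_covariate_effect_predicts_training_mean():
    rng = np.random.default_rng(0)
    n, V = 80, 60
    cov = _cov(rng, n)
    Y = 5.0 + rng.normal(0, 1, (n, V))
    fit = nf.fit_normative(Y, cov, seed=0)
    cov_new = _cov(rng, 50)
    mu, _ = predict(fit, cov_new)
    assert np.all(np.abs(mu.mean(axis=0) - Y.mean(axis=0)) < 0.1)


def test_planted_age_decline_beats_intercept_baseline(small_bundle):
    """CV standardized MSE below the intercept-only model at every quantile."""
    Y = small_bundle.control_matrix[:, :150]
    cov = small_bundle.covariates("control")
    cv = nf.crossvalidate(Y, cov, k_folds=5, seed=0)
    # intercept-only baseline under the same folds
    base_pred = np.empty_like(Y)
    for f in range(5):
        hold = cv.fold_assignment == f
        base_pred[hold] = Y[~hold].mean(axis=0)
    base = _smse(Y, base_pred)
    for q in (0.25, 0.5, 0.75):
        assert np.quantile(cv.smse, q) < np.quantile(base, q)


def test_refit_is_deterministic(small_bundle):
    Y = small_bundle.control_matrix[:, :40]
    cov = small_bundle.covariates("control")
    f1 = nf.fit_normative(Y, cov, seed=5)
    f2 = nf.fit_normative(Y, cov, seed=5)
    assert np.array_equal(f1.cand_idx, f2.cand_idx)
    assert np.array_equal(f1.alpha, f2.alpha)


def test_training_controls_score_near_standard_normal(small_parts, small_bundle):
    _, fit = small_parts
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dev = nf.score_deviations(
            fit, small_bundle.control_matrix, small_bundle.covariates("control")
        )
    assert abs(dev.Z.mean()) < 0.05
    assert 0.9 <= dev.Z.std() <= 1.1


def test_subject_matching_prediction_scores_zero(small_parts, small_bundle):
    _, fit = small_parts
    cov = small_bundle.covariates("patient").iloc[:3]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mu, _ = predict(fit, cov)
        dev = nf.score_deviations(fit, mu, cov)
    assert np.allclose(dev.Z, 0.0)


def test_z_is_exactly_delta_over_sigma(small_parts, small_bundle):
    """Adding delta to one subject's GMV at one voxel moves Z by delta/sigma."""
    _, fit = small_parts
    cov = small_bundle.covariates("patient").iloc[:2]
    Y = small_bundle.patient_matrix[:2].copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        z0 = nf.score_deviations(fit, Y, cov).Z
        _, sd = predict(fit, cov)
        Y[0, 7] += 0.5
        z1 = nf.score_deviations(fit, Y, cov).Z
    delta_z = z1 - z0
    assert np.isclose(delta_z[0, 7], 0.5 / sd[0, 7], rtol=1e-10)
    delta_z[0, 7] = 0.0
    assert np.allclose(delta_z, 0.0)


def test_pure_noise_smse_near_one():
    rng = np.random.default_rng(4)
    Y = rng.normal(0, 1, (100, 150))
    cv = nf.crossvalidate(Y, _cov(rng, 100), k_folds=10, seed=0)
    assert abs(cv.smse.mean() - 1.0) < 0.15


def test_smse_zero_for_perfect_predictions():
    y = np.random.default_rng(0).normal(size=(20, 5))
    assert np.allclose(_smse(y, y), 0.0)


def test_transfer_equals_resubstitution_on_same_cohort(small_bundle, small_parts):
    _, fit = small_parts
    Y = small_bundle.control_matrix
    cov = small_bundle.covariates("control")
    rep = nf.transfer_fit_check(fit, Y, cov)
    mu, _ = predict(fit, cov)
    assert np.allclose(rep.smse, _smse(Y, mu))


def test_out_of_range_ages_warn(small_parts):
    _, fit = small_parts
    cov = pd.DataFrame({"age": [80.0, 85.0], "sex": [0.0, 1.0]})
    Y = np.zeros((2, fit.n_voxels))
    with pytest.warns(UserWarning, match="outside the normative training range"):
        nf.transfer_fit_check(fit, Y, cov)


def test_fold_size_and_count_validation():
    rng = np.random.default_rng(1)
    Y = rng.normal(size=(15, 5))
    with pytest.raises(ValueError):
        nf.crossvalidate(Y, _cov(rng, 15), k_folds=20)
    with pytest.raises(ValueError):
        nf.crossvalidate(Y, _cov(rng, 15), k_folds=11)  # smallest fold has 1 subject


def test_constant_voxel_flagged():
    rng = np.random.default_rng(2)
    Y = rng.normal(size=(30, 4))
    Y[:, 2] = 3.14
    fit = nf.fit_normative(Y, _cov(rng, 30), seed=0)
    assert fit.constant_voxels.tolist() == [False, False, True, False]


def test_age_profile_recovery(small_bundle, small_parts):
    """GP predictive age curve matches the planted decline at signal voxels."""
    _, fit = small_parts
    c1, c2 = small_bundle.truth.age_effect
    signal = np.argsort(c1 + c2)[-30:]  # strongest planted declines
    lo, hi = small_bundle.spec.age_range
    ages = np.linspace(lo, hi, 15)
    cov = pd.DataFrame({"age": ages, "sex": np.zeros(15)})
    mu, _ = predict(fit, cov)
    u = (ages - lo) / (hi - lo)
    good = 0
    for v in signal:
        planted = -(c1[v] * u + c2[v] * u**2)
        r = np.corrcoef(mu[:, v], planted)[0, 1]
        good += r >= 0.9
    assert good >= 0.8 * signal.size


class TestSplitSigned:
    def test_definition(self):
        Z = np.array([[1.0, -2.0], [0.0, 3.0]])
        parts = nf.split_signed(Z)
        assert np.array_equal(parts.D_pos, [[1, 0], [0, 3]])
        assert np.array_equal(parts.D_neg, [[0, 2], [0, 0]])

    def test_all_positive_gives_zero_negative_part(self):
        Z = np.abs(np.random.default_rng(0).normal(size=(4, 6)))
        assert np.all(nf.split_signed(Z).D_neg == 0)

    def test_reconstruction_is_exact(self):
        Z = np.random.default_rng(1).normal(size=(10, 20))
        parts = nf.split_signed(Z)
        assert np.array_equal(parts.D_pos - parts.D_neg, Z)
        assert np.all(parts.D_pos >= 0) and np.all(parts.D_neg >= 0)
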