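"""Per-voxel Gaussian-process normative models of gray matter volume.

A normative model plays the role of a growth chart: GMV at each voxel is
regressed on age and sex in healthy controls, and every target subject is
scored by the signed Z deviation of their observed GMV from the predictive
distribution.  Positive Z means more volume than the norm predicts.

Model per voxel (after centring the training GMV):

    y ~ N(0, tau * M),   M = w_rbf * K_rbf(age; l) + w_lin * K_lin(sex, ...) + r * I

i.e. a sum of a radial-basis kernel on standardized age, a linear kernel on
the binary sex code (plus optional extra linear covariates), and white noise.
All voxels share the covariates, so for any candidate hyperparameter setting
a single Cholesky factor serves every voxel; the overall scale ``tau`` has a
closed-form maximum-likelihood profile.  Hyperparameters are therefore chosen
per voxel by maximizing the log marginal likelihood over a bounded log-space
candidate set (a deterministic grid plus seeded random restarts), which keeps
the per-voxel fits independent yet fast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular

_VAR_FLOOR = 1e-8  # control-variance floor below which a voxel is "constant"
_NOISE_FLOOR = np.finfo(float).eps


@dataclass
class NormativeFit:
    """Fitted per-voxel normative models sharing one covariate design."""

    age_mean: float
    age_sd: float
    linear_cols: list[str]
    lin_means: np.ndarray
    lin_sds: np.ndarray
    train_X_age: np.ndarray  # standardized training ages (n,)
    train_X_lin: np.ndarray  # standardized linear covariates (n, p)
    train_y_mean: np.ndarray  # per-voxel training mean (V,)
    candidates: np.ndarray  # (C, 4): length_scale, w_rbf, w_lin, noise_frac
    cand_idx: np.ndarray  # per-voxel selected candidate (V,)
    tau: np.ndarray  # per-voxel profiled scale (V,)
    alpha: np.ndarray  # per-voxel M^{-1} (y - mean), shape (n, V)
    log_marginal: np.ndarray  # per-voxel maximized log marginal likelihood
    constant_voxels: np.ndarray  # boolean flag (V,)
    n_train: int = 0
    seed: int = 0

    @property
    def n_voxels(self) -> int:
        return self.train_y_mean.size

    def standardize(self, covariates: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
        age = np.asarray(covariates["age"], float)
        a = (age - self.age_mean) / self.age_sd
        lin = np.column_stack(
            [
                (np.asarray(covariates[c], float) - m) / s
                for c, m, s in zip(self.linear_cols, self.lin_means, self.lin_sds)
            ]
        )
        return a, lin


@dataclass
class DeviationMatrix:
    """Signed voxelwise Z deviations for a set of target subjects."""

    Z: np.ndarray  # (subjects, V)
    provenance: str = ""
    extrapolated: bool = False

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("non-finite Z scores")


@dataclass
class SignedParts:
    """Positive and rectified-negative halves of a deviation matrix."""

    D_pos: np.ndarray
    D_neg: np.ndarray


@dataclass
class CVReport:
    """Standardized-MSE evaluation of a normative fit."""

    smse: np.ndarray  # pooled per-voxel standardized MSE (V,)
    per_fold: np.ndarray | None  # (k_folds, V) or None for direct transfer
    fold_assignment: np.ndarray | None
    flagged_voxels: np.ndarray | None = None

    def summary(self) -> dict:
        qs = np.quantile(self.smse, [0.05, 0.25, 0.5, 0.75, 0.95])
        return {
            "smse_q05": float(qs[0]),
            "smse_q25": float(qs[1]),
            "smse_median": float(qs[2]),
            "smse_q75": float(qs[3]),
            "smse_q95": float(qs[4]),
            "smse_mean": float(self.smse.mean()),
        }


def _candidate_set(n_restarts: int, seed: int) -> np.ndarray:
    """(length_scale, w_rbf, w_lin, noise_frac) rows; signal weights sum to 1-r."""
    lengths = [0.25, 0.5, 1.0, 2.0]
    noise = [0.02, 0.05, 0.1, 0.2, 0.35, 0.5, 0.7, 0.85, 0.95, 0.99]
    alphas = [0.0, 1.0 / 3.0, 2.0 / 3.0, 1.0]
    rows = []
    for r in noise:
        for a in alphas:
            sig = 1.0 - r
            if a == 0.0:
                rows.append((1.0, 0.0, sig, r))  # length scale irrelevant
                continue
            for l in lengths:
                rows.append((l, sig * a, sig * (1.0 - a), r))
    rng = np.random.default_rng(seed)
    for _ in range(4 * max(n_restarts, 0)):
        l = float(np.exp(rng.uniform(np.log(0.2), np.log(3.0))))
        r = float(rng.uniform(0.01, 0.99))
        a = float(rng.uniform(0.0, 1.0))
        rows.append((l, (1 - r) * a, (1 - r) * (1 - a), r))
    return np.asarray(rows)


def _kernel(
    cand: np.ndarray,
    a1: np.ndarray,
    lin1: np.ndarray,
    a2: np.ndarray | None = None,
    lin2: np.ndarray | None = None,
) -> np.ndarray:
    l, w_rbf, w_lin, _r = cand
    if a2 is None:
        a2, lin2 = a1, lin1
    K = w_rbf * np.exp(-((a1[:, None] - a2[None, :]) ** 2) / (2.0 * l * l))
    K += w_lin * (lin1 @ lin2.T)
    return K


def fit_normative(
    control_matrix: np.ndarray,
    control_covariates: pd.DataFrame,
    n_restarts: int = 3,
    seed: int = 0,
    extra_linear: tuple[str, ...] = (),
) -> NormativeFit:
    """Fit one GP per voxel on healthy controls.

    ``control_covariates`` must contain ``age`` and ``sex`` columns (plus any
    ``extra_linear`` columns, e.g. ``tiv``, which enter the linear kernel).
    Deterministic given ``seed``.
    """
    Y = np.asarray(control_matrix, float)
    if Y.ndim != 2:
        raise ValueError("control_matrix must be subjects x voxels")
    n, V = Y.shape
    if n < 10:
        raise ValueError("need at least 10 controls to fit a normative model")
    for col in ("age", "sex", *extra_linear):
        if col not in control_covariates.columns:
            raise ValueError(f"missing covariate column {col!r}")
        if control_covariates[col].isna().any():
            raise ValueError(f"covariate column {col!r} has missing values")

    age = np.asarray(control_covariates["age"], float)
    age_mean, age_sd = float(age.mean()), float(age.std() or 1.0)
    lin_cols = ["sex", *extra_linear]
    lin_raw = np.column_stack([np.asarray(control_covariates[c], float) for c in lin_cols])
    lin_means = lin_raw.mean(axis=0)
    lin_sds = np.where(lin_raw.std(axis=0) > 0, lin_raw.std(axis=0), 1.0)
    a = (age - age_mean) / age_sd
    lin = (lin_raw - lin_means) / lin_sds

    y_mean = Y.mean(axis=0)
    Yc = Y - y_mean
    var = Yc.var(axis=0)
    constant = var < _VAR_FLOOR

    cands = _candidate_set(n_restarts, seed)
    best_nll = np.full(V, np.inf)
    best_idx = np.zeros(V, dtype=int)
    best_q = np.ones(V)
    for ci, cand in enumerate(cands):
        M = _kernel(cand, a, lin) + cand[3] * np.eye(n)
        L = cholesky(M, lower=True)
        Z = solve_triangular(L, Yc, lower=True)
        q = np.einsum("ij,ij->j", Z, Z)  # y^T M^{-1} y per voxel
        q = np.maximum(q, n * _VAR_FLOOR)
        logdet = 2.0 * np.sum(np.log(np.diag(L)))
        nll = 0.5 * n * np.log(q / n) + 0.5 * logdet
        better = nll < best_nll
        best_nll[better] = nll[better]
        best_idx[better] = ci
        best_q[better] = q[better]

    tau = best_q / n
    # constant voxels: intercept-only with a machine-epsilon noise floor
    tau[constant] = _NOISE_FLOOR
    best_idx[constant] = _noise_only_index(cands)

    alpha = np.empty((n, V))
    for ci in np.unique(best_idx):
        cols = best_idx == ci
        M = _kernel(cands[ci], a, lin) + cands[ci][3] * np.eye(n)
        cf = cho_factor(M, lower=True)
        alpha[:, cols] = cho_solve(cf, Yc[:, cols])

    return NormativeFit(
        age_mean=age_mean,
        age_sd=age_sd,
        linear_cols=lin_cols,
        lin_means=lin_means,
        lin_sds=lin_sds,
        train_X_age=a,
        train_X_lin=lin,
        train_y_mean=y_mean,
        candidates=cands,
        cand_idx=best_idx,
        tau=tau,
        alpha=alpha,
        log_marginal=-best_nll - 0.5 * n * (1.0 + np.log(2.0 * np.pi)),
        constant_voxels=constant,
        n_train=n,
        seed=seed,
    )


def _noise_only_index(cands: np.ndarray) -> int:
    pure = np.where((cands[:, 1] == 0) & (cands[:, 2] == 0))[0]
    if pure.size:
        return int(pure[0])
    # highest noise fraction as fallback
    return int(np.argmax(cands[:, 3]))


def predict(
    fit: NormativeFit, covariates: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Predictive mean and standard deviation for each (subject, voxel).

    The predictive standard deviation combines latent-function uncertainty
    and the fitted noise variance — the denominator of the Z score.
    """
    a_new, lin_new = fit.standardize(covariates)
    m = a_new.size
    V = fit.n_voxels
    mu = np.empty((m, V))
    sd = np.empty((m, V))
    for ci in np.unique(fit.cand_idx):
        cols = fit.cand_idx == ci
        cand = fit.candidates[ci]
        M = _kernel(cand, fit.train_X_age, fit.train_X_lin) + cand[3] * np.eye(fit.n_train)
        L = cholesky(M, lower=True)
        Ks = _kernel(cand, a_new, lin_new, fit.train_X_age, fit.train_X_lin)  # (m, n)
        mu[:, cols] = Ks @ fit.alpha[:, cols] + fit.train_y_mean[cols]
        kss = cand[1] + cand[2] * np.einsum("ij,ij->i", lin_new, lin_new)
        v = solve_triangular(L, Ks.T, lower=True)  # (n, m)
        latent = np.maximum(kss - np.einsum("ij,ij->j", v, v), 0.0)
        unit_var = latent + cand[3]  # + noise
        sd[:, cols] = np.sqrt(np.outer(unit_var, fit.tau[cols]))
    sd = np.maximum(sd, np.sqrt(_NOISE_FLOOR))
    return mu, sd


def _check_range(fit: NormativeFit, covariates: pd.DataFrame) -> bool:
    a_new, _ = fit.standardize(covariates)
    lo, hi = fit.train_X_age.min(), fit.train_X_age.max()
    out = bool(np.any(a_new < lo) or np.any(a_new > hi))
    if out:
        warnings.warn(
            "target ages fall outside the normative training range; "
            "Z scores there are extrapolations",
            stacklevel=3,
        )
    return out


def score_deviations(
    fit: NormativeFit,
    target_matrix: np.ndarray,
    target_covariates: pd.DataFrame,
    provenance: str = "",
) -> DeviationMatrix:
    """Z[s, v] = (y[s, v] - mu_pred) / sd_pred; positive = above the norm."""
    Y = np.asarray(target_matrix, float)
    extrap = _check_range(fit, target_covariates)
    mu, sd = predict(fit, target_covariates)
    if Y.shape != mu.shape:
        raise ValueError(f"target matrix shape {Y.shape} != expected {mu.shape}")
    Z = (Y - mu) / sd
    if not np.all(np.isfinite(Z)):
        bad = np.unique(np.where(~np.isfinite(Z))[1])
        raise FloatingPointError(f"non-finite prediction at voxel(s) {bad[:10].tolist()}")
    return DeviationMatrix(Z=Z, provenance=provenance, extrapolated=extrap)


def split_signed(dev: DeviationMatrix | np.ndarray) -> SignedParts:
    """Split Z into its positive part and the magnitude of its negative part."""
    Z = dev.Z if isinstance(dev, DeviationMatrix) else np.asarray(dev, float)
    return SignedParts(D_pos=np.maximum(Z, 0.0), D_neg=np.maximum(-Z, 0.0))


def _smse(y_true: np.ndarray, y_pred: np.ndarray) -> np.ndarray:
    err = np.mean((y_true - y_pred) ** 2, axis=0)
    denom = np.maximum(y_true.var(axis=0), _VAR_FLOOR)
    return err / denom


def crossvalidate(
    control_matrix: np.ndarray,
    covariates: pd.DataFrame,
    k_folds: int = 10,
    seed: int = 0,
    n_restarts: int = 3,
) -> CVReport:
    """K-fold CV of the normative model on controls.

    The per-voxel standardized MSE pools squared prediction errors over all
    held-out subjects and divides by the variance of the held-out truths; a
    value of 1 matches predicting the held-out mean, smaller is better.
    """
    Y = np.asarray(control_matrix, float)
    n, V = Y.shape
    if k_folds > n:
        raise ValueError("k_folds exceeds the number of controls")
    rng = np.random.default_rng(seed)
    assignment = np.repeat(np.arange(k_folds), np.ceil(n / k_folds))[:n]
    rng.shuffle(assignment)
    counts = np.bincount(assignment, minlength=k_folds)
    if np.any(counts < 2):
        raise ValueError("every fold needs at least 2 subjects")

    preds = np.empty_like(Y)
    per_fold = np.empty((k_folds, V))
    cov = covariates.reset_index(drop=True)
    for f in range(k_folds):
        hold = assignment == f
        fit = fit_normative(Y[~hold], cov.loc[~hold], n_restarts=n_restarts, seed=seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mu, _sd = predict(fit, cov.loc[hold])
        preds[hold] = mu
        per_fold[f] = _smse(Y[hold], mu)
    pooled = _smse(Y, preds)
    return CVReport(smse=pooled, per_fold=per_fold, fold_assignment=assignment)


def transfer_fit_check(
    fit: NormativeFit,
    cohort_b_matrix: np.ndarray,
    cohort_b_covariates: pd.DataFrame,
) -> CVReport:
    """Score an independent control cohort with an already-fitted model."""
    Y = np.asarray(cohort_b_matrix, float)
    _check_range(fit, cohort_b_covariates)
    mu, _sd = predict(fit, cohort_b_covariates)
    return CVReport(smse=_smse(Y, mu), per_fold=None, fold_assignment=None)
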