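"""Bridge between subject-level factors and the group-level case-control map.

The conventional mass-univariate result — a voxelwise two-sample t map with
nuisance covariates — is recomputed here with ordinary least squares, then
regressed (intercept-free) on the disease-factor maps of both signs.  The
regression coefficients are interpreted as the factor composition of an
"average patient", which can be embedded alongside every real patient's
composition with t-SNE to show where the group-level result sits in the
population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.manifold import TSNE

from .factors import FactorSet
from .significance import fdr_bh


@dataclass
class GroupMap:
    t: np.ndarray  # per-voxel t statistic of the group term
    p: np.ndarray
    fdr_mask: np.ndarray  # q < 0.05, display only
    df: int
    covariates: tuple[str, ...]


@dataclass
class BridgeFit:
    coefficients: np.ndarray  # signed, ordered pos factors then neg factors
    r_squared: float
    f_statistic: float
    p_value: float
    intercept: float | None = None  # None under the default no-intercept fit


def grouplevel_tmap(
    gmv: np.ndarray,
    table: pd.DataFrame,
    covariates: tuple[str, ...] = ("age", "sex", "education_years", "tiv"),
    q: float = 0.05,
) -> GroupMap:
    """Voxelwise patient-vs-control t map from an OLS fit with covariates.

    Design per voxel: [intercept, patient indicator, covariates]; t is the
    group coefficient over its standard error.  Subjects with missing
    covariates are dropped with a warning.  The FDR mask is for display; the
    unthresholded map is what downstream regression consumes.
    """
    gmv = np.asarray(gmv, float)
    cols = ["group", *covariates]
    keep = table[cols].notna().all(axis=1).to_numpy()
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} subjects with missing covariates")
    tab = table.loc[keep]
    Y = gmv[keep]
    group = (tab["group"] == "patient").to_numpy(float)
    if group.sum() < 3 or (1 - group).sum() < 3:
        raise ValueError("each group needs at least 3 subjects")
    X = np.column_stack(
        [np.ones(len(tab)), group] + [np.asarray(tab[c], float) for c in covariates]
    )
    names = ["intercept", "group", *covariates]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        from scipy.linalg import qr as _sqr  # pivoted QR names the offenders

        _, _, piv = _sqr(X, pivoting=True)
        bad = [names[i] for i in piv[rank:]]
        raise ValueError(f"collinear design columns: {bad}")

    n, p = X.shape
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ (X.T @ Y)  # (p, V)
    resid = Y - X @ beta
    dof = n - p
    sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
    se = np.sqrt(np.maximum(XtX_inv[1, 1] * sigma2, 1e-300))
    t = beta[1] / se
    pvals = 2.0 * stats.t.sf(np.abs(t), dof)
    return GroupMap(
        t=t, p=pvals, fdr_mask=fdr_bh(pvals) < q, df=dof, covariates=tuple(covariates)
    )


def regress_tmap_on_factors(
    group_map: GroupMap | np.ndarray,
    factors_pos: FactorSet | np.ndarray,
    factors_neg: FactorSet | np.ndarray,
    fit_intercept: bool = False,
) -> BridgeFit:
    """Intercept-free least squares of the unthresholded t map on all factors.

    Regressors are the positive-factor rows followed by the negative-factor
    rows; with planted structure the fitted coefficients come out signed
    accordingly.  R^2 is uncentered under the default no-intercept fit;
    F = (R^2/k) / ((1-R^2)/(m-k)) with m the voxel count.
    """
    t = group_map.t if isinstance(group_map, GroupMap) else np.asarray(group_map, float)
    Hp = factors_pos.H if isinstance(factors_pos, FactorSet) else np.asarray(factors_pos, float)
    Hn = factors_neg.H if isinstance(factors_neg, FactorSet) else np.asarray(factors_neg, float)
    if Hp.shape[1] != t.size or Hn.shape[1] != t.size:
        raise ValueError("factor maps and t map must share the voxel space")
    X = np.vstack([Hp, Hn]).T  # (m, k)
    if fit_intercept:
        X = np.column_stack([X, np.ones(t.size)])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("factor design is rank deficient")
    coef, *_ = np.linalg.lstsq(X, t, rcond=None)
    fitted = X @ coef
    resid = t - fitted
    k = Hp.shape[0] + Hn.shape[0]
    m = t.size
    if fit_intercept:
        ss_tot = np.sum((t - t.mean()) ** 2)
        intercept = float(coef[-1])
        coef = coef[:-1]
        n_reg = k + 1
    else:
        ss_tot = np.sum(t**2)
        intercept = None
        n_reg = k
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    f = (r2 / k) / max((1.0 - r2) / (m - n_reg), 1e-300)
    p = float(stats.f.sf(f, k, m - n_reg))
    return BridgeFit(
        coefficients=coef, r_squared=float(r2), f_statistic=float(f), p_value=p,
        intercept=intercept,
    )


def embed_compositions(
    W: np.ndarray,
    average_patient_coeffs: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, int | None]:
    """t-SNE embedding of patient compositions (plus the "average patient").

    Columns are standardized with the patients' means and SDs; the
    average-patient row (the bridge coefficients, whose scale is arbitrary)
    is standardized with the same constants and appended last.  Returns the
    (n [+1], 2) coordinates and the row index of the average patient.
    """
    W = np.asarray(W, float)
    if W.ndim != 2 or W.shape[1] < 2:
        raise ValueError("W must be 2-D with k >= 2")
    if W.shape[0] < 5:
        raise ValueError("need at least 5 patients to embed")
    mu = W.mean(axis=0)
    sd = np.where(W.std(axis=0) > 0, W.std(axis=0), 1.0)
    Xs = (W - mu) / sd
    avg_index = None
    if average_patient_coeffs is not None:
        avg = (np.asarray(average_patient_coeffs, float) - mu) / sd
        Xs = np.vstack([Xs, avg])
        avg_index = Xs.shape[0] - 1
    perplexity = min(30, Xs.shape[0] // 4)
    coords = TSNE(
        n_components=2,
        perplexity=max(2, perplexity),
        random_state=int(seed) % (2**32),
        init="pca",
    ).fit_transform(Xs)
    return coords, avg_index
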