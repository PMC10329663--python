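"""Nonnegative factorization of deviation matrices with stability-based rank
selection.

The model is D = W @ H + eps with W, H >= 0: H rows are spatial "disease
factors" over masked voxels, W rows are per-patient factor compositions.
Because NMF is non-convex and its restarts disagree when the rank is wrong,
the factor count K is chosen by a run-stability criterion: factorize many
times from random starts, align factors across every run pair with the
Hungarian algorithm on Pearson correlations, and pick the K whose mean
pairwise agreement (the stability value) is largest.  Consensus factors are
the permutation-aligned average over runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import NMF as _SkNMF
from sklearn.exceptions import ConvergenceWarning

#: multiplicative-update defaults: squared Frobenius objective, random
#: nonnegative init, relative-tolerance stop
NMF_MAX_ITER = 500
NMF_TOL = 1e-5


@dataclass
class FactorSet:
    H: np.ndarray  # (k, n_voxels), nonnegative, rows unit L2 norm
    sign_part: str = "positive"
    normalization: str = "unit_l2"

    @property
    def k(self) -> int:
        return self.H.shape[0]

    def __post_init__(self) -> None:
        if np.any(self.H < 0):
            raise ValueError("H must be nonnegative")
        if np.any(np.linalg.norm(self.H, axis=1) == 0):
            raise ValueError("H contains an all-zero factor row")


@dataclass
class CompositionMatrix:
    W: np.ndarray  # (subjects, k), nonnegative
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        if np.any(self.W < 0):
            raise ValueError("W must be nonnegative")


@dataclass
class StabilityEntry:
    k: int
    n_runs: int
    agreement: np.ndarray  # (R, R), symmetric, unit diagonal
    stability: float
    selected: bool = False


@dataclass
class StabilityProfile:
    entries: dict[int, StabilityEntry] = field(default_factory=dict)

    def stability_by_k(self) -> dict[int, float]:
        return {k: e.stability for k, e in sorted(self.entries.items())}


@dataclass
class VarianceExplained:
    r_squared: np.ndarray  # per patient
    coefficients: np.ndarray  # (patients, k)
    centered: bool = False
    flagged: np.ndarray | None = None  # all-zero patient rows


def _rescale_unit_h(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Resolve the NMF scale indeterminacy: unit-L2 H rows, scale into W."""
    norms = np.linalg.norm(H, axis=1)
    norms = np.where(norms > 0, norms, 1.0)
    return W * norms[None, :], H / norms[:, None]


def nmf_single_run(
    D: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = NMF_MAX_ITER,
    tol: float = NMF_TOL,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One NMF run: multiplicative updates on the squared Frobenius objective
    from a seeded random nonnegative start.  Returns (W, H, residual norm)
    with H rows rescaled to unit Euclidean norm (scale absorbed into W).
    """
    D = np.asarray(D)
    if D.ndim != 2:
        raise ValueError("D must be 2-D")
    if np.any(D < 0):
        raise ValueError("D must be nonnegative")
    if not np.any(D > 0):
        raise ValueError("D is all zero; nothing to factorize")
    if k >= min(D.shape):
        raise ValueError(f"k={k} must be smaller than min(D.shape)={min(D.shape)}")
    model = _SkNMF(
        n_components=k,
        init="random",
        solver="mu",
        beta_loss="frobenius",
        tol=tol,
        max_iter=max_iter,
        random_state=int(seed) % (2**32),
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(D)
    H = model.components_
    W, H = _rescale_unit_h(W, H)
    err = float(np.linalg.norm(D - W @ H))
    return W, H, err


def multiplicative_update_trace(
    D: np.ndarray,
    k: int,
    seed: int,
    n_iter: int = 100,
    init: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Plain multiplicative updates recording the objective at every step.

    Used to verify objective monotonicity and to cross-check the production
    solver on small problems.  ``init`` overrides the seeded random start.
    """
    D = np.asarray(D, float)
    rng = np.random.default_rng(seed)
    scale = np.sqrt(D.mean() / k)
    if init is not None:
        W, H = init[0].copy(), init[1].copy()
    else:
        W = scale * rng.random((D.shape[0], k)) + 1e-6
        H = scale * rng.random((k, D.shape[1])) + 1e-6
    errs = np.empty(n_iter)
    eps = 1e-12
    for it in range(n_iter):
        H *= (W.T @ D) / (W.T @ W @ H + eps)
        W *= (D @ H.T) / (W @ (H @ H.T) + eps)
        errs[it] = np.linalg.norm(D - W @ H)
    return W, H, errs


def _standardized_rows(H: np.ndarray) -> np.ndarray:
    """Rows z-scored and scaled so that Hz_a @ Hz_b.T is the Pearson matrix."""
    H = np.asarray(H, float)
    mu = H.mean(axis=1, keepdims=True)
    sd = H.std(axis=1, keepdims=True)
    out = np.zeros_like(H)
    ok = sd[:, 0] > 0
    out[ok] = (H[ok] - mu[ok]) / (sd[ok] * np.sqrt(H.shape[1]))
    return out


def match_factors(
    H_a: np.ndarray, H_b: np.ndarray
) -> tuple[np.ndarray, float]:
    """Optimally pair the rows of two factor sets.

    Solves the linear assignment problem with cost 1 - Pearson r, i.e. the
    permutation maximizing the total correlation of paired rows.  Returns
    ``perm`` with ``H_b[perm[i]]`` matched to ``H_a[i]``, and the mean of the
    k matched correlations.  Zero-variance rows correlate 0 by convention.
    """
    H_a, H_b = np.asarray(H_a, float), np.asarray(H_b, float)
    if H_a.shape != H_b.shape:
        raise ValueError("factor sets must share k and voxel count")
    za, zb = _standardized_rows(H_a), _standardized_rows(H_b)
    if (za.sum(axis=1) == 0).all() is False and (
        np.any(np.all(za == 0, axis=1)) or np.any(np.all(zb == 0, axis=1))
    ):
        warnings.warn("zero-variance factor row; its correlations set to 0", stacklevel=2)
    corr = za @ zb.T
    rows, cols = linear_sum_assignment(1.0 - corr)
    perm = np.empty(H_a.shape[0], dtype=int)
    perm[rows] = cols
    return perm, float(corr[rows, cols].mean())


def pairwise_agreement(runs_H: list[np.ndarray]) -> np.ndarray:
    """R x R matrix of matched mean correlations between runs (diag = 1)."""
    R = len(runs_H)
    zs = [_standardized_rows(H) for H in runs_H]
    A = np.eye(R)
    for i in range(R):
        for j in range(i + 1, R):
            corr = zs[i] @ zs[j].T
            r, c = linear_sum_assignment(1.0 - corr)
            A[i, j] = A[j, i] = corr[r, c].mean()
    return A


def stability_value(
    D: np.ndarray,
    k: int,
    n_runs: int = 100,
    seed: int = 0,
    include_diagonal: bool = True,
    run_seeds: list[int] | None = None,
    max_iter: int = NMF_MAX_ITER,
    tol: float = NMF_TOL,
) -> tuple[StabilityEntry, list[tuple[np.ndarray, np.ndarray]]]:
    """Mean pairwise run agreement at a fixed K.

    Runs NMF ``n_runs`` times (seeds ``seed+1 .. seed+n_runs`` unless
    ``run_seeds`` overrides), builds the R x R matched-correlation matrix and
    averages it (diagonal included by default, which shifts every K equally).
    Failed runs are dropped with a warning.
    """
    if run_seeds is None:
        if n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        run_seeds = [seed + 1 + i for i in range(n_runs)]
    runs: list[tuple[np.ndarray, np.ndarray]] = []
    for s in run_seeds:
        try:
            W, H, _ = nmf_single_run(D, k, seed=s, max_iter=max_iter, tol=tol)
            runs.append((W, H))
        except (ValueError, np.linalg.LinAlgError) as exc:  # pragma: no cover
            warnings.warn(f"NMF run with seed {s} failed and was excluded: {exc}")
    if len(runs) < 2:
        raise RuntimeError("fewer than 2 successful NMF runs; cannot assess stability")
    A = pairwise_agreement([H for _W, H in runs])
    if include_diagonal:
        stab = float(A.mean())
    else:
        off = ~np.eye(A.shape[0], dtype=bool)
        stab = float(A[off].mean())
    return StabilityEntry(k=k, n_runs=len(runs), agreement=A, stability=stab), runs


def select_k(
    D: np.ndarray,
    k_min: int = 2,
    k_max: int = 10,
    n_runs: int = 100,
    seed: int = 0,
    include_diagonal: bool = True,
    max_iter: int = NMF_MAX_ITER,
    tol: float = NMF_TOL,
) -> tuple[int, StabilityProfile, list[tuple[np.ndarray, np.ndarray]]]:
    """Pick K in [k_min, k_max] maximizing the stability value.

    Ties break toward smaller K.  Note that restart agreement is typically
    high for every K at or below the data's true factor count and only
    degrades beyond it, so on cleanly separable data the argmax tends to sit
    at the low end of the plateau; the full profile is returned so the
    plateau and its knee can be inspected (see the methods notes).

    Returns the selected K, the profile over all K (for plotting) and the
    retained runs at the selected K (for consensus averaging).
    """
    if k_max < k_min:
        raise ValueError("k_max must be >= k_min")
    if k_max >= min(np.asarray(D).shape):
        raise ValueError("k_max must be smaller than min(D.shape)")
    profile = StabilityProfile()
    runs_by_k: dict[int, list] = {}
    for k in range(k_min, k_max + 1):
        entry, runs = stability_value(
            D, k, n_runs=n_runs, seed=seed, include_diagonal=include_diagonal,
            max_iter=max_iter, tol=tol,
        )
        profile.entries[k] = entry
        runs_by_k[k] = runs
    ks = sorted(profile.entries)
    stabs = [profile.entries[k].stability for k in ks]
    k_opt = ks[int(np.argmax(stabs))]  # first max -> smaller K
    profile.entries[k_opt].selected = True
    return k_opt, profile, runs_by_k[k_opt]


def consensus_factors(
    runs: list[tuple[np.ndarray, np.ndarray]],
    sign_part: str = "positive",
    subject_ids: list[str] | None = None,
) -> tuple[FactorSet, CompositionMatrix]:
    """Align all runs to a reference and average W and H elementwise.

    The reference run is the one with the highest mean agreement to all
    others (ties -> earliest run, i.e. lowest seed).  Every other run's
    factors are permuted to the reference with the Hungarian matcher; both H
    and W are averaged across aligned runs and renormalized to unit-norm H.
    """
    if len(runs) < 2:
        raise ValueError("need at least 2 runs for a consensus")
    Hs = [H for _W, H in runs]
    A = pairwise_agreement(Hs)
    ref = int(np.argmax(A.mean(axis=1)))  # first max -> lowest seed
    H_ref = Hs[ref]
    H_sum = np.zeros_like(H_ref)
    W_sum = np.zeros_like(runs[ref][0])
    for W, H in runs:
        perm, _ = match_factors(H_ref, H)
        H_sum += H[perm]
        W_sum += W[:, perm]
    H_bar = H_sum / len(runs)
    W_bar = W_sum / len(runs)
    W_bar, H_bar = _rescale_unit_h(W_bar, H_bar)
    return (
        FactorSet(H=H_bar, sign_part=sign_part),
        CompositionMatrix(W=W_bar, subject_ids=subject_ids),
    )


def variance_explained(
    D: np.ndarray, H: np.ndarray | FactorSet, centered: bool = False
) -> VarianceExplained:
    """Per-patient R^2 of the deviation row regressed on the factor maps.

    The fit is intercept-free (consistent with the bilinear model) and the
    default R^2 is uncentered: 1 - ||resid||^2 / ||row||^2, which lies in
    [0, 1].  A centered alternative is available behind the flag.
    """
    H = H.H if isinstance(H, FactorSet) else np.asarray(H, float)
    D = np.asarray(D, float)
    coef, *_ = np.linalg.lstsq(H.T, D.T, rcond=None)  # (k, patients)
    resid = D - coef.T @ H
    ss_res = np.einsum("ij,ij->i", resid, resid)
    if centered:
        Dc = D - D.mean(axis=1, keepdims=True)
        ss_tot = np.einsum("ij,ij->i", Dc, Dc)
    else:
        ss_tot = np.einsum("ij,ij->i", D, D)
    flagged = ss_tot <= 0
    r2 = np.zeros(D.shape[0])
    ok = ~flagged
    r2[ok] = 1.0 - ss_res[ok] / ss_tot[ok]
    r2 = np.clip(r2, 0.0, 1.0) if not centered else r2
    return VarianceExplained(
        r_squared=r2, coefficients=coef.T, centered=centered, flagged=flagged
    )
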