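"""Subsample robustness of the identified factors.

Refits the consensus factorization on repeated random 90% subsamples of the
patients (K held fixed), Hungarian-matches each refit to the full-sample
factors, and reports the matched Spearman correlations — voxelwise for the
factor maps (H) and across shared patients for the compositions (W).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import spearmanr

from .factors import CompositionMatrix, FactorSet, consensus_factors, match_factors, stability_value


@dataclass
class RobustnessReport:
    n_repeats: int
    fraction: float
    n_runs_per_repeat: int
    h_spearman: np.ndarray  # (n_repeats, k): matched H-row correlations
    w_spearman: np.ndarray  # (n_repeats, k): matched W-column correlations
    failed: np.ndarray  # boolean per repeat

    def summary(self) -> dict:
        ok = ~self.failed
        return {
            "h_spearman_median": float(np.median(self.h_spearman[ok])),
            "h_spearman_iqr": float(
                np.subtract(*np.percentile(self.h_spearman[ok], [75, 25]))
            ),
            "w_spearman_median": float(np.median(self.w_spearman[ok])),
            "failed_fraction": float(self.failed.mean()),
        }


def _col_spearman(a: np.ndarray, b: np.ndarray) -> float:
    rho = spearmanr(a, b).statistic
    return float(rho) if np.isfinite(rho) else 0.0


def subsample_robustness(
    D: np.ndarray,
    H_full: FactorSet | np.ndarray,
    W_full: CompositionMatrix | np.ndarray,
    k_opt: int,
    fraction: float = 0.9,
    n_repeats: int = 100,
    n_runs: int = 20,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-5,
) -> RobustnessReport:
    """Refit on random patient subsamples and correlate with the full fit.

    Each repeat draws ``ceil(fraction * n)`` patients without replacement,
    fits consensus factors at ``k_opt`` from ``n_runs`` restarts, matches
    them to ``H_full`` and records per-factor Spearman correlations of the
    matched H rows (over voxels) and of the matched W columns (over the
    sampled patients).  Failed repeats are flagged, never silently dropped.
    """
    D = np.asarray(D, float)
    H_full = H_full.H if isinstance(H_full, FactorSet) else np.asarray(H_full, float)
    W_full = W_full.W if isinstance(W_full, CompositionMatrix) else np.asarray(W_full, float)
    n = D.shape[0]
    n_sub = int(np.ceil(fraction * n))
    if n_sub < k_opt + 2:
        raise ValueError("subsample too small for the requested k_opt")

    rng = np.random.default_rng(seed)
    k = H_full.shape[0]
    h_rho = np.full((n_repeats, k), np.nan)
    w_rho = np.full((n_repeats, k), np.nan)
    failed = np.zeros(n_repeats, dtype=bool)
    for rep in range(n_repeats):
        idx = np.sort(rng.choice(n, size=n_sub, replace=False))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            _entry, runs = stability_value(
                D[idx], k_opt, n_runs=n_runs, seed=sub_seed, max_iter=max_iter, tol=tol
            )
            H_sub, W_sub = consensus_factors(runs)
        except (RuntimeError, ValueError) as exc:
            warnings.warn(f"subsample repeat {rep} failed: {exc}")
            failed[rep] = True
            continue
        perm, _ = match_factors(H_full, H_sub.H)
        for j in range(k):
            h_rho[rep, j] = _col_spearman(H_full[j], H_sub.H[perm[j]])
            w_rho[rep, j] = _col_spearman(W_full[idx, j], W_sub.W[:, perm[j]])
    return RobustnessReport(
        n_repeats=n_repeats,
        fraction=fraction,
        n_runs_per_repeat=n_runs,
        h_spearman=h_rho,
        w_spearman=w_rho,
        failed=failed,
    )
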