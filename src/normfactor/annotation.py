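"""Functional annotation of disease factors against probabilistic term maps.

Each factor is reduced to its most representative voxels (the top 5% by
loading), and every functional term (e.g. a curated Neurosynth vocabulary)
is scored by its mean activation over that voxel set.  Significance comes
from a permutation null of equal-size uniformly random in-mask voxel sets
(shared across terms per permutation), with BH-FDR over terms and a
word-cloud weight exported as 1/p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .significance import fdr_bh


@dataclass
class TermMapSet:
    """Voxel x term matrix of nonnegative probabilistic activation values."""

    values: np.ndarray  # (n_voxels, n_terms)
    terms: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.terms):
            raise ValueError("values must be voxels x terms matching the label list")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("term labels must be unique")
        if np.any(self.values < 0):
            raise ValueError("term maps must be nonnegative")


def top_fraction_mask(h_row: np.ndarray, fraction: float = 0.05) -> np.ndarray:
    """Indices of the ceil(fraction * n) largest values of a factor row.

    Ties at the threshold break toward the lower voxel index (stable sort on
    descending value).
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must be in (0, 1)")
    h = np.asarray(h_row, float)
    n_keep = int(np.ceil(fraction * h.size))
    order = np.argsort(-h, kind="stable")
    return np.sort(order[:n_keep])


def term_association(
    voxel_set: np.ndarray,
    term_maps: TermMapSet,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Score and permutation-test every term against one voxel set.

    score(term) = mean term-map value over the voxel set; the null draws
    ``n_perm`` random voxel sets of the same size from the mask (one draw
    serves all terms); p = (1 + #{null >= observed}) / (1 + n_perm); q is
    BH-FDR across terms.  All-zero term columns are flagged.
    """
    voxel_set = np.asarray(voxel_set, int)
    if voxel_set.size == 0:
        raise ValueError("voxel set is empty")
    T = term_maps.values
    n_vox = T.shape[0]
    if voxel_set.max() >= n_vox:
        raise ValueError("voxel set indices exceed the term-map voxel space")

    observed = T[voxel_set].mean(axis=0)
    rng = np.random.default_rng(seed)
    exceed = np.zeros(T.shape[1])
    for _ in range(n_perm):
        idx = rng.choice(n_vox, size=voxel_set.size, replace=False)
        exceed += T[idx].mean(axis=0) >= observed
    p = (1.0 + exceed) / (1.0 + n_perm)
    flagged = ~np.any(T > 0, axis=0)
    out = pd.DataFrame(
        {
            "term": term_maps.terms,
            "score": observed,
            "p": p,
            "q": fdr_bh(p),
            "wordcloud_weight": 1.0 / p,
            "flagged": flagged,
        }
    )
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def annotate_factors(
    H: np.ndarray,
    term_maps: TermMapSet,
    fraction: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[int, pd.DataFrame]:
    """Run the top-fraction + permutation annotation for every factor row."""
    H = np.asarray(H, float)
    return {
        j: term_association(
            top_fraction_mask(H[j], fraction), term_maps, n_perm=n_perm, seed=seed + j
        )
        for j in range(H.shape[0])
    }
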