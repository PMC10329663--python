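"""Clinical associations of factor compositions.

Spearman correlations between per-patient factor loadings and clinical
measures (HAMD factor scores, illness duration, onset age, education), with
BH-FDR over the full factor x measure grid; and two-sample contrasts
(adolescent- vs adult-onset at 18 years, male vs female) with Cohen's d.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .significance import fdr_bh

ONSET_CUTOFF_YEARS = 18.0  # onset <= 18 -> adolescent, > 18 -> adult

DEFAULT_MEASURES = [
    "hamd_anxiety_somatization",
    "hamd_weight",
    "hamd_cognitive_impairment",
    "hamd_psychomotor_slowing",
    "hamd_sleep_disturbance",
    "hamd_total",
    "duration",
    "onset_age",
    "education_years",
]


@dataclass
class AssociationReport:
    table: pd.DataFrame  # columns: factor, measure, rho, p, p_fdr, n, flagged

    def significant(self, q: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_fdr"] < q]


@dataclass
class ContrastReport:
    table: pd.DataFrame  # per factor: means, t, df, p, p_fdr, cohens_d, welch
    grouping: str = ""


def cohens_d(group1: np.ndarray, group2: np.ndarray) -> float:
    """Pooled-SD standardized mean difference, sign = group1 - group2."""
    g1, g2 = np.asarray(group1, float), np.asarray(group2, float)
    n1, n2 = g1.size, g2.size
    pooled = np.sqrt(
        ((n1 - 1) * g1.var(ddof=1) + (n2 - 1) * g2.var(ddof=1)) / (n1 + n2 - 2)
    )
    if pooled == 0:
        return 0.0
    return float((g1.mean() - g2.mean()) / pooled)


def associate_clinical(
    W: np.ndarray,
    table: pd.DataFrame,
    measures: list[str] | None = None,
    factor_names: list[str] | None = None,
    min_pairs: int = 5,
) -> AssociationReport:
    """Spearman rho for every (factor, measure) cell, FDR over the grid.

    Pairwise-complete observations; cells with fewer than ``min_pairs``
    complete pairs or a constant measure are flagged and excluded from the
    FDR family.
    """
    W = np.asarray(W, float)
    measures = measures or [m for m in DEFAULT_MEASURES if m in table.columns]
    names = factor_names or [f"factor_{j + 1}" for j in range(W.shape[1])]
    if len(table) != W.shape[0]:
        raise ValueError("table and W must describe the same patients")

    rows = []
    for j, fname in enumerate(names):
        for m in measures:
            x = W[:, j]
            y = np.asarray(table[m], float)
            ok = np.isfinite(x) & np.isfinite(y)
            flagged = ok.sum() < min_pairs or np.nanstd(y[ok]) == 0
            if flagged:
                rho, p = np.nan, np.nan
            else:
                res = stats.spearmanr(x[ok], y[ok])
                rho, p = float(res.statistic), float(res.pvalue)
                if not np.isfinite(rho):
                    flagged, rho, p = True, np.nan, np.nan
            rows.append(
                {"factor": fname, "measure": m, "rho": rho, "p": p, "n": int(ok.sum()),
                 "flagged": flagged}
            )
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    computed = ~out["flagged"]
    if computed.any():
        out.loc[computed, "p_fdr"] = fdr_bh(out.loc[computed, "p"].to_numpy())
    return AssociationReport(table=out)


def contrast_groups(
    W: np.ndarray,
    labels: np.ndarray,
    group1,
    group2,
    factor_names: list[str] | None = None,
    adjust: bool = True,
) -> ContrastReport:
    """Two-sample t test (pooled variance) per factor with Cohen's d.

    ``labels`` assigns each patient to a group; rows outside the two groups
    are ignored.  With ``adjust`` the p values are BH-FDR corrected across
    factors (the onset contrast); without it raw p values are reported (the
    sex contrast).  Zero-variance groups trigger a recorded Welch fallback.
    """
    W = np.asarray(W, float)
    labels = np.asarray(labels)
    m1, m2 = labels == group1, labels == group2
    if m1.sum() < 3 or m2.sum() < 3:
        raise ValueError("both groups need at least 3 members")
    names = factor_names or [f"factor_{j + 1}" for j in range(W.shape[1])]

    rows = []
    for j, fname in enumerate(names):
        g1, g2 = W[m1, j], W[m2, j]
        welch = g1.var(ddof=1) == 0 or g2.var(ddof=1) == 0
        if welch:
            warnings.warn(f"{fname}: zero within-group variance; Welch t applied")
        res = stats.ttest_ind(g1, g2, equal_var=not welch)
        rows.append(
            {
                "factor": fname,
                "mean_1": float(g1.mean()),
                "mean_2": float(g2.mean()),
                "t": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
                "cohens_d": cohens_d(g1, g2),
                "welch": welch,
            }
        )
    out = pd.DataFrame(rows)
    out["p_fdr"] = fdr_bh(out["p"].to_numpy()) if adjust else out["p"]
    return ContrastReport(table=out)


def onset_contrast(
    W: np.ndarray, table: pd.DataFrame, factor_names: list[str] | None = None
) -> ContrastReport:
    """Adult-onset (> 18 y) vs adolescent-onset (<= 18 y) composition contrast."""
    onset = np.asarray(table["onset_age"], float)
    ok = np.isfinite(onset)
    labels = np.where(onset > ONSET_CUTOFF_YEARS, "adult", "adolescent")
    rep = contrast_groups(
        W[ok], labels[ok], "adult", "adolescent", factor_names=factor_names, adjust=True
    )
    rep.grouping = "adult_vs_adolescent_onset"
    return rep


def sex_contrast(
    W: np.ndarray, table: pd.DataFrame, factor_names: list[str] | None = None
) -> ContrastReport:
    """Male vs female composition contrast, reported with raw p values."""
    labels = np.asarray(table["sex"]).astype(int)
    rep = contrast_groups(W, labels, 1, 0, factor_names=factor_names, adjust=False)
    rep.grouping = "male_vs_female"
    return rep
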