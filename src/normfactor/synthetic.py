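"""Synthetic VBM cohorts with known normative structure and planted factors.

The generator emulates the statistical structure the framework assumes:
healthy-control gray matter volume (GMV) varies smoothly with age (monotone
decline) and sex on top of a smooth spatial baseline, with i.i.d. Gaussian
residual noise; patients additionally carry a nonnegative mixture of planted
spatial disease factors (positive factors add volume, negative factors remove
it).  Clinical scores can be coupled to the planted loadings through a
Gaussian copula on ranks, so rank correlations hit a requested target without
distorting the marginal score distributions.

Everything is deterministic given ``CohortSpec.seed``.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.stats import norm, rankdata

from .io import CLINICAL_COLUMNS, VoxelSpace, write_subject_table

# HAMD factor-score marginals (mean, sd) used for simulated patients:
# anxiety/somatization, weight, cognitive impairment, psychomotor slowing,
# sleep disturbance — typical first-episode outpatient values.
_HAMD_MARGINALS = [
    ("hamd_anxiety_somatization", 5.77, 2.56),
    ("hamd_weight", 0.15, 0.51),
    ("hamd_cognitive_impairment", 2.92, 2.46),
    ("hamd_psychomotor_slowing", 8.55, 2.00),
    ("hamd_sleep_disturbance", 4.21, 2.25),
]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    Defaults mirror a single-site first-episode depression sample: 130
    controls and 105 patients aged 11-37, a ~3200-voxel ellipsoidal mask on an
    18^3 grid (1.5 mm isotropic), two positive and two negative planted
    factors, and residual noise at 20% of the unit factor amplitude.
    """

    n_controls: int = 130
    n_patients: int = 105
    grid_shape: tuple[int, int, int] = (18, 18, 18)
    mask_fraction: float = 0.55
    age_range: tuple[float, float] = (11.0, 37.0)
    k_pos: int = 2
    k_neg: int = 2
    factor_smoothness: float = 1.5
    loading_scale: float = 1.0
    noise_sd: float = 0.2
    clinical_coupling: float | tuple[float, ...] = 0.0
    seed: int = 0
    #: seed for the spatial truth (mask, baseline, age/sex fields, factor
    #: maps).  Defaults to ``seed``; give two specs the same structure_seed
    #: but different seeds to draw independent cohorts from one generative
    #: process (paired discovery/validation cohorts).
    structure_seed: int | None = None

    def validate(self) -> None:
        if self.n_controls < 10 or self.n_patients < 10:
            raise ValueError("need at least 10 controls and 10 patients")
        if self.k_pos < 1 or self.k_neg < 1:
            raise ValueError("k_pos and k_neg must be >= 1")
        if not (0.0 < self.mask_fraction <= 1.0):
            raise ValueError("mask_fraction must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.age_range[1] <= self.age_range[0]:
            raise ValueError("age_range must be increasing")
        for rho in np.atleast_1d(np.asarray(self.clinical_coupling, float)):
            if not (-1.0 <= rho <= 1.0):
                raise ValueError("clinical_coupling entries must lie in [-1, 1]")
        n_masked = int(round(self.mask_fraction * np.prod(self.grid_shape)))
        if n_masked < 100:
            raise ValueError("grid too small: fewer than 100 masked voxels")

    def coupling_vector(self, k_total: int) -> np.ndarray:
        rho = np.atleast_1d(np.asarray(self.clinical_coupling, float))
        if rho.size == 1:
            rho = np.repeat(rho, k_total)
        out = np.zeros(k_total)
        out[: min(rho.size, k_total)] = rho[:k_total]
        return out


@dataclass
class SyntheticTruth:
    """Planted generative quantities (the ground truth of a synthetic cohort)."""

    true_H_pos: np.ndarray  # (k_pos, n_voxels), nonnegative, unit max
    true_H_neg: np.ndarray
    true_W_pos: np.ndarray  # (n_patients, k_pos), nonnegative
    true_W_neg: np.ndarray
    age_effect: np.ndarray  # (2, n_voxels): linear & quadratic decline coefs
    sex_effect: np.ndarray  # (n_voxels,)
    baseline: np.ndarray  # (n_voxels,)
    clip_fraction: float = 0.0

    def validate(self) -> None:
        for name in ("true_H_pos", "true_H_neg", "true_W_pos", "true_W_neg"):
            arr = getattr(self, name)
            if np.any(arr < 0):
                raise AssertionError(f"{name} has negative entries")
        for H in (self.true_H_pos, self.true_H_neg):
            if np.any((H > 0).sum(axis=1) == 0):
                raise AssertionError("a planted factor map is everywhere zero")


@dataclass
class CohortBundle:
    """In-memory synthetic cohort: covariate table, GMV matrix, space, truth."""

    spec: CohortSpec
    table: pd.DataFrame
    gmv: np.ndarray  # (n_controls + n_patients, n_voxels)
    space: VoxelSpace
    truth: SyntheticTruth

    @property
    def is_control(self) -> np.ndarray:
        return (self.table["group"] == "control").to_numpy()

    @property
    def control_matrix(self) -> np.ndarray:
        return self.gmv[self.is_control]

    @property
    def patient_matrix(self) -> np.ndarray:
        return self.gmv[~self.is_control]

    def covariates(self, which: str = "all") -> pd.DataFrame:
        sel = {
            "all": slice(None),
            "control": self.is_control,
            "patient": ~self.is_control,
        }[which]
        return self.table.loc[sel, ["age", "sex"]].reset_index(drop=True)


def _ellipsoid_mask(grid_shape: tuple[int, int, int], mask_fraction: float) -> np.ndarray:
    """Centered ellipsoidal mask with exactly round(fraction * n_grid) voxels."""
    n_grid = int(np.prod(grid_shape))
    n_keep = int(round(mask_fraction * n_grid))
    coords = np.stack(
        np.meshgrid(*[np.arange(s) for s in grid_shape], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    center = (np.asarray(grid_shape) - 1) / 2.0
    radii = np.asarray(grid_shape) / 2.0
    dist = np.sum(((coords - center) / radii) ** 2, axis=1)
    keep = np.argsort(dist, kind="stable")[:n_keep]
    mask = np.zeros(n_grid, dtype=bool)
    mask[keep] = True
    return mask.reshape(grid_shape)


def _smooth_field(rng: np.random.Generator, grid_shape, sigma: float) -> np.ndarray:
    f = gaussian_filter(rng.standard_normal(grid_shape), sigma=sigma)
    return (f - f.mean()) / (f.std() + 1e-12)


def _blob_factor(
    rng: np.random.Generator,
    space: VoxelSpace,
    smoothness: float,
) -> np.ndarray:
    """One factor map: 2-4 Gaussian blobs at random in-mask sites, unit max."""
    grid = space.grid_shape
    coords = np.stack(np.unravel_index(space.mask_indices, grid), axis=1).astype(float)
    n_blobs = int(rng.integers(2, 5))
    centers = coords[rng.integers(0, coords.shape[0], size=n_blobs)]
    d2 = ((coords[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    f = np.exp(-d2 / (2.0 * smoothness**2)).sum(axis=1)
    return f / f.max()


def _planted_factors(
    rng: np.random.Generator,
    space: VoxelSpace,
    k: int,
    smoothness: float,
    max_overlap: float = 0.3,
    avoid: list[np.ndarray] | None = None,
) -> np.ndarray:
    """Draw k factor maps, resampling until pairwise correlation <= max_overlap.

    ``avoid`` holds already-planted maps (e.g. the opposite sign's factors):
    overlap with those is constrained too, since positive and negative
    deviations cancel where factors of opposite sign coincide.
    """
    rows: list[np.ndarray] = list(avoid or [])
    out: list[np.ndarray] = []
    for _ in range(k):
        for _attempt in range(50):
            cand = _blob_factor(rng, space, smoothness)
            if all(abs(np.corrcoef(cand, r)[0, 1]) <= max_overlap for r in rows):
                break
        rows.append(cand)
        out.append(cand)
    return np.asarray(out)


def _coupled_scores(
    rng: np.random.Generator,
    w_col: np.ndarray,
    rho: float,
    mean: float,
    sd: float,
) -> np.ndarray:
    """Gaussian copula: score with Spearman-type correlation rho to w_col."""
    n = w_col.size
    z_w = norm.ppf((rankdata(w_col) - 0.5) / n)
    eps = rng.standard_normal(n)
    z = rho * z_w + np.sqrt(max(0.0, 1.0 - rho**2)) * eps
    return mean + sd * z


def generate_cohort(spec: CohortSpec) -> CohortBundle:
    """Generate a control + patient cohort with planted disease factors.

    Control GMV at voxel v is ``baseline_v + f_v(age) + g_v * sex + noise``
    with ``f_v`` a monotone-decreasing quadratic over the age range; patients
    additionally receive ``+ W_pos @ H_pos - W_neg @ H_neg``.  GMV is clipped
    at zero (the clip fraction is recorded on the truth object).
    """
    spec.validate()
    struct_seed = spec.seed if spec.structure_seed is None else spec.structure_seed
    rng_s = np.random.default_rng(np.random.SeedSequence([struct_seed, 0]))
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    grid = spec.grid_shape

    mask = _ellipsoid_mask(grid, spec.mask_fraction)
    affine = np.diag([1.5, 1.5, 1.5, 1.0])
    space = VoxelSpace.from_mask(mask, affine)
    V = space.n_voxels

    baseline = 4.0 + 0.5 * space.vectorize(_smooth_field(rng_s, grid, sigma=2.0))
    # monotone-decreasing quadratic age effect: f_v(u) = -(c1 u + c2 u^2),
    # u in [0, 1]; c1, c2 >= 0 and spatially smooth
    c1 = 0.45 * np.abs(space.vectorize(_smooth_field(rng_s, grid, sigma=2.0)))
    c2 = 0.35 * np.abs(space.vectorize(_smooth_field(rng_s, grid, sigma=2.0)))
    sex_eff = 0.2 * space.vectorize(_smooth_field(rng_s, grid, sigma=2.0))

    H_pos = _planted_factors(rng_s, space, spec.k_pos, spec.factor_smoothness)
    H_neg = _planted_factors(
        rng_s, space, spec.k_neg, spec.factor_smoothness, avoid=list(H_pos)
    )

    n_ctrl, n_pat = spec.n_controls, spec.n_patients
    n_total = n_ctrl + n_pat
    age = rng.uniform(*spec.age_range, size=n_total)
    sex = rng.integers(0, 2, size=n_total).astype(float)
    u = (age - spec.age_range[0]) / (spec.age_range[1] - spec.age_range[0])

    gmv = (
        baseline[None, :]
        - np.outer(u, c1)
        - np.outer(u**2, c2)
        + np.outer(sex, sex_eff)
        + rng.normal(0.0, spec.noise_sd, size=(n_total, V))
    )

    if spec.loading_scale > 0:
        shape = 4.0
        W_pos = rng.gamma(shape, spec.loading_scale / shape, size=(n_pat, spec.k_pos))
        W_neg = rng.gamma(shape, spec.loading_scale / shape, size=(n_pat, spec.k_neg))
    else:
        # null cohort: patients carry no factor signal at all
        rng.gamma(4.0, 1.0, size=(n_pat, spec.k_pos + spec.k_neg))  # keep stream aligned
        W_pos = np.zeros((n_pat, spec.k_pos))
        W_neg = np.zeros((n_pat, spec.k_neg))
    gmv[n_ctrl:] += W_pos @ H_pos - W_neg @ H_neg

    clip_fraction = float(np.mean(gmv < 0))
    gmv = np.clip(gmv, 0.0, None)

    table = pd.DataFrame(
        {
            "subject_id": [f"sub-C{i + 1:03d}" for i in range(n_ctrl)]
            + [f"sub-P{i + 1:03d}" for i in range(n_pat)],
            "age": np.round(age, 2),
            "sex": sex.astype(int),
            "group": ["control"] * n_ctrl + ["patient"] * n_pat,
            "education_years": np.round(np.clip(rng.normal(13.0, 4.0, n_total), 6, 22), 1),
            "tiv": np.round(rng.normal(1450.0, 120.0, n_total), 1),
            "iqr": np.round(rng.normal(2.0, 0.15, n_total), 3),
        }
    )

    # clinical scores for patients: HAMD factor scores in fixed order, the
    # i-th coupled to the i-th planted factor (positive factors first)
    k_total = spec.k_pos + spec.k_neg
    rho = spec.coupling_vector(k_total)
    W_all = np.hstack([W_pos, W_neg])
    for col in CLINICAL_COLUMNS:
        table[col] = np.nan
    pat_idx = table.index[n_ctrl:]
    for j, (col, mean, sd) in enumerate(_HAMD_MARGINALS):
        if j < k_total and abs(rho[j]) > 0 and spec.loading_scale > 0:
            scores = _coupled_scores(rng, W_all[:, j], rho[j], mean, sd)
        else:
            scores = rng.normal(mean, sd, size=n_pat)
        table.loc[pat_idx, col] = np.round(scores, 2)
    subscales = [c for c, _, _ in _HAMD_MARGINALS]
    table.loc[pat_idx, "hamd_total"] = table.loc[pat_idx, subscales].sum(axis=1).round(2)
    duration = rng.gamma(2.0, 0.75, size=n_pat)
    table.loc[pat_idx, "duration"] = np.round(duration, 2)
    table.loc[pat_idx, "onset_age"] = np.round(
        np.maximum(age[n_ctrl:] - duration, 8.0), 2
    )

    truth = SyntheticTruth(
        true_H_pos=H_pos,
        true_H_neg=H_neg,
        true_W_pos=W_pos,
        true_W_neg=W_neg,
        age_effect=np.stack([c1, c2]),
        sex_effect=sex_eff,
        baseline=baseline,
        clip_fraction=clip_fraction,
    )
    truth.validate()
    return CohortBundle(spec=spec, table=table, gmv=gmv, space=space, truth=truth)


def write_fixture(bundle: CohortBundle, out_dir: str | Path, force: bool = False) -> dict:
    """Write a cohort to disk: one NIfTI per subject, mask, tables, truth.

    Refuses to write into an existing non-empty directory unless ``force``.
    Returns a dict of the written paths.
    """
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not force:
            raise FileExistsError(f"{out_dir} exists and is not empty (use force=True)")
        shutil.rmtree(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    space = bundle.space
    nib.save(
        nib.Nifti1Image(space.mask_volume().astype(np.uint8), space.affine),
        str(out_dir / "mask.nii.gz"),
    )
    image_paths = []
    for sid, row in zip(bundle.table["subject_id"], bundle.gmv):
        p = img_dir / f"{sid}.nii.gz"
        vol = space.devectorize(row).astype(np.float32)
        nib.save(nib.Nifti1Image(vol, space.affine), str(p))
        image_paths.append(p)

    write_subject_table(bundle.table, out_dir / "subjects.tsv")
    clin = bundle.table[bundle.table["group"] == "patient"][
        ["subject_id"] + CLINICAL_COLUMNS
    ]
    write_subject_table(clin, out_dir / "clinical.tsv")

    t = bundle.truth
    np.savez(
        out_dir / "truth.npz",
        true_H_pos=t.true_H_pos,
        true_H_neg=t.true_H_neg,
        true_W_pos=t.true_W_pos,
        true_W_neg=t.true_W_neg,
        age_effect=t.age_effect,
        sex_effect=t.sex_effect,
        baseline=t.baseline,
        clip_fraction=t.clip_fraction,
    )
    return {
        "images": image_paths,
        "mask": out_dir / "mask.nii.gz",
        "subjects": out_dir / "subjects.tsv",
        "clinical": out_dir / "clinical.tsv",
        "truth": out_dir / "truth.npz",
    }


def load_truth(path: str | Path) -> SyntheticTruth:
    z = np.load(path)
    return SyntheticTruth(
        true_H_pos=z["true_H_pos"],
        true_H_neg=z["true_H_neg"],
        true_W_pos=z["true_W_pos"],
        true_W_neg=z["true_W_neg"],
        age_effect=z["age_effect"],
        sex_effect=z["sex_effect"],
        baseline=z["baseline"],
        clip_fraction=float(z["clip_fraction"]),
    )
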