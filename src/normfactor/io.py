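"""NIfTI / table I/O and the masked-voxel vector convention.

All algebra in this package happens on ``subjects x masked-voxels`` matrices;
full 3-D grids appear only at the I/O boundary.  A :class:`VoxelSpace` pins
down the grid, the affine and the (strictly increasing) linear indices of the
in-mask voxels, so every vectorized map in a project has the same length and
voxel order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from ._utils import as_2d, check_finite

AFFINE_ATOL = 1e-4

#: canonical covariate / clinical column names for subject tables
SUBJECT_COLUMNS = ["subject_id", "age", "sex", "group", "education_years", "tiv", "iqr"]
CLINICAL_COLUMNS = [
    "hamd_anxiety_somatization",
    "hamd_weight",
    "hamd_cognitive_impairment",
    "hamd_psychomotor_slowing",
    "hamd_sleep_disturbance",
    "hamd_total",
    "duration",
    "onset_age",
]


@dataclass
class VoxelSpace:
    """Grid geometry plus the ordered linear indices of in-mask voxels."""

    grid_shape: tuple[int, int, int]
    affine: np.ndarray
    mask_indices: np.ndarray

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask_indices = np.asarray(self.mask_indices, dtype=np.int64)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        n_grid = int(np.prod(self.grid_shape))
        if self.mask_indices.size and (
            np.any(np.diff(self.mask_indices) <= 0)
            or self.mask_indices[0] < 0
            or self.mask_indices[-1] >= n_grid
        ):
            raise ValueError("mask_indices must be strictly increasing and within grid bounds")

    @property
    def n_voxels(self) -> int:
        return int(self.mask_indices.size)

    @classmethod
    def from_mask(cls, mask: np.ndarray, affine: np.ndarray) -> "VoxelSpace":
        mask = np.asarray(mask) > 0
        if mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        idx = np.flatnonzero(mask.ravel(order="C"))
        return cls(tuple(mask.shape), np.asarray(affine, float), idx)

    def mask_volume(self) -> np.ndarray:
        vol = np.zeros(int(np.prod(self.grid_shape)), dtype=np.uint8)
        vol[self.mask_indices] = 1
        return vol.reshape(self.grid_shape)

    def vectorize(self, volume: np.ndarray) -> np.ndarray:
        """3-D grid -> masked vector (mask_indices order)."""
        volume = np.asarray(volume)
        if volume.shape != tuple(self.grid_shape):
            raise ValueError(f"volume shape {volume.shape} != grid {self.grid_shape}")
        return volume.ravel(order="C")[self.mask_indices]

    def devectorize(self, vector: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Masked vector -> 3-D grid with ``fill`` outside the mask."""
        vector = np.asarray(vector)
        if vector.shape != (self.n_voxels,):
            raise ValueError(f"vector length {vector.shape} != mask size {self.n_voxels}")
        vol = np.full(int(np.prod(self.grid_shape)), fill, dtype=float)
        vol[self.mask_indices] = vector
        return vol.reshape(self.grid_shape)


def load_mask(mask_path: str | Path) -> VoxelSpace:
    img = nib.load(str(mask_path))
    return VoxelSpace.from_mask(np.asarray(img.dataobj), img.affine)


def read_subject_table(table_path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(table_path, sep="\t")
    if "subject_id" not in table.columns:
        raise ValueError(f"{table_path}: missing subject_id column")
    if table["subject_id"].duplicated().any():
        dupes = table.loc[table["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject_id values: {dupes}")
    if "age" in table.columns and (table["age"] <= 0).any():
        raise ValueError("non-positive ages in subject table")
    return table


def write_subject_table(table: pd.DataFrame, table_path: str | Path) -> None:
    table.to_csv(table_path, sep="\t", index=False)


def load_cohort(
    image_paths: Sequence[str | Path],
    mask_path: str | Path,
    table_path: str | Path,
) -> tuple[np.ndarray, VoxelSpace, pd.DataFrame]:
    """Load per-subject GMV images into a subjects x masked-voxels matrix.

    Row order follows the subject table; image files are matched to table rows
    by subject_id (file stem up to the first '.').  Grid shape and affine of
    every image must agree with the mask within ``AFFINE_ATOL``.
    """
    space = load_mask(mask_path)
    table = read_subject_table(table_path)

    by_id: dict[str, Path] = {}
    for p in map(Path, image_paths):
        by_id[p.name.split(".")[0]] = p

    table_ids = [str(s) for s in table["subject_id"]]
    missing_img = sorted(set(table_ids) - set(by_id))
    missing_row = sorted(set(by_id) - set(table_ids))
    if missing_img or missing_row:
        raise ValueError(
            "subject/image mismatch: "
            f"table rows without image {missing_img}; images without table row {missing_row}"
        )

    rows = np.empty((len(table_ids), space.n_voxels), dtype=np.float64)
    for i, sid in enumerate(table_ids):
        img = nib.load(str(by_id[sid]))
        if tuple(img.shape) != tuple(space.grid_shape):
            raise ValueError(f"{by_id[sid]}: grid {img.shape} != mask grid {space.grid_shape}")
        if not np.allclose(img.affine, space.affine, atol=AFFINE_ATOL):
            raise ValueError(f"{by_id[sid]}: affine differs from mask affine beyond {AFFINE_ATOL}")
        rows[i] = space.vectorize(np.asarray(img.get_fdata()))
    return rows, space, table


def save_image(vector: np.ndarray, space: VoxelSpace, path: str | Path) -> None:
    vol = space.devectorize(np.asarray(vector, dtype=np.float32).astype(float))
    nib.save(nib.Nifti1Image(vol.astype(np.float32), space.affine), str(path))


def save_factor_maps(
    H: np.ndarray,
    space: VoxelSpace,
    out_dir: str | Path,
    prefix: str = "factor",
    top_fraction: float = 0.05,
) -> list[Path]:
    """Write one NIfTI per factor plus a thresholded copy (top in-mask voxels).

    The displayed copy keeps the ``top_fraction`` of in-mask voxels with the
    largest loadings (ties broken toward the lower voxel index); the threshold
    used per factor is recorded in a sidecar text file.
    """
    from .annotation import top_fraction_mask

    H = as_2d(H, "H")
    check_finite(H, "H")
    if H.shape[1] != space.n_voxels:
        raise ValueError("H column count does not match the voxel space")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    sidecar_lines = []
    for j, row in enumerate(H, start=1):
        p_full = out_dir / f"{prefix}_{j:02d}.nii.gz"
        save_image(row, space, p_full)
        keep = top_fraction_mask(row, fraction=top_fraction)
        thresh = float(np.min(row[keep]))
        top_row = np.zeros_like(row)
        top_row[keep] = row[keep]
        p_top = out_dir / f"{prefix}_{j:02d}_top{int(round(100 * top_fraction))}pct.nii.gz"
        save_image(top_row, space, p_top)
        sidecar_lines.append(f"{prefix}_{j:02d}\tthreshold={thresh:.8g}\tn_kept={keep.size}")
        written += [p_full, p_top]
    (out_dir / f"{prefix}_thresholds.txt").write_text("\n".join(sidecar_lines) + "\n")
    return written


def save_matrix_tsv(
    matrix: np.ndarray, row_ids: Sequence[str], col_names: Sequence[str], path: str | Path
) -> None:
    pd.DataFrame(matrix, index=list(row_ids), columns=list(col_names)).rename_axis(
        "subject_id"
    ).to_csv(path, sep="\t")


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
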