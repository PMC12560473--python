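"""Reading, writing and validation of multi-b-value DWI series and ROI masks.

All imaging I/O is NIfTI-1 via nibabel.  b-values travel in an FSL-style
``.bval`` text file (one line, whitespace-separated), which is the single
source of truth for the diffusion weighting of each volume.  No resampling or
registration is ever performed here: volumes that do not share a grid and
affine are rejected loudly.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "DWISeries",
    "ROIMask",
    "load_series",
    "save_series",
    "load_mask",
    "read_bval",
    "write_bval",
    "load_cohort",
    "save_cohort",
    "COHORT_COLUMNS",
]

#: canonical cohort-table header (CSV)
COHORT_COLUMNS = [
    "subject_id",
    "group",
    "sdc_au_per_s",
    "ddvd_au_per_pixel",
    "adc_e4_mm2_per_s",
    "idh_gene",
    "idh_ihc",
    "grade",
    "ki67_pct",
]


class GeometryError(ValueError):
    """Volumes or masks that do not live on the same voxel grid."""


@dataclasses.dataclass
class DWISeries:
    """A stack of co-registered diffusion-weighted volumes indexed by b-value.

    Parameters
    ----------
    b_values
        Unique diffusion weightings in s/mm**2, stored sorted ascending.
    data
        Signal array of shape ``(*grid, n_b)``, arbitrary units, float.
    affine
        4x4 NIfTI voxel-to-world affine shared by every volume.
    """

    b_values: np.ndarray
    data: np.ndarray
    affine: np.ndarray = dataclasses.field(
        default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.b_values = np.asarray(self.b_values, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.b_values.ndim != 1:
            raise ValueError("b_values must be one-dimensional")
        if self.data.ndim != 4:
            raise ValueError("data must be 4-D: (x, y, z, b)")
        if self.data.shape[-1] != self.b_values.size:
            raise ValueError(
                f"bval/volume count mismatch: {self.b_values.size} b-values "
                f"but {self.data.shape[-1]} volumes")
        if np.any(self.b_values < 0):
            raise ValueError("b-values must be non-negative")
        if np.unique(self.b_values).size != self.b_values.size:
            raise ValueError("duplicate b-values in series")
        order = np.argsort(self.b_values)
        self.b_values = self.b_values[order]
        self.data = self.data[..., order]
        bad = np.count_nonzero(~np.isfinite(self.data))
        if bad:
            raise ValueError(f"non-finite signal in {bad} voxel(s)")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths (mm) from the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def volume(self, b: float) -> np.ndarray:
        """Signal volume acquired at b-value ``b``; KeyError if absent."""
        idx = np.flatnonzero(np.isclose(self.b_values, b))
        if idx.size == 0:
            raise KeyError(
                f"no volume at b={b}; available: {self.b_values.tolist()}")
        return self.data[..., idx[0]]

    def has_b(self, b: float) -> bool:
        return bool(np.any(np.isclose(self.b_values, b)))


@dataclasses.dataclass
class ROIMask:
    """Binary region-of-interest on the grid of an accompanying DWISeries.

    ``exclusion`` voxels (necrosis, cysts, edema, calcification) are removed
    from the inclusion mask before use; the effective ROI must be non-empty.
    """

    mask: np.ndarray
    affine: np.ndarray = dataclasses.field(
        default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask).astype(bool)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        if self.pixel_count == 0:
            raise ValueError("empty ROI: mask selects no voxels")

    @property
    def pixel_count(self) -> int:
        return int(np.count_nonzero(self.mask))

    def check_grid(self, series: DWISeries) -> None:
        if self.mask.shape != series.grid_shape:
            raise GeometryError(
                f"mask grid {self.mask.shape} != series grid "
                f"{series.grid_shape}")
        if not np.allclose(self.affine, series.affine, atol=1e-4):
            raise GeometryError("mask affine differs from series affine")


def read_bval(path: str | Path) -> np.ndarray:
    """Read an FSL-style .bval file (whitespace-separated, one row)."""
    vals = np.loadtxt(path, ndmin=1).ravel()
    return vals.astype(float)


def write_bval(b_values: Sequence[float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in b_values) + "\n")


def _load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def load_series(
    image_paths: str | Path | Sequence[str | Path],
    bval_path: str | Path,
) -> DWISeries:
    """Assemble a validated DWISeries from one 4-D NIfTI or several 3-D ones.

    The number of entries in the .bval file must equal the number of volumes;
    grids and affines must agree exactly (no silent resampling).  Input file
    order is irrelevant: the series is sorted by b-value.
    """
    b_values = read_bval(bval_path)
    if isinstance(image_paths, (str, Path)):
        data, affine = _load_nifti(image_paths)
        if data.ndim == 3:
            data = data[..., None]
        if data.ndim != 4:
            raise ValueError(
                f"{image_paths}: expected 3-D or 4-D image, got "
                f"{data.ndim}-D")
    else:
        vols, affines = [], []
        for p in image_paths:
            arr, aff = _load_nifti(p)
            if arr.ndim != 3:
                raise ValueError(f"{p}: expected a 3-D volume")
            vols.append(arr)
            affines.append(aff)
        shapes = {v.shape for v in vols}
        if len(shapes) > 1:
            raise GeometryError(
                f"volumes have different grids: {sorted(shapes)}")
        for p, aff in zip(image_paths, affines):
            if not np.allclose(aff, affines[0], atol=1e-4):
                raise GeometryError(f"{p}: affine differs from first volume")
        data = np.stack(vols, axis=-1)
        affine = affines[0]
    if data.shape[-1] != b_values.size:
        raise ValueError(
            f"bval/volume count mismatch: {b_values.size} b-values in "
            f"{bval_path} but {data.shape[-1]} volumes")
    return DWISeries(b_values=b_values, data=data, affine=affine)


def save_series(
    series: DWISeries,
    image_path: str | Path,
    bval_path: str | Path,
    description: str = "",
) -> None:
    """Write a DWISeries as a single 4-D NIfTI plus a .bval file."""
    img = nib.Nifti1Image(series.data.astype(np.float32), series.affine)
    if description:
        img.header["descrip"] = description.encode()[:79]
    nib.save(img, str(image_path))
    write_bval(series.b_values, bval_path)


def save_map(
    arr: np.ndarray,
    affine: np.ndarray,
    path: str | Path,
    unit: str = "",
) -> None:
    """Write a scalar map with its unit string in the NIfTI descrip field."""
    img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine)
    if unit:
        img.header["descrip"] = f"unit: {unit}".encode()[:79]
    nib.save(img, str(path))


def load_mask(
    path: str | Path,
    series: DWISeries,
    exclusion_path: str | Path | None = None,
) -> ROIMask:
    """Load a binary mask, subtract an optional exclusion mask, validate grid."""
    arr, affine = _load_nifti(path)
    if arr.shape != series.grid_shape:
        raise GeometryError(
            f"mask grid {arr.shape} != series grid {series.grid_shape}")
    mask = arr > 0
    if exclusion_path is not None:
        excl, excl_aff = _load_nifti(exclusion_path)
        if excl.shape != series.grid_shape:
            raise GeometryError(
                f"exclusion mask grid {excl.shape} != series grid "
                f"{series.grid_shape}")
        mask = mask & ~(excl > 0)
    if not mask.any():
        raise ValueError("empty ROI: all voxels excluded")
    return ROIMask(mask=mask, affine=affine)


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV and check the canonical columns are present."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    return df


def save_cohort(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
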