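"""Reading, writing and validation of diffusion-weighted volumes.

Conventions
-----------
* World space is RAS (right/anterior/superior); the world x-axis is the
  right–left axis on which the perivascular-space diffusivity is read out.
* b-vectors are interpreted in world axes (after any reorientation), not in
  the scanner frame.
* Gradient tables are FSL-style plain text: one row of b-values, three rows
  of b-vector components. Gzipped NIfTI is accepted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "GradientTable",
    "DWIVolume",
    "GradientValidationReport",
    "DwiIOError",
    "load_dwi",
    "write_dwi",
    "validate_gradients",
]

#: tolerance on unit-norm b-vectors
_BVEC_NORM_TOL = 1e-3


class DwiIOError(ValueError):
    """Raised for malformed diffusion volumes or gradient tables."""


@dataclass(frozen=True)
class GradientTable:
    """Acquisition geometry: per-volume b-value (s/mm^2) and unit b-vector.

    b=0 volumes carry a zero vector.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self) -> None:
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.ndim != 2 or bvecs.shape[1] != 3:
            if bvecs.shape[0] == 3 and bvecs.ndim == 2:
                bvecs = bvecs.T
            else:
                raise DwiIOError(f"bvecs must be (n, 3); got {bvecs.shape}")
        if len(bvals) != len(bvecs):
            raise DwiIOError(
                f"bval/bvec length mismatch: {len(bvals)} vs {len(bvecs)}"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    def design_matrix(self) -> np.ndarray:
        """Rows [b gx^2, b gy^2, b gz^2, 2b gx gy, 2b gx gz, 2b gy gz] of
        the log-linear tensor model, one per volume."""
        b = self.bvals
        gx, gy, gz = self.bvecs.T
        return np.column_stack(
            [b * gx**2, b * gy**2, b * gz**2,
             2 * b * gx * gy, 2 * b * gx * gz, 2 * b * gy * gz]
        )


@dataclass(frozen=True)
class DWIVolume:
    """4-D diffusion-weighted signal grid with its spatial frame."""

    data: np.ndarray
    affine: np.ndarray
    voxel_size: tuple[float, float, float] = field(init=False)
    axcodes: tuple[str, str, str] = field(init=False)

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 4:
            raise DwiIOError(f"expected a 4-D volume; got {data.ndim}-D")
        if np.isnan(data).any():
            raise DwiIOError("volume contains NaN intensities")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise DwiIOError("affine must be 4x4")
        vox = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
        if np.any(vox <= 0):
            raise DwiIOError("voxel sizes must be strictly positive")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "voxel_size", tuple(float(v) for v in vox))
        object.__setattr__(self, "axcodes", tuple(nib.aff2axcodes(affine)))

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map (…, 3) 0-based voxel indices to world mm coordinates."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class GradientValidationReport:
    """Report-only validation result; empty ``violations`` means valid."""

    violations: list[str]

    @property
    def ok(self) -> bool:
        return not self.violations


def _read_fsl_table(bval_path: str | os.PathLike, bvec_path: str | os.PathLike) -> GradientTable:
    bvals = np.loadtxt(bval_path, dtype=float).ravel()
    bvecs = np.loadtxt(bvec_path, dtype=float)
    if bvecs.ndim != 2:
        raise DwiIOError(f"bvec file {bvec_path} is not a 3xN table")
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return GradientTable(bvals=bvals, bvecs=bvecs)


def validate_gradients(table: GradientTable) -> GradientValidationReport:
    """Check the gradient-table invariants without raising.

    A valid table has unit b-vectors wherever b>0, at least one b=0
    volume, and at least six non-collinear diffusion directions (the
    tensor has six unknowns on top of the baseline signal).
    """
    if len(table) == 0:
        raise DwiIOError("empty gradient table")
    violations: list[str] = []
    norms = np.linalg.norm(table.bvecs, axis=1)
    dw = table.bvals > 0
    bad = dw & (np.abs(norms - 1.0) > _BVEC_NORM_TOL)
    for i in np.flatnonzero(bad):
        violations.append(
            f"volume {i}: b={table.bvals[i]:g} but |bvec|={norms[i]:.6f} (expected 1)"
        )
    if table.n_b0 == 0:
        violations.append("no b=0 volume present")
    # collinearity: rank of the quadratic design over distinct directions
    if dw.any():
        design = table.design_matrix()[dw]
        rank = np.linalg.matrix_rank(design)
        if rank < 6:
            violations.append(
                f"insufficient directions: tensor design rank {rank} < 6"
            )
    else:
        violations.append("no diffusion-weighted volumes present")
    return GradientValidationReport(violations=violations)


def load_dwi(
    image_path: str | os.PathLike,
    bval_path: str | os.PathLike,
    bvec_path: str | os.PathLike,
) -> tuple[DWIVolume, GradientTable]:
    """Load and cross-validate a 4-D NIfTI with its FSL-style gradient files.

    Raises :class:`DwiIOError` on a dimension mismatch between image and
    table, on NaNs in the image, or on a non-4-D image.
    """
    for p in (image_path, bval_path, bvec_path):
        if not os.path.exists(p):
            raise FileNotFoundError(p)
    img = nib.load(str(image_path))
    data = np.asarray(img.dataobj, dtype=float)
    volume = DWIVolume(data=data, affine=np.asarray(img.affine))
    table = _read_fsl_table(bval_path, bvec_path)
    if volume.n_volumes != len(table):
        raise DwiIOError(
            f"image has {volume.n_volumes} volumes but gradient table has "
            f"{len(table)} entries"
        )
    return volume, table


def write_dwi(
    volume: DWIVolume, table: GradientTable, prefix: str | os.PathLike
) -> dict[str, str]:
    """Write ``<prefix>.nii.gz`` plus FSL-style ``.bval``/``.bvec`` files.

    Intensities are stored as float64 so a round trip is bit exact.
    """
    prefix = str(prefix)
    paths = {
        "image": prefix + ".nii.gz",
        "bval": prefix + ".bval",
        "bvec": prefix + ".bvec",
    }
    img = nib.Nifti1Image(volume.data.astype(np.float64), volume.affine)
    img.to_filename(paths["image"])
    np.savetxt(paths["bval"], table.bvals[None, :], fmt="%.10g")
    np.savetxt(paths["bvec"], table.bvecs.T, fmt="%.17g")
    return paths
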