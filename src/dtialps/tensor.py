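"""Voxel-wise diffusion-tensor estimation and scalar maps.

The estimator is plain (unweighted) log-linear least squares on

    ln S = ln S0 - b g^T D g

which is exact on noiseless data and deterministic. Multiple b=0 volumes
are averaged into one baseline row before fitting. Voxels with any
non-positive fitted signal are flagged as background and excluded.

Eigenvalues are clamped at zero only for FA / colour-FA; the raw diagonal
entries Dxx/Dyy/Dzz feeding the ALPS index are reported as fitted.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .dwi_io import DWIVolume, GradientTable, validate_gradients

__all__ = [
    "DiffusionTensor",
    "TensorMaps",
    "TensorFitError",
    "fit_tensor",
    "fit_tensor_volume",
    "scalar_maps",
    "write_tensor_maps",
]

_COMP_NAMES = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")


class TensorFitError(ValueError):
    pass


@dataclass(frozen=True)
class DiffusionTensor:
    """Six unique tensor components (mm^2/s) plus the baseline signal S0."""

    dxx: float
    dyy: float
    dzz: float
    dxy: float
    dxz: float
    dyz: float
    s0: float

    @property
    def matrix(self) -> np.ndarray:
        return np.array(
            [
                [self.dxx, self.dxy, self.dxz],
                [self.dxy, self.dyy, self.dyz],
                [self.dxz, self.dyz, self.dzz],
            ]
        )

    @property
    def components(self) -> np.ndarray:
        return np.array([self.dxx, self.dyy, self.dzz, self.dxy, self.dxz, self.dyz])


@dataclass(frozen=True)
class TensorMaps:
    """Per-voxel tensor field with derived scalar maps on one grid.

    ``tensor`` has shape (X, Y, Z, 6) ordered Dxx, Dyy, Dzz, Dxy, Dxz, Dyz.
    ``evec1`` is the unit principal eigenvector where the mask is set;
    ``cfa`` is the FA-scaled absolute eigenvector (colour FA).
    """

    tensor: np.ndarray
    s0: np.ndarray
    fa: np.ndarray
    md: np.ndarray
    evec1: np.ndarray
    cfa: np.ndarray
    mask: np.ndarray
    affine: np.ndarray

    @property
    def dxx(self) -> np.ndarray:
        return self.tensor[..., 0]

    @property
    def dyy(self) -> np.ndarray:
        return self.tensor[..., 1]

    @property
    def dzz(self) -> np.ndarray:
        return self.tensor[..., 2]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        inv = np.linalg.inv(self.affine)
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ inv[:3, :3].T + inv[:3, 3]


def _collapse_b0(signals: np.ndarray, table: GradientTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Average all b=0 rows into one; return (signals, bvals-design, b0 mean)."""
    b0 = table.b0_mask
    dw = ~b0
    s_b0 = signals[..., b0].mean(axis=-1)
    return signals[..., dw], table.design_matrix()[dw], s_b0


def _check_design(design: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(design)
    if rank < 6:
        # name the unidentifiable tensor components via the null space
        _, s, vt = np.linalg.svd(design)
        null = vt[rank:]
        names = sorted(
            {_COMP_NAMES[int(j)] for row in null for j in np.flatnonzero(np.abs(row) > 1e-8)}
        )
        raise TensorFitError(
            f"rank-deficient gradient design (rank {rank} < 6); "
            f"unidentifiable components involve: {', '.join(names)}"
        )


def fit_tensor(signals: np.ndarray, table: GradientTable) -> DiffusionTensor:
    """Fit one voxel's diffusion tensor by ordinary least squares.

    Raises :class:`TensorFitError` on non-positive signals (background) or
    a rank-deficient direction set.
    """
    signals = np.asarray(signals, dtype=float).ravel()
    if len(signals) != len(table):
        raise TensorFitError("signal vector length does not match gradient table")
    if np.any(signals <= 0):
        raise TensorFitError("non-positive signal: voxel excluded as background")
    s_dw, design, s_b0 = _collapse_b0(signals, table)
    _check_design(design)
    # ln S = ln S0 - design @ d  ->  solve for [ln S0, d]
    a = np.column_stack([np.ones(len(s_dw) + 1), -np.vstack([np.zeros(6), design])])
    y = np.concatenate([[np.log(s_b0)], np.log(s_dw)])
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    d = coef[1:]
    return DiffusionTensor(*d, s0=float(np.exp(coef[0])))


def fit_tensor_volume(volume: DWIVolume, table: GradientTable) -> TensorMaps:
    """Vectorised OLS tensor fit over a whole 4-D volume.

    Background voxels (any non-positive signal) are excluded via the mask
    and carry zero tensors.
    """
    report = validate_gradients(table)
    if not report.ok:
        raise TensorFitError("invalid gradient table: " + "; ".join(report.violations))
    data = volume.data
    if data.shape[3] != len(table):
        raise TensorFitError("volume/table length mismatch")
    mask = np.all(data > 0, axis=3)
    s_dw, design, s_b0 = _collapse_b0(data, table)
    _check_design(design)

    shape = data.shape[:3]
    nvox = int(np.prod(shape))
    a = np.column_stack([np.ones(design.shape[0] + 1), -np.vstack([np.zeros(6), design])])
    y = np.empty((a.shape[0], nvox))
    flat_mask = mask.reshape(nvox)
    with np.errstate(divide="ignore", invalid="ignore"):
        y[0] = np.where(flat_mask, np.log(np.where(flat_mask, s_b0.reshape(nvox), 1.0)), 0.0)
        sd = s_dw.reshape(nvox, -1).T
        y[1:] = np.where(flat_mask[None, :], np.log(np.where(sd > 0, sd, 1.0)), 0.0)
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    tensor = coef[1:].T.reshape(*shape, 6)
    s0 = np.exp(coef[0]).reshape(shape)
    tensor[~mask] = 0.0
    s0[~mask] = 0.0
    return scalar_maps(tensor, s0=s0, mask=mask, affine=volume.affine)


def _fa_from_eigvals(ev: np.ndarray) -> np.ndarray:
    """Standard FA from (..., 3) eigenvalues; all-zero tensors give FA 0."""
    mean = ev.mean(axis=-1, keepdims=True)
    num = ((ev - mean) ** 2).sum(axis=-1)
    den = (ev**2).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.sqrt(1.5 * np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0))
    return np.clip(fa, 0.0, 1.0)


def scalar_maps(
    tensor: np.ndarray,
    s0: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    affine: np.ndarray | None = None,
) -> TensorMaps:
    """Derive FA, MD, principal eigenvector and colour FA from a tensor field.

    ``tensor`` is (..., 6) in the order Dxx, Dyy, Dzz, Dxy, Dxz, Dyz.
    Negative eigenvalues are clamped at zero for FA and colour FA only;
    MD and the stored diagonal remain as fitted.
    """
    tensor = np.asarray(tensor, dtype=float)
    if not np.isfinite(tensor).all():
        raise TensorFitError("tensor field contains non-finite values")
    shape = tensor.shape[:-1]
    if s0 is None:
        s0 = np.ones(shape)
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    if affine is None:
        affine = np.eye(4)

    dxx, dyy, dzz, dxy, dxz, dyz = np.moveaxis(tensor, -1, 0)
    mats = np.empty(shape + (3, 3))
    mats[..., 0, 0] = dxx
    mats[..., 1, 1] = dyy
    mats[..., 2, 2] = dzz
    mats[..., 0, 1] = mats[..., 1, 0] = dxy
    mats[..., 0, 2] = mats[..., 2, 0] = dxz
    mats[..., 1, 2] = mats[..., 2, 1] = dyz
    eigvals, eigvecs = np.linalg.eigh(mats)  # ascending
    md = tensor[..., :3].sum(axis=-1) / 3.0
    ev_clamped = np.clip(eigvals, 0.0, None)
    fa = _fa_from_eigvals(ev_clamped)
    evec1 = eigvecs[..., :, 2]  # principal direction
    # canonical sign for reproducibility: largest-|component| positive
    idx = np.argmax(np.abs(evec1), axis=-1, keepdims=True)
    sign = np.sign(np.take_along_axis(evec1, idx, axis=-1))
    sign[sign == 0] = 1.0
    evec1 = evec1 * sign
    cfa = fa[..., None] * np.abs(evec1)
    fa = np.where(mask, fa, 0.0)
    md = np.where(mask, md, 0.0)
    cfa = np.where(mask[..., None], cfa, 0.0)
    return TensorMaps(
        tensor=tensor, s0=np.asarray(s0, dtype=float), fa=fa, md=md,
        evec1=evec1, cfa=cfa, mask=np.asarray(mask, dtype=bool),
        affine=np.asarray(affine, dtype=float),
    )


def write_tensor_maps(maps: TensorMaps, out_dir: str | os.PathLike, prefix: str = "dti") -> dict[str, str]:
    """Write FA/MD/Dxx/Dyy/Dzz/colour-FA NIfTI maps plus a provenance sidecar."""
    os.makedirs(out_dir, exist_ok=True)
    arrays = {
        "FA": maps.fa, "MD": maps.md,
        "Dxx": maps.dxx, "Dyy": maps.dyy, "Dzz": maps.dzz,
        "cFA": maps.cfa,
    }
    paths: dict[str, str] = {}
    for name, arr in arrays.items():
        p = os.path.join(out_dir, f"{prefix}_{name}.nii.gz")
        nib.Nifti1Image(np.asarray(arr, dtype=np.float64), maps.affine).to_filename(p)
        paths[name] = p
    sidecar = os.path.join(out_dir, f"{prefix}_fit.json")
    with open(sidecar, "w") as fh:
        json.dump(
            {
                "estimator": "unweighted log-linear least squares",
                "b0_handling": "averaged before fitting",
                "eigenvalue_clamping": "FA/colour-FA only",
                "n_voxels_fitted": int(maps.mask.sum()),
            },
            fh,
            indent=2,
        )
    paths["sidecar"] = sidecar
    return paths
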