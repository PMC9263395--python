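"""ALPS index: fiber-orthogonal spherical ROIs over axis-diffusivity maps.

At the level of the lateral-ventricle body the perivascular spaces run
right–left (the world x-axis), perpendicular both to the projection
fibers (z-dominant) and the association fibers (y-dominant). Diffusivity
along x in those two fiber regions therefore carries the perivascular
component, while Dy (projection) and Dz (association) are purely
fiber-perpendicular. The index is

    ALPS = mean(Dxproj, Dxassoc) / mean(Dyproj, Dzassoc)

ROI centers are given in world mm (placement on the colour-FA map is a
judgement call; automation only suggests). Spheres are 5 mm diameter by
default and membership is by voxel-center distance <= radius, ties
included. ROI means are unweighted voxel averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .tensor import TensorMaps

__all__ = [
    "AlpsRoi",
    "AlpsMeasurement",
    "OrientationQC",
    "AlpsError",
    "roi_mask",
    "compute_alps",
    "validate_fiber_orientation",
    "suggest_roi_center",
]

FiberClass = Literal["projection", "association"]

#: expected dominant axis index per fiber class (x=0, y=1, z=2)
DOMINANT_AXIS = {"projection": 2, "association": 1}


class AlpsError(ValueError):
    pass


@dataclass(frozen=True)
class AlpsRoi:
    """Spherical region of interest in world coordinates."""

    center_mm: tuple[float, float, float]
    fiber_class: FiberClass
    diameter_mm: float = 5.0

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise AlpsError("ROI diameter must be positive")
        if self.fiber_class not in DOMINANT_AXIS:
            raise AlpsError(f"unknown fiber class {self.fiber_class!r}")


@dataclass(frozen=True)
class OrientationQC:
    """Fraction of ROI voxels whose tensor looks like the expected fiber."""

    fraction_ok: float
    passed: bool
    n_voxels: int


@dataclass(frozen=True)
class AlpsMeasurement:
    dx_proj: float
    dy_proj: float
    dx_assoc: float
    dz_assoc: float
    alps_index: float
    n_voxels_proj: int
    n_voxels_assoc: int
    qc: dict = field(default_factory=dict)


def roi_mask(roi: AlpsRoi, maps_or_grid) -> np.ndarray:
    """Boolean voxel mask of the sphere on the map grid.

    ``maps_or_grid`` is a :class:`TensorMaps` (or any object with
    ``affine`` and a ``fa``-shaped array). Raises :class:`AlpsError` on an
    empty mask (center outside the image or diameter below voxel size).
    """
    affine = np.asarray(maps_or_grid.affine, dtype=float)
    shape = maps_or_grid.fa.shape if hasattr(maps_or_grid, "fa") else maps_or_grid.shape
    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    ijk = np.stack([ii, jj, kk], axis=-1).astype(float)
    xyz = ijk @ affine[:3, :3].T + affine[:3, 3]
    dist = np.linalg.norm(xyz - np.asarray(roi.center_mm), axis=-1)
    mask = dist <= roi.diameter_mm / 2.0
    if not mask.any():
        raise AlpsError(
            f"ROI at {roi.center_mm} mm (diameter {roi.diameter_mm} mm) "
            "contains no voxel centers"
        )
    return mask


def compute_alps(
    maps: TensorMaps,
    roi_proj: AlpsRoi,
    roi_assoc: AlpsRoi,
    min_fa: float = 0.2,
    min_fraction: float = 0.5,
) -> AlpsMeasurement:
    """ROI-mean axis diffusivities and the ALPS index, with orientation QC.

    Raises :class:`AlpsError` when the fiber-perpendicular denominator is
    non-positive (non-physical diffusivities).
    """
    if roi_proj.fiber_class != "projection" or roi_assoc.fiber_class != "association":
        raise AlpsError("compute_alps expects (projection, association) ROIs")
    m_proj = roi_mask(roi_proj, maps)
    m_assoc = roi_mask(roi_assoc, maps)
    dx_proj = float(maps.dxx[m_proj].mean())
    dy_proj = float(maps.dyy[m_proj].mean())
    dx_assoc = float(maps.dxx[m_assoc].mean())
    dz_assoc = float(maps.dzz[m_assoc].mean())
    denom = (dy_proj + dz_assoc) / 2.0
    if denom <= 0:
        raise AlpsError(
            f"non-positive perpendicular diffusivity mean ({denom:g} mm^2/s)"
        )
    index = ((dx_proj + dx_assoc) / 2.0) / denom
    qc = {
        "projection": validate_fiber_orientation(maps, roi_proj, min_fa, min_fraction),
        "association": validate_fiber_orientation(maps, roi_assoc, min_fa, min_fraction),
    }
    return AlpsMeasurement(
        dx_proj=dx_proj,
        dy_proj=dy_proj,
        dx_assoc=dx_assoc,
        dz_assoc=dz_assoc,
        alps_index=index,
        n_voxels_proj=int(m_proj.sum()),
        n_voxels_assoc=int(m_assoc.sum()),
        qc=qc,
    )


def validate_fiber_orientation(
    maps: TensorMaps,
    roi: AlpsRoi,
    min_fa: float = 0.2,
    min_fraction: float = 0.5,
) -> OrientationQC:
    """QC-only check that the ROI sits in the expected fiber population.

    A voxel qualifies when FA >= ``min_fa`` and the principal eigenvector
    is dominant on the fiber class's expected axis (projection: z,
    association: y). The ROI passes when at least ``min_fraction`` of its
    voxels qualify.
    """
    mask = roi_mask(roi, maps)
    axis = DOMINANT_AXIS[roi.fiber_class]
    fa = maps.fa[mask]
    v = np.abs(maps.evec1[mask])
    dominant = np.argmax(v, axis=-1) == axis
    ok = (fa >= min_fa) & dominant
    fraction = float(ok.mean())
    return OrientationQC(
        fraction_ok=fraction,
        passed=fraction >= min_fraction,
        n_voxels=int(mask.sum()),
    )


def suggest_roi_center(
    maps: TensorMaps,
    fiber_class: FiberClass,
    k_slice: int | None = None,
    diameter_mm: float = 5.0,
    min_fa: float = 0.2,
) -> tuple[float, float, float]:
    """Suggest a world-mm ROI center by maximising the orientation-QC score.

    Scans voxel centers (optionally restricted to one axial slice) and
    returns the center whose sphere has the highest fraction of voxels
    with the expected dominant axis. Manual coordinates remain
    authoritative; this is a placement aid only.
    """
    axis = DOMINANT_AXIS[fiber_class]
    candidate = (maps.fa >= min_fa) & (np.argmax(np.abs(maps.evec1), axis=-1) == axis)
    if k_slice is not None:
        keep = np.zeros_like(candidate)
        keep[:, :, k_slice] = candidate[:, :, k_slice]
        candidate = keep
    idx = np.argwhere(candidate)
    if len(idx) == 0:
        raise AlpsError(f"no voxels match the {fiber_class} orientation criteria")
    best_score, best_center = -1.0, None
    for ijk in idx:
        center = tuple(maps.voxel_to_world(ijk.astype(float)))
        roi = AlpsRoi(center_mm=center, fiber_class=fiber_class, diameter_mm=diameter_mm)
        try:
            qc = validate_fiber_orientation(maps, roi, min_fa=min_fa, min_fraction=0.0)
        except AlpsError:
            continue
        if qc.fraction_ok > best_score:
            best_score, best_center = qc.fraction_ok, center
    if best_center is None:
        raise AlpsError("no valid ROI placement found")
    return best_center
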