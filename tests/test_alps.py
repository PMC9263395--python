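import numpy as np
import pytest

from _oracles import sphere_lattice_count
from dtialps.alps import (
    AlpsError,
    AlpsRoi,
    compute_alps,
    roi_mask,
    suggest_roi_center,
    validate_fiber_orientation,
)
from dtialps.synthetic import PhantomSpec, make_phantom
from dtialps.tensor import fit_tensor_volume, scalar_maps


def _uniform_maps(shape=(20, 20, 20), affine=None, dxx=0.8e-3, dyy=0.8e-3, dzz=0.8e-3):
    tensor = np.zeros(shape + (6,))
    tensor[..., 0] = dxx
    tensor[..., 1] = dyy
    tensor[..., 2] = dzz
    return scalar_maps(tensor, affine=affine)


def test_sphere_mask_matches_lattice_count():
    """A 5 mm ROI on a 1 mm isotropic grid centered on a voxel center
    contains exactly the 81 lattice points within radius 2.5."""
    maps = _uniform_maps()
    roi = AlpsRoi(center_mm=(10.0, 10.0, 10.0), fiber_class="projection")
    mask = roi_mask(roi, maps)
    assert mask.sum() == 81
    assert mask.sum() == sphere_lattice_count(2.5, (1.0, 1.0, 1.0))


def test_mask_translates_with_center():
    maps = _uniform_maps()
    m1 = roi_mask(AlpsRoi((9.0, 10.0, 10.0), "projection"), maps)
    m2 = roi_mask(AlpsRoi((10.0, 10.0, 10.0), "projection"), maps)
    np.testing.assert_array_equal(np.roll(m1, 1, axis=0), m2)


def test_tiny_roi_on_thick_slices_is_empty():
    affine = np.diag([1.75, 1.75, 2.4, 1.0])
    maps = _uniform_maps(shape=(10, 10, 10), affine=affine)
    roi = AlpsRoi(center_mm=(5.0, 5.0, 1.2 + 1e-3), fiber_class="projection",
                  diameter_mm=0.1)
    with pytest.raises(AlpsError, match="no voxel"):
        roi_mask(roi, maps)


def test_alps_arithmetic_identity():
    """All four ROI means equal -> index 1; the printed-formula example
    (1.2, 1.0, 0.6, 0.5)e-3 -> index 2."""
    maps = _uniform_maps()
    proj = AlpsRoi((5.0, 10.0, 10.0), "projection")
    assoc = AlpsRoi((15.0, 10.0, 10.0), "association")
    m = compute_alps(maps, proj, assoc)
    assert m.alps_index == pytest.approx(1.0, abs=1e-15)

    tensor = np.zeros((20, 20, 20, 6))
    tensor[:10, ..., 0] = 1.2e-3   # Dxproj
    tensor[:10, ..., 1] = 0.6e-3   # Dyproj
    tensor[10:, ..., 0] = 1.0e-3   # Dxassoc
    tensor[10:, ..., 2] = 0.5e-3   # Dzassoc
    maps2 = scalar_maps(tensor)
    m2 = compute_alps(maps2, proj, assoc)
    assert m2.alps_index == pytest.approx(2.0, rel=1e-12)
    # the stored fields recompute the index exactly
    recomputed = ((m2.dx_proj + m2.dx_assoc) / 2) / ((m2.dy_proj + m2.dz_assoc) / 2)
    assert abs(recomputed - m2.alps_index) <= 1e-12


def test_nonpositive_denominator_is_an_error():
    maps = _uniform_maps(dyy=-0.8e-3, dzz=-0.8e-3)
    with pytest.raises(AlpsError, match="perpendicular"):
        compute_alps(
            maps,
            AlpsRoi((5.0, 10.0, 10.0), "projection"),
            AlpsRoi((15.0, 10.0, 10.0), "association"),
        )


@pytest.mark.parametrize("scale", [0.5, 2.0, 1e3])
def test_index_scale_invariance(canonical_phantom, scale):
    """Scaling every diffusivity map by c > 0 leaves the index unchanged."""
    spec, (volume, table, truth, true_alps) = canonical_phantom
    centers = spec.roi_centers_mm()
    proj = AlpsRoi(centers["projection"], "projection")
    assoc = AlpsRoi(centers["association"], "association")
    base = compute_alps(truth, proj, assoc).alps_index
    scaled = scalar_maps(truth.tensor * scale, affine=truth.affine)
    assert compute_alps(scaled, proj, assoc).alps_index == pytest.approx(base, rel=1e-12)


def test_end_to_end_phantom_recovers_analytic_index(canonical_phantom):
    """fit -> maps -> ROIs -> index reproduces the analytic phantom value
    1.5 = mean(0.6, 0.6) / mean(0.4, 0.4) within 1e-6."""
    spec, (volume, table, truth, true_alps) = canonical_phantom
    assert true_alps == pytest.approx(1.5, abs=1e-15)
    maps = fit_tensor_volume(volume, table)
    centers = spec.roi_centers_mm()
    m = compute_alps(
        maps,
        AlpsRoi(centers["projection"], "projection"),
        AlpsRoi(centers["association"], "association"),
    )
    assert m.alps_index == pytest.approx(true_alps, abs=1e-6)
    assert m.qc["projection"].passed and m.qc["association"].passed


def test_orientation_qc_pass_and_fail(canonical_phantom):
    """Projection ROI in the z-dominant slab passes; the same ROI dropped
    into the isotropic ventricle fails on FA."""
    spec, (volume, table, truth, _) = canonical_phantom
    centers = spec.roi_centers_mm()
    ok = validate_fiber_orientation(truth, AlpsRoi(centers["projection"], "projection"))
    assert ok.passed and ok.fraction_ok == 1.0
    mid = tuple(np.array(spec.shape) / 2 * np.array(spec.voxel_size_mm))
    bad = validate_fiber_orientation(truth, AlpsRoi(mid, "projection"))
    assert not bad.passed and bad.fraction_ok == 0.0


def test_orientation_qc_boundary_fraction():
    """An ROI straddling a fiber/isotropic boundary with 40% qualifying
    voxels fails at min_fraction 0.5; the 40% is a direct count."""
    tensor = np.zeros((20, 20, 20, 6))
    tensor[..., :3] = 0.9e-3                      # isotropic everywhere
    tensor[:9, :, :, :3] = (0.3e-3, 0.3e-3, 1.5e-3)  # z-dominant fibers
    maps = scalar_maps(tensor)
    roi = AlpsRoi((9.0, 10.0, 10.0), "projection")
    mask = roi_mask(roi, maps)
    qualifying = (maps.fa[mask] >= 0.2) & (
        np.argmax(np.abs(maps.evec1), axis=-1)[mask] == 2
    )
    expected_fraction = qualifying.mean()
    qc = validate_fiber_orientation(maps, roi, min_fa=0.2, min_fraction=0.5)
    assert qc.fraction_ok == pytest.approx(expected_fraction)
    assert expected_fraction < 0.5
    assert not qc.passed


def test_suggest_center_lands_in_fiber_slab(canonical_phantom):
    spec, (volume, table, truth, _) = canonical_phantom
    center = suggest_roi_center(truth, "association", k_slice=spec.shape[2] // 2)
    roi = AlpsRoi(center, "association")
    assert validate_fiber_orientation(truth, roi).passed
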