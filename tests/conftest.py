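import numpy as np
import pytest

from dtialps.directions import protocol_gradient_arrays
from dtialps.dwi_io import GradientTable
from dtialps.synthetic import PhantomSpec, make_phantom


@pytest.fixture(scope="session")
def protocol_table() -> GradientTable:
    bvals, bvecs = protocol_gradient_arrays()
    return GradientTable(bvals=bvals, bvecs=bvecs)


@pytest.fixture(scope="session")
def canonical_phantom():
    """Noiseless phantom with projection diag(0.6, 0.4, 1.4)e-3 and
    association diag(0.6, 1.4, 0.4)e-3 (delta folded into the x axis);
    analytic ALPS index 1.5."""
    spec = PhantomSpec(
        projection_eigvals=(0.4e-3, 0.4e-3, 1.4e-3),
        association_eigvals=(0.4e-3, 1.4e-3, 0.4e-3),
        delta=0.2e-3,
    )
    return spec, make_phantom(spec)


def random_pd_tensor(rng: np.random.Generator, scale: float = 1e-3) -> np.ndarray:
    """Random positive-definite tensor with diffusivities on the tissue
    scale (~1e-3 mm^2/s)."""
    a = rng.standard_normal((3, 3))
    d = a @ a.T
    d += 3 * np.eye(3) * 0.05
    return d * scale / 3.0


def forward_signal(d: np.ndarray, table: GradientTable, s0: float = 1000.0) -> np.ndarray:
    """Noiseless DWI signal from the monoexponential tensor model."""
    g = table.bvecs
    att = np.einsum("ni,ij,nj->n", g, d, g) * table.bvals
    return s0 * np.exp(-att)
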