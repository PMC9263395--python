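"""Fixed diffusion-gradient direction set.

A 20-direction unit-vector scheme obtained once by minimising the
antipodally symmetric Coulomb (electrostatic-repulsion) energy on the
sphere and frozen here verbatim so that every simulation is reproducible.
The design matrix of the corresponding tensor fit has condition number
~1.59, i.e. the scheme is nearly rotation-uniform.
"""

from __future__ import annotations

import numpy as np

#: 20 unit vectors, z >= 0 hemisphere, antipodally symmetrised energy.
DIRECTIONS_20 = np.array(
    [
        [0.010407931941077, 0.608855751455416, 0.793212675688160],
        [-0.419860687925523, -0.697189565967135, 0.581071176226514],
        [0.873579187400863, 0.388936335831928, 0.292554148850569],
        [0.890713983888672, -0.126665208879588, 0.436559874203597],
        [0.471690457041673, 0.786969578603641, 0.397727287331690],
        [-0.876938895392136, 0.466134049171962, 0.117035131268225],
        [0.066543575282961, 0.114327748367451, 0.991211944309485],
        [0.667811743735748, -0.613432152259439, 0.421578544879804],
        [-0.579601061172254, 0.625765838249557, 0.521995905700252],
        [0.440252140766133, -0.298992362419135, 0.846629564665599],
        [-0.749965303526777, -0.203321442028225, 0.629454076734397],
        [-0.501524066919833, 0.211681845209288, 0.838847069917385],
        [-0.086248549399757, 0.924486995595619, 0.371328672069668],
        [-0.982036997924998, -0.046247644769225, 0.182933020692703],
        [0.424486529780277, -0.904385672979874, 0.043563063985888],
        [-0.186766508708511, -0.351587363159349, 0.917335596873625],
        [-0.743757699519570, -0.649726292487652, 0.157099424746265],
        [0.563392426821987, 0.301487281875685, 0.769216739460890],
        [0.148663968608573, -0.785309705066786, 0.600988927989083],
        [-0.199617732820316, -0.971761736091019, 0.125824834643427],
    ]
)


def protocol_gradient_arrays(b_value: float = 1000.0) -> tuple[np.ndarray, np.ndarray]:
    """b-values and b-vectors for the acquisition protocol emulated here:
    one b=0 volume followed by 20 diffusion-weighted directions at
    ``b_value`` s/mm^2."""
    bvals = np.concatenate([[0.0], np.full(len(DIRECTIONS_20), b_value)])
    bvecs = np.vstack([np.zeros(3), DIRECTIONS_20])
    return bvals, bvecs
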