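"""Ground-truth generators: DWI phantoms and clinical cohorts.

The study data are not shareable, so validation runs on synthetic inputs
with known ground truth.

Phantoms
--------
A rectangular grid holds four regions: a projection-fiber slab whose
tensors are z-dominant, an association-fiber slab (y-dominant), an
isotropic CSF-like "ventricle" block, and isotropic background. A
perivascular x-axis diffusivity increment ``delta`` is added in both
fiber regions, so the analytic ALPS index of the specification is

    mean(lambda_x_proj + delta, lambda_x_assoc + delta)
    -----------------------------------------------------
    mean(lambda_y_proj, lambda_z_assoc)

computable without any simulation. Signals follow the monoexponential
DWI equation S = S0 exp(-b g^T D g) over one b=0 volume plus 20
directions at b = 1000 s/mm^2 (the frozen scheme in ``directions``).
Optional Rician noise is the magnitude of a complex Gaussian
perturbation with sigma = S0 / SNR.

Cohorts
-------
Subject records with the observed case–control structure: per-group ALPS
index distributions N(1.054, 0.142) / N(0.958, 0.088), WML-sum
categories 3–6 with the observed frequencies, negative-binomial CMB and
lacune counts matched to the observed mean/SD, PVS grades tuned to the
observed moderate-to-severe prevalence, and cognitive scores linearly
coupled to the ALPS index, WML load and education (coefficients on the
scale of the adjusted regression tables, e.g. ~16 MoCA points per unit
ALPS). The CN/CI group label is NOT drawn: it is assigned by applying
the education-adjusted MoCA cutoff to the generated MoCA, so the
classification rule itself is exercised; the generating (latent) group
is kept in a separate column.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .clinical import classify_cognition, is_moderate_severe_pvs
from .directions import protocol_gradient_arrays
from .dwi_io import DWIVolume, GradientTable
from .tensor import TensorMaps, scalar_maps

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "GroupParams",
    "SyntheticError",
    "make_phantom",
    "make_cohort",
    "null_alps_spec",
    "TABLE1_COHORT",
]


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# phantom

@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, per-region tensors and noise model of a DWI phantom.

    Eigenvalues are in mm^2/s; ``voxel_size_mm`` follows the emulated
    protocol (in-plane 1.75 mm, slice thickness 2.4 mm).
    """

    shape: tuple[int, int, int] = (32, 32, 12)
    voxel_size_mm: tuple[float, float, float] = (1.75, 1.75, 2.4)
    # (lambda_x, lambda_y, lambda_z) before the perivascular increment
    projection_eigvals: tuple[float, float, float] = (0.4e-3, 0.4e-3, 1.4e-3)
    association_eigvals: tuple[float, float, float] = (0.4e-3, 1.4e-3, 0.4e-3)
    ventricle_diffusivity: float = 3.0e-3
    background_diffusivity: float = 0.8e-3
    delta: float = 0.2e-3          # perivascular x-axis increment
    s0: float = 1000.0
    b_value: float = 1000.0
    snr: float | None = None       # None = noiseless; else Rician, S0/sigma
    seed: int = 0

    def __post_init__(self):
        for lam in (*self.projection_eigvals, *self.association_eigvals):
            if lam < 0:
                raise SyntheticError("negative eigenvalue in phantom spec")
        if self.projection_eigvals[0] + self.delta < 0 or \
           self.association_eigvals[0] + self.delta < 0:
            raise SyntheticError("delta drives an x-axis eigenvalue negative")
        if min(self.shape) < 6:
            raise SyntheticError("phantom grid too small for its regions")

    # region slabs in voxel indices (x-axis split: projection | ventricle |
    # association), mimicking tissue lateral to the ventricle body
    def region_map(self) -> np.ndarray:
        """0 background, 1 projection, 2 association, 3 ventricle."""
        nx, ny, nz = self.shape
        regions = np.zeros(self.shape, dtype=np.int8)
        x3 = nx // 4
        margin = max(nx // 8, 2)
        ylo, yhi = margin, ny - margin
        regions[margin:x3 + margin, ylo:yhi, :] = 1
        regions[nx - x3 - margin:nx - margin, ylo:yhi, :] = 2
        qx, qy = nx // 8, ny // 8
        regions[nx // 2 - qx:nx // 2 + qx, ny // 2 - qy:ny // 2 + qy, :] = 3
        return regions

    def region_tensors(self) -> dict[int, np.ndarray]:
        """Diagonal tensor (Dxx, Dyy, Dzz) per region label."""
        px, py, pz = self.projection_eigvals
        ax, ay, az = self.association_eigvals
        return {
            0: np.array([self.background_diffusivity] * 3),
            1: np.array([px + self.delta, py, pz]),
            2: np.array([ax + self.delta, ay, az]),
            3: np.array([self.ventricle_diffusivity] * 3),
        }

    @property
    def true_alps(self) -> float:
        """Analytic ALPS index of the specification, no simulation needed."""
        px, py, _ = self.projection_eigvals
        ax, _, az = self.association_eigvals
        return ((px + self.delta) + (ax + self.delta)) / (py + az)

    @property
    def affine(self) -> np.ndarray:
        aff = np.diag([*self.voxel_size_mm, 1.0])
        return aff

    def roi_centers_mm(self) -> dict[str, tuple[float, float, float]]:
        """World-mm centers of the two fiber slabs (for ROI placement)."""
        regions = self.region_map()
        out = {}
        for name, label in (("projection", 1), ("association", 2)):
            idx = np.argwhere(regions == label).mean(axis=0)
            out[name] = tuple(idx * np.asarray(self.voxel_size_mm))
        return out


def make_phantom(spec: PhantomSpec) -> tuple[DWIVolume, GradientTable, TensorMaps, float]:
    """Simulate a phantom DWI acquisition from ``spec``.

    Returns the 4-D volume, its gradient table, the ground-truth tensor
    maps, and the analytic true ALPS index. Same spec + seed gives
    byte-identical output.
    """
    bvals, bvecs = protocol_gradient_arrays(spec.b_value)
    table = GradientTable(bvals=bvals, bvecs=bvecs)
    regions = spec.region_map()
    tensors = spec.region_tensors()

    diag = np.zeros(spec.shape + (3,))
    for label, d in tensors.items():
        diag[regions == label] = d
    # b g^T D g for diagonal D: sum_i b * g_i^2 * D_ii
    g2 = table.bvecs**2                                    # (n, 3)
    att = np.einsum("...i,ni->...n", diag, table.bvals[:, None] * g2)
    signal = spec.s0 * np.exp(-att)
    if spec.snr is not None:
        if spec.snr <= 0:
            raise SyntheticError("SNR must be positive")
        rng = np.random.default_rng(spec.seed)
        sigma = spec.s0 / spec.snr
        noise_r = rng.normal(0.0, sigma, signal.shape)
        noise_i = rng.normal(0.0, sigma, signal.shape)
        signal = np.sqrt((signal + noise_r) ** 2 + noise_i**2)
    volume = DWIVolume(data=signal, affine=spec.affine)

    tensor6 = np.zeros(spec.shape + (6,))
    tensor6[..., :3] = diag
    truth = scalar_maps(tensor6, s0=np.full(spec.shape, spec.s0), affine=spec.affine)
    return volume, table, truth, spec.true_alps


# ---------------------------------------------------------------------------
# cohort

@dataclass(frozen=True)
class GroupParams:
    """Per-group marginal distributions of a synthetic CSVD cohort."""

    n: int
    alps_mean: float
    alps_sd: float
    age_mean: float
    age_sd: float
    edu_mean: float
    edu_sd: float
    male_p: float
    hypertension_p: float
    diabetes_p: float
    smoking_p: float
    alcohol_p: float
    wml_probs: tuple[float, float, float, float]  # P(sum = 3, 4, 5, 6)
    lacune_mean: float
    lacune_sd: float
    cmb_mean: float
    cmb_sd: float
    pvs_ms_p: float               # moderate-to-severe PVS prevalence
    moca_base: float              # group-level MoCA intercept

    def __post_init__(self):
        probs = np.asarray(self.wml_probs)
        if np.any(probs < 0) or abs(probs.sum() - 1.0) > 1e-9:
            raise SyntheticError("WML category probabilities must sum to 1")
        for p in (self.male_p, self.hypertension_p, self.diabetes_p,
                  self.smoking_p, self.alcohol_p, self.pvs_ms_p):
            if not 0 <= p <= 1:
                raise SyntheticError("probabilities must lie in [0, 1]")
        if self.alps_sd < 0 or self.age_sd < 0 or self.edu_sd < 0:
            raise SyntheticError("negative SD in cohort spec")


@dataclass(frozen=True)
class CohortSpec:
    """Cohort generator settings; defaults reproduce the observed case-
    control structure (see ``TABLE1_COHORT``)."""

    cn: GroupParams
    ci: GroupParams
    # linear couplings of every cognitive score: per unit ALPS, per
    # education year, per WML grade; residual SD; group mean offsets are
    # the observed group means
    score_models: dict = field(default_factory=dict)
    # MoCA coupling: (b_alps, b_edu, b_wml, resid_sd)
    moca_model: tuple[float, float, float, float] = (16.094, 0.683, -1.577, 2.0)
    risk_missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.risk_missing_rate < 1:
            raise SyntheticError("missingness rate must be in [0, 1)")
        if self.moca_model[3] < 0:
            raise SyntheticError("negative residual SD in MoCA model")


# (b_alps, b_edu, b_wml, resid_sd, mean_cn, mean_ci) per score; coefficient
# magnitudes follow the adjusted regression tables, group means the observed
# cohort summaries
_SCORE_MODELS: dict[str, tuple[float, float, float, float, float, float]] = {
    "tmt_b_a": (-252.0, -7.16, 11.5, 60.0, 151.0, 206.8),
    "avlt_sum": (25.9, 0.60, -2.36, 5.0, 21.4, 10.7),
    "sdmt": (43.7, 1.20, -2.04, 5.5, 31.5, 16.8),
    "vft": (27.1, 0.67, -2.45, 6.5, 41.2, 31.8),
    "bnt": (0.98, 0.58, -0.96, 2.0, 20.5, 18.3),
    "rcft_c": (5.15, 0.58, -0.85, 2.5, 30.7, 23.5),
}

_CN = GroupParams(
    n=50, alps_mean=1.054, alps_sd=0.142,
    age_mean=64.45, age_sd=7.768, edu_mean=10.21, edu_sd=4.247,
    male_p=0.64, hypertension_p=0.878, diabetes_p=0.1715,
    smoking_p=0.15, alcohol_p=0.10,
    wml_probs=(0.18, 0.32, 0.28, 0.22),
    lacune_mean=2.36, lacune_sd=2.593, cmb_mean=8.80, cmb_sd=13.178,
    pvs_ms_p=0.884, moca_base=26.5,
)
_CI = GroupParams(
    n=83, alps_mean=0.958, alps_sd=0.088,
    age_mean=66.18, age_sd=7.575, edu_mean=8.78, edu_sd=4.749,
    male_p=0.639, hypertension_p=0.929, diabetes_p=0.25,
    smoking_p=0.232, alcohol_p=0.14,
    wml_probs=(7 / 82, 11 / 82, 11 / 82, 53 / 82),
    lacune_mean=3.27, lacune_sd=4.067, cmb_mean=20.14, cmb_sd=26.623,
    pvs_ms_p=0.863, moca_base=15.5,
)

#: default parameterisation matching the observed cohort structure
TABLE1_COHORT = CohortSpec(cn=_CN, ci=_CI, score_models=dict(_SCORE_MODELS))


def _neg_binomial(rng: np.random.Generator, mean: float, sd: float, size: int) -> np.ndarray:
    """Counts with the requested mean/SD; Poisson if under-dispersed."""
    var = sd**2
    if var <= mean:
        return rng.poisson(mean, size)
    r = mean**2 / (var - mean)
    p = r / (r + mean)
    return rng.negative_binomial(r, p, size)


def _pvs_grades(rng: np.random.Generator, ms_p: float, size: int) -> tuple[np.ndarray, np.ndarray]:
    """Region grades 0-4 with P(either > 2) = ms_p, regions independent."""
    q = 1.0 - np.sqrt(1.0 - ms_p)  # per-region P(grade > 2)
    base = np.array([0.05, 0.15, 0.20, 0.0, 0.0])
    low = base[:3] / base[:3].sum() * (1 - q)
    probs = np.array([*low, 0.62 * q, 0.38 * q])
    cso = rng.choice(5, size=size, p=probs)
    bg = rng.choice(5, size=size, p=probs)
    return cso, bg


def _wml_decompose(rng: np.random.Generator, sums: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Uniform split of a summed grade into (periventricular, deep), each
    0-3 with at least one region >= 2 (the inclusion criterion)."""
    pv = np.empty_like(sums)
    options = {
        s: [(a, s - a) for a in range(4) if 0 <= s - a <= 3 and max(a, s - a) >= 2]
        for s in range(3, 7)
    }
    for i, s in enumerate(sums):
        pv[i] = options[int(s)][rng.integers(len(options[int(s)]))][0]
    return pv, sums - pv


def make_cohort(spec: CohortSpec = TABLE1_COHORT, seed: int | None = None) -> pd.DataFrame:
    """Generate one synthetic cohort as a tidy clinical table.

    The returned frame follows the clinical column dictionary plus a
    ``latent_group`` column recording the generating group; ``group`` is
    assigned by the education-adjusted MoCA cutoff. ``seed`` overrides
    ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames = []
    for latent, g in (("CN", spec.cn), ("CI", spec.ci)):
        n = g.n
        alps = rng.normal(g.alps_mean, g.alps_sd, n)
        age = np.clip(rng.normal(g.age_mean, g.age_sd, n), 50, 80)
        edu = np.clip(np.round(rng.normal(g.edu_mean, g.edu_sd, n)), 0, 22)
        wml_sum = rng.choice([3, 4, 5, 6], size=n, p=g.wml_probs)
        wml_pv, wml_deep = _wml_decompose(rng, wml_sum)
        lacunes = _neg_binomial(rng, g.lacune_mean, g.lacune_sd, n)
        cmbs = _neg_binomial(rng, g.cmb_mean, g.cmb_sd, n)
        pvs_cso, pvs_bg = _pvs_grades(rng, g.pvs_ms_p, n)

        b_alps, b_edu, b_wml, sd_moca = spec.moca_model
        lin = (b_alps * (alps - g.alps_mean)
               + b_edu * (edu - g.edu_mean)
               + b_wml * (wml_sum - wml_sum.mean()))
        moca = np.clip(np.round(g.moca_base + lin + rng.normal(0, sd_moca, n)), 0, 30)

        scores = {}
        models = spec.score_models or _SCORE_MODELS
        for name, (ba, be, bw, sd, mean_cn, mean_ci) in models.items():
            base = mean_cn if latent == "CN" else mean_ci
            val = (base
                   + ba * (alps - g.alps_mean)
                   + be * (edu - g.edu_mean)
                   + bw * (wml_sum - wml_sum.mean())
                   + rng.normal(0, sd, n))
            scores[name] = np.round(np.clip(val, 0, None), 1)

        def _risk(p):
            v = rng.binomial(1, p, n).astype(float)
            v[rng.random(n) < spec.risk_missing_rate] = np.nan
            return v

        frames.append(pd.DataFrame({
            "latent_group": latent,
            "age": np.round(age, 1),
            "male": rng.binomial(1, g.male_p, n),
            "education": edu,
            "hypertension": _risk(g.hypertension_p),
            "diabetes": _risk(g.diabetes_p),
            "smoking": _risk(g.smoking_p),
            "alcohol": _risk(g.alcohol_p),
            "wml_pv": wml_pv,
            "wml_deep": wml_deep,
            "wml_sum": wml_sum,
            "lacunes": lacunes,
            "cmbs": cmbs,
            "pvs_cso": pvs_cso,
            "pvs_bg": pvs_bg,
            "alps_index": alps,
            "moca": moca.astype(int),
            **scores,
        }))
    df = pd.concat(frames, ignore_index=True)
    df.insert(0, "subject_id", [f"S{i:04d}" for i in range(len(df))])
    df["pvs_moderate_severe"] = [
        int(is_moderate_severe_pvs(c, b)) for c, b in zip(df.pvs_cso, df.pvs_bg)
    ]
    df["group"] = [
        classify_cognition(int(m), e) for m, e in zip(df.moca, df.education)
    ]
    return df


def null_alps_spec(base: CohortSpec = TABLE1_COHORT) -> CohortSpec:
    """Variant with no ALPS effect anywhere: both groups share one ALPS
    distribution and every ALPS coupling is zero. Used for type-I-error
    style simulations."""
    cn = replace(base.cn, alps_mean=1.0, alps_sd=0.12)
    ci = replace(base.ci, alps_mean=1.0, alps_sd=0.12)
    models = {
        k: (0.0, *v[1:]) for k, v in (base.score_models or _SCORE_MODELS).items()
    }
    moca = (0.0, *base.moca_model[1:])
    return replace(base, cn=cn, ci=ci, score_models=models, moca_model=moca)
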