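"""Independent oracles used by the tests and the acceptance script.

Each oracle deliberately avoids the code path it checks: brute-force
pairwise counting for the AUC, full enumeration for the exact
Mann–Whitney null, direct negative-log-likelihood minimisation
(scipy.optimize, not statsmodels) plus subset enumeration for the
stepwise selection, and the closed-form FA formula on eigenvalues.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy import optimize
from scipy.stats import chi2


def pairwise_auc(scores, labels) -> float:
    """AUC as the proportion of positive–negative pairs correctly ordered,
    ties counted 1/2, by brute force over all pairs."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = s[y == 1]
    neg = s[y == 0]
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / diff.size)


def mann_whitney_u_brute(x, y) -> float:
    """Midrank U statistic for x vs y by direct pair counting."""
    x = np.asarray(x, dtype=float)[:, None]
    y = np.asarray(y, dtype=float)[None, :]
    return float(np.sum(x > y) + 0.5 * np.sum(x == y))


def mann_whitney_exact_p(x, y) -> float:
    """Two-sided exact Mann–Whitney p-value by full enumeration of all
    C(n1+n2, n1) group assignments (untied data only)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if len(np.unique(pooled)) < len(pooled):
        raise ValueError("enumeration oracle requires untied data")
    n1 = len(x)
    u_obs = mann_whitney_u_brute(x, y)
    mu = n1 * len(y) / 2.0
    dev = abs(u_obs - mu)
    count = 0
    total = 0
    idx = np.arange(len(pooled))
    for grp in combinations(idx, n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(grp)] = True
        u = mann_whitney_u_brute(pooled[mask], pooled[~mask])
        total += 1
        # symmetric null: two-sided p = P(|U - mu| >= |u_obs - mu|)
        if abs(u - mu) >= dev - 1e-12:
            count += 1
    return count / total


# ---------------------------------------------------------------------------
# logistic regression via direct NLL minimisation (independent of statsmodels)

def logistic_llf_scipy(x: np.ndarray, y: np.ndarray) -> float:
    """Maximised log-likelihood of a logistic model with intercept,
    obtained by BFGS on the negative log-likelihood."""
    x = np.column_stack([np.ones(len(y)), np.asarray(x, dtype=float)])
    y = np.asarray(y, dtype=float)

    def nll(beta):
        z = x @ beta
        return float(np.sum(np.logaddexp(0.0, z)) - y @ z)

    def grad(beta):
        p = 1.0 / (1.0 + np.exp(-(x @ beta)))
        return x.T @ (p - y)

    res = optimize.minimize(nll, np.zeros(x.shape[1]), jac=grad, method="BFGS",
                            options={"gtol": 1e-10, "maxiter": 500})
    return -float(res.fun)


def intercept_only_llf(y: np.ndarray) -> float:
    p1 = float(np.mean(y))
    if p1 in (0.0, 1.0):
        return 0.0
    n1 = float(np.sum(y))
    n0 = len(y) - n1
    return n1 * np.log(p1) + n0 * np.log(1 - p1)


def exhaustive_backward_selection(xdf, y, alpha_remove: float = 0.10) -> tuple[str, ...]:
    """Replay the backward likelihood-ratio removal rule from a table of
    log-likelihoods enumerated over ALL candidate subsets (each fitted by
    scipy NLL minimisation). Returns the retained terms in the original
    column order."""
    cols = list(xdf.columns)
    y = np.asarray(y, dtype=float)
    llf = {}
    for r in range(len(cols) + 1):
        for subset in combinations(cols, r):
            if r == 0:
                llf[subset] = intercept_only_llf(y)
            else:
                llf[subset] = logistic_llf_scipy(xdf[list(subset)].to_numpy(), y)
    current = tuple(cols)
    while current:
        pvals = {}
        for term in current:
            reduced = tuple(c for c in current if c != term)
            lr = max(2.0 * (llf[current] - llf[reduced]), 0.0)
            pvals[term] = float(chi2.sf(lr, df=1))
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= alpha_remove:
            break
        current = tuple(c for c in current if c != worst)
    return current


def fa_closed_form(eigvals) -> float:
    """Fractional anisotropy from eigenvalues, standard formula."""
    lam = np.asarray(eigvals, dtype=float)
    lbar = lam.mean()
    return float(np.sqrt(1.5 * np.sum((lam - lbar) ** 2) / np.sum(lam**2)))


def sphere_lattice_count(radius: float, spacing: tuple[float, float, float]) -> int:
    """Brute-force count of lattice points (voxel centers) within radius."""
    sx, sy, sz = spacing
    nx = int(radius // sx) + 1
    ny = int(radius // sy) + 1
    nz = int(radius // sz) + 1
    count = 0
    for i in range(-nx, nx + 1):
        for j in range(-ny, ny + 1):
            for k in range(-nz, nz + 1):
                if (i * sx) ** 2 + (j * sy) ** 2 + (k * sz) ** 2 <= radius**2:
                    count += 1
    return count
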