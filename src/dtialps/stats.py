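"""Cohort statistics: group tests, stepwise logistic regression, ROC, OLS.

Implements the analysis battery used for case–control CSVD cohorts:

* Mann–Whitney U for continuous variables (exact enumeration p-value for
  small untied samples, tie-corrected normal approximation otherwise),
* Pearson chi-square with automatic Yates continuity correction for 2x2
  tables with small expected counts,
* maximum-likelihood logistic regression with Wald odds-ratio intervals,
* backward stepwise elimination by likelihood-ratio test,
* empirical ROC curves / AUROC,
* ordinary least squares with t-based intervals and variance inflation
  factors.

All tests are two-sided; intervals are 95%; missing data are handled by
per-model listwise deletion with the analysed n reported on every fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "GroupComparison",
    "LogisticFit",
    "LinearFit",
    "RocCurve",
    "StepwiseTrace",
    "StatsError",
    "SeparationError",
    "CollinearityError",
    "mann_whitney",
    "chi_square",
    "logistic_fit",
    "backward_stepwise",
    "roc_auc",
    "linear_fit",
]

_Z95 = 1.96


class StatsError(ValueError):
    pass


class SeparationError(StatsError):
    """Perfect separation: the logistic MLE does not exist."""


class CollinearityError(StatsError):
    def __init__(self, terms: Sequence[str], vif: dict[str, float] | None = None):
        self.terms = list(terms)
        self.vif = vif or {}
        super().__init__(f"rank-deficient design; collinear terms: {', '.join(self.terms)}")


# ---------------------------------------------------------------------------
# group comparisons

@dataclass(frozen=True)
class GroupComparison:
    variable: str
    test: Literal["mann_whitney", "chi_square", "chi_square_continuity"]
    statistic: float
    p_value: float
    summaries: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0 <= self.p_value <= 1:
            raise StatsError(f"p-value {self.p_value} outside [0, 1]")


def mann_whitney(x, y, variable: str = "") -> GroupComparison:
    """Two-sided Mann–Whitney U test with midrank ties.

    Uses the exact null distribution when min(n) <= 8 and there are no
    ties, and the tie-corrected continuity-corrected normal approximation
    otherwise. Missing values are dropped per sample.
    """
    x = np.asarray(pd.Series(x).dropna(), dtype=float)
    y = np.asarray(pd.Series(y).dropna(), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise StatsError("mann_whitney requires non-empty samples")
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return GroupComparison(
        variable=variable,
        test="mann_whitney",
        statistic=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        summaries={
            "n": (len(x), len(y)),
            "mean": (float(x.mean()), float(y.mean())),
            "sd": (float(x.std(ddof=1)) if len(x) > 1 else 0.0,
                   float(y.std(ddof=1)) if len(y) > 1 else 0.0),
            "method": method,
        },
    )


def chi_square(table, continuity: Literal["auto", True, False] = "auto",
               variable: str = "") -> GroupComparison:
    """Pearson chi-square on an r x c count table.

    With ``continuity='auto'`` the Yates correction is applied exactly for
    2x2 tables in which any expected count is below 5.
    """
    table = np.asarray(table, dtype=float)
    if np.any(table < 0) or np.any(table != np.round(table)):
        raise StatsError("counts must be non-negative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise StatsError("zero margin in contingency table")
    expected = sps.contingency.expected_freq(table)
    if continuity == "auto":
        use_corr = table.shape == (2, 2) and bool((expected < 5).any())
    else:
        use_corr = bool(continuity) and table.shape == (2, 2)
    stat, p, dof, _ = sps.chi2_contingency(table, correction=use_corr)
    col_tot = table.sum(axis=0)
    return GroupComparison(
        variable=variable,
        test="chi_square_continuity" if use_corr else "chi_square",
        statistic=float(stat),
        p_value=float(p),
        summaries={
            "df": int(dof),
            "counts": table.astype(int).tolist(),
            "percent": (100 * table / col_tot).tolist(),
            "n": tuple(int(c) for c in col_tot),
        },
    )


# ---------------------------------------------------------------------------
# design-matrix plumbing

def _as_design(design, outcome) -> tuple[pd.DataFrame, pd.Series]:
    x = pd.DataFrame(design).astype(float)
    y = pd.Series(np.asarray(outcome, dtype=float), index=x.index)
    keep = x.notna().all(axis=1) & y.notna()
    return x.loc[keep], y.loc[keep]


def _collinear_terms(x: pd.DataFrame) -> list[str]:
    mat = np.column_stack([np.ones(len(x)), x.to_numpy()])
    rank = np.linalg.matrix_rank(mat)
    if rank == mat.shape[1]:
        return []
    bad = []
    for j, name in enumerate(x.columns):
        reduced = np.delete(mat, j + 1, axis=1)
        if np.linalg.matrix_rank(reduced) == rank:
            bad.append(str(name))
    return bad


# ---------------------------------------------------------------------------
# logistic regression

@dataclass(frozen=True)
class LogisticFit:
    terms: tuple[str, ...]
    coef: np.ndarray          # includes intercept first
    se: np.ndarray
    p_values: np.ndarray
    odds_ratio: np.ndarray    # per non-intercept term
    ci_low: np.ndarray
    ci_high: np.ndarray
    llf: float
    converged: bool
    n_obs: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "B": self.coef[1:],
                "SE": self.se[1:],
                "OR": self.odds_ratio,
                "OR_CI_low": self.ci_low,
                "OR_CI_high": self.ci_high,
                "P": self.p_values[1:],
            },
            index=list(self.terms),
        )


def logistic_fit(design, outcome) -> LogisticFit:
    """Maximum-likelihood logistic regression with Wald inference.

    Odds ratios are exp(B) with 95% intervals exp(B ± 1.96 SE). Raises
    :class:`SeparationError` on perfect separation and
    :class:`CollinearityError` naming the collinear terms on a
    rank-deficient design (both after listwise deletion).
    """
    x, y = _as_design(design, outcome)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise StatsError("outcome must be binary 0/1")
    if len(x) == 0:
        raise StatsError("no complete cases")
    bad = _collinear_terms(x)
    if bad:
        raise CollinearityError(bad)
    xmat = sm.add_constant(x, has_constant="add")
    with warnings.catch_warnings(), np.errstate(over="ignore", divide="ignore"):
        warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
        warnings.simplefilter("ignore", category=sm.tools.sm_exceptions.ConvergenceWarning)
        warnings.simplefilter("ignore", category=sm.tools.sm_exceptions.HessianInversionWarning)
        warnings.simplefilter("ignore", category=RuntimeWarning)
        try:
            res = sm.Logit(y, xmat).fit(disp=0, maxiter=200)
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as exc:
            raise SeparationError(str(exc)) from exc
        except np.linalg.LinAlgError:
            # Newton's Hessian can go singular under quasi-separation (an
            # indicator whose off level is all one class); BFGS still
            # reaches the finite part of the likelihood surface
            res = sm.Logit(y, xmat).fit(disp=0, maxiter=500, method="bfgs")
            if not res.mle_retvals["converged"]:
                raise SeparationError(
                    "logistic likelihood has no attained maximum "
                    "((quasi-)separation)"
                ) from None
    coef = np.asarray(res.params)
    if not np.all(np.isfinite(coef)) or np.max(np.abs(coef[1:]), initial=0.0) > 1e3:
        raise SeparationError("divergent coefficients: (quasi-)separation suspected")
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")
        se = np.asarray(res.bse)
        p_values = np.asarray(res.pvalues)
        ci_low = np.exp(coef[1:] - _Z95 * se[1:])
        ci_high = np.exp(coef[1:] + _Z95 * se[1:])
    return LogisticFit(
        terms=tuple(str(c) for c in x.columns),
        coef=coef,
        se=se,
        p_values=p_values,
        odds_ratio=np.exp(coef[1:]),
        ci_low=ci_low,
        ci_high=ci_high,
        llf=float(res.llf),
        converged=bool(res.mle_retvals["converged"]),
        n_obs=int(res.nobs),
    )


@dataclass(frozen=True)
class StepwiseTrace:
    removals: tuple[tuple[str, float], ...]  # (term, LR p at removal)


def _lr_pvalues(x: pd.DataFrame, y: pd.Series, llf_full: float) -> dict[str, float]:
    out = {}
    for term in x.columns:
        reduced = x.drop(columns=[term])
        if reduced.shape[1] == 0:
            p1 = float(np.mean(y))
            llf_red = float(np.sum(y * np.log(p1) + (1 - y) * np.log1p(-p1))) if 0 < p1 < 1 else 0.0
        else:
            llf_red = logistic_fit(reduced, y).llf
        lr = max(2.0 * (llf_full - llf_red), 0.0)
        out[str(term)] = float(sps.chi2.sf(lr, df=1))
    return out


def backward_stepwise(design, outcome, alpha_remove: float = 0.10
                      ) -> tuple[LogisticFit, StepwiseTrace]:
    """Backward stepwise logistic regression with likelihood-ratio removal.

    Starts from the full model and repeatedly drops the term whose
    single-term likelihood-ratio p-value is largest, as long as it exceeds
    ``alpha_remove``; stops when every remaining term has p <= alpha.
    Listwise deletion is performed once on the full candidate set so every
    step is fitted on the same cases. An intercept-only final model is
    allowed.
    """
    if not 0 < alpha_remove <= 1:
        raise StatsError("alpha_remove must be in (0, 1]")
    x, y = _as_design(design, outcome)
    if x.shape[1] == 0:
        raise StatsError("at least one candidate term is required")
    removals: list[tuple[str, float]] = []
    current = x
    while current.shape[1] > 0:
        fit = logistic_fit(current, y)
        pvals = _lr_pvalues(current, y, fit.llf)
        worst = max(pvals, key=pvals.get)
        if pvals[worst] <= alpha_remove:
            return fit, StepwiseTrace(tuple(removals))
        removals.append((worst, pvals[worst]))
        current = current.drop(columns=[worst])
    # intercept-only model
    p1 = float(np.mean(y))
    llf = float(np.sum(y * np.log(p1) + (1 - y) * np.log1p(-p1))) if 0 < p1 < 1 else 0.0
    empty = LogisticFit(
        terms=(), coef=np.array([np.log(p1 / (1 - p1)) if 0 < p1 < 1 else 0.0]),
        se=np.array([np.nan]), p_values=np.array([np.nan]),
        odds_ratio=np.array([]), ci_low=np.array([]), ci_high=np.array([]),
        llf=llf, converged=True, n_obs=len(y),
    )
    return empty, StepwiseTrace(tuple(removals))


# ---------------------------------------------------------------------------
# ROC

@dataclass(frozen=True)
class RocCurve:
    fpr: np.ndarray            # 1 - specificity, ascending
    tpr: np.ndarray            # sensitivity
    thresholds: np.ndarray
    auc: float
    direction: Literal["higher", "lower"]

    def __post_init__(self):
        trap = float(np.trapezoid(self.tpr, self.fpr))
        if abs(trap - self.auc) > 1e-12:
            raise StatsError("stored AUC inconsistent with curve points")


def roc_auc(scores, labels, direction: Literal["higher", "lower", "auto"] = "auto"
            ) -> RocCurve:
    """Empirical ROC curve and trapezoidal AUC.

    ``direction`` states whether higher or lower scores indicate the
    positive class; ``auto`` picks the orientation with AUC >= 0.5 (for
    the ALPS index, lower values flag impairment). Ties are handled by
    simultaneous threshold crossing, equivalent to counting tied
    positive–negative pairs as 1/2.
    """
    from sklearn.metrics import roc_curve as _sk_roc

    s = np.asarray(scores, dtype=float)
    yl = np.asarray(labels, dtype=float)
    keep = ~(np.isnan(s) | np.isnan(yl))
    s, yl = s[keep], yl[keep]
    classes = set(np.unique(yl))
    if not classes == {0.0, 1.0}:
        raise StatsError("labels must contain both classes, coded 0/1")

    def _curve(sign: int):
        fpr, tpr, thr = _sk_roc(yl, sign * s)
        return fpr, tpr, thr, float(np.trapezoid(tpr, fpr))

    if direction == "auto":
        fpr, tpr, thr, auc = _curve(+1)
        chosen = "higher"
        if auc < 0.5:
            fpr, tpr, thr, auc = _curve(-1)
            chosen = "lower"
    else:
        sign = +1 if direction == "higher" else -1
        fpr, tpr, thr, auc = _curve(sign)
        chosen = direction
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=auc, direction=chosen)


# ---------------------------------------------------------------------------
# linear models

@dataclass(frozen=True)
class LinearFit:
    terms: tuple[str, ...]
    coef: np.ndarray          # intercept first
    ci_low: np.ndarray        # per non-intercept term, t-based
    ci_high: np.ndarray
    p_values: np.ndarray
    vif: dict[str, float]
    resid_sd: float
    r_squared: float
    n_obs: int
    se: np.ndarray

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "B": self.coef[1:],
                "CI_low": self.ci_low,
                "CI_high": self.ci_high,
                "P": self.p_values[1:],
                "VIF": [self.vif[t] for t in self.terms],
            },
            index=list(self.terms),
        )


def _vif(x: pd.DataFrame) -> dict[str, float]:
    """VIF_j = 1 / (1 - R^2_j) from regressing predictor j on the others
    (with intercept). Infinite under exact collinearity."""
    out: dict[str, float] = {}
    for term in x.columns:
        others = sm.add_constant(x.drop(columns=[term]), has_constant="add")
        r2 = sm.OLS(x[term], others).fit().rsquared if others.shape[1] > 1 else 0.0
        out[str(term)] = float(np.inf) if r2 >= 1 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


def linear_fit(design, response) -> LinearFit:
    """Ordinary least squares with t-based 95% intervals and per-predictor
    variance inflation factors.

    On an exactly collinear design the VIFs (infinite for the offending
    terms) are attached to the raised :class:`CollinearityError`.
    """
    x, y = _as_design(design, response)
    if len(x) <= x.shape[1] + 1:
        raise StatsError("too few complete cases for the requested model")
    vif = _vif(x)
    bad = _collinear_terms(x)
    if bad:
        raise CollinearityError(bad, vif=vif)
    xmat = sm.add_constant(x, has_constant="add")
    res = sm.OLS(y, xmat).fit()
    ci = np.asarray(res.conf_int(alpha=0.05))
    return LinearFit(
        terms=tuple(str(c) for c in x.columns),
        coef=np.asarray(res.params),
        ci_low=ci[1:, 0],
        ci_high=ci[1:, 1],
        p_values=np.asarray(res.pvalues),
        vif=vif,
        resid_sd=float(np.sqrt(res.mse_resid)) if res.df_resid > 0 else 0.0,
        r_squared=float(res.rsquared),
        n_obs=int(res.nobs),
        se=np.asarray(res.bse),
    )
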