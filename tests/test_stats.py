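import numpy as np
import pandas as pd
import pytest

from _oracles import (
    exhaustive_backward_selection,
    logistic_llf_scipy,
    mann_whitney_exact_p,
    mann_whitney_u_brute,
    pairwise_auc,
)
from dtialps.stats import (
    CollinearityError,
    SeparationError,
    StatsError,
    backward_stepwise,
    chi_square,
    linear_fit,
    logistic_fit,
    mann_whitney,
    roc_auc,
)


# ---------------------------------------------------------------------------
# Mann-Whitney

def test_mann_whitney_separated_samples():
    """Fully separated n=3 samples: U = 0 and exact two-sided p = 0.1
    (2 of the 20 equally likely rank assignments are as extreme)."""
    res = mann_whitney([1, 2, 3], [4, 5, 6])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1, abs=1e-12)
    assert res.p_value == pytest.approx(mann_whitney_exact_p([1, 2, 3], [4, 5, 6]))


def test_mann_whitney_identical_samples():
    x = [3, 1, 4, 1, 5]
    res = mann_whitney(x, list(x))
    assert res.statistic == len(x) ** 2 / 2  # midrank ties
    assert res.p_value == pytest.approx(1.0, abs=1e-9)


def test_mann_whitney_exact_matches_enumeration():
    rng = np.random.default_rng(0)
    for n1, n2 in [(2, 5), (4, 4), (6, 3), (5, 6)]:
        vals = rng.permutation(n1 + n2) + 1.0
        x, y = vals[:n1], vals[n1:]
        res = mann_whitney(x, y)
        assert res.summaries["method"] == "exact"
        assert res.p_value == pytest.approx(mann_whitney_exact_p(x, y), abs=1e-12)
        assert res.statistic == mann_whitney_u_brute(x, y)


def test_mann_whitney_type_one_error_rate():
    """Under the null (equal normals, n=50 each) the two-sided 5% test
    rejects at ~5% over 2000 replicates."""
    rng = np.random.default_rng(123)
    rejections = 0
    for _ in range(2000):
        x = rng.standard_normal(50)
        y = rng.standard_normal(50)
        if mann_whitney(x, y).p_value < 0.05:
            rejections += 1
    assert rejections / 2000 == pytest.approx(0.05, abs=0.01)


def test_mann_whitney_empty_after_missing():
    with pytest.raises(StatsError):
        mann_whitney([np.nan, np.nan], [1.0, 2.0])


# ---------------------------------------------------------------------------
# chi-square

def test_chi_square_homogeneous_table():
    res = chi_square([[10, 10], [10, 10]])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(1.0)


def test_chi_square_on_printed_wml_table():
    """The observed 4x2 WML-category table is highly significant."""
    res = chi_square([[9, 7], [16, 11], [14, 11], [11, 53]])
    assert res.p_value < 0.001
    assert res.test == "chi_square"
    assert res.summaries["df"] == 3


def test_continuity_correction_shrinks_statistic():
    table = [[2, 8], [8, 2]]
    corrected = chi_square(table, continuity=True)
    plain = chi_square(table, continuity=False)
    assert corrected.statistic < plain.statistic
    assert corrected.test == "chi_square_continuity"
    # direct Pearson formula oracle for the uncorrected statistic
    t = np.array(table, dtype=float)
    expected = np.outer(t.sum(1), t.sum(0)) / t.sum()
    assert plain.statistic == pytest.approx(((t - expected) ** 2 / expected).sum())


def test_chi_square_auto_correction_rule():
    small = chi_square([[2, 8], [8, 2]], continuity="auto")  # expected counts 5
    assert small.test == "chi_square"  # expected exactly 5, not < 5
    smaller = chi_square([[1, 8], [8, 1]], continuity="auto")
    assert smaller.test == "chi_square_continuity"


def test_chi_square_zero_margin_rejected():
    with pytest.raises(StatsError, match="margin"):
        chi_square([[0, 0], [5, 3]])


# ---------------------------------------------------------------------------
# logistic regression

def _sim_logit(rng, n=500, beta=(-1.0, 0.5)):
    x = rng.standard_normal((n, len(beta)))
    lin = -0.3 + x @ np.array(beta)
    y = rng.random(n) < 1 / (1 + np.exp(-lin))
    return pd.DataFrame(x, columns=[f"x{i}" for i in range(len(beta))]), y.astype(float)


def test_logistic_recovers_known_coefficients():
    rng = np.random.default_rng(7)
    x, y = _sim_logit(rng, n=2000)
    fit = logistic_fit(x, y)
    for b, se, truth in zip(fit.coef[1:], fit.se[1:], (-1.0, 0.5)):
        assert abs(b - truth) < 3 * se


def test_odds_ratio_self_consistency():
    """OR = exp(B) and the Wald interval brackets it, to 1e-12."""
    rng = np.random.default_rng(8)
    x, y = _sim_logit(rng)
    fit = logistic_fit(x, y)
    np.testing.assert_allclose(fit.odds_ratio, np.exp(fit.coef[1:]), rtol=1e-12)
    assert (fit.ci_low <= fit.odds_ratio).all() and (fit.odds_ratio <= fit.ci_high).all()
    np.testing.assert_allclose(
        fit.ci_low, np.exp(fit.coef[1:] - 1.96 * fit.se[1:]), rtol=1e-12
    )


def test_loglik_matches_convex_optimisation_oracle():
    """statsmodels-backed fit agrees with direct scipy NLL minimisation
    on seeded small datasets."""
    rng = np.random.default_rng(9)
    for _ in range(50):
        x, y = _sim_logit(rng, n=80, beta=tuple(rng.normal(0, 0.8, 2)))
        fit = logistic_fit(x, y)
        assert fit.llf == pytest.approx(logistic_llf_scipy(x.to_numpy(), y), abs=1e-8)


def test_perfect_separation_raises():
    x = pd.DataFrame({"x": np.r_[np.zeros(10), np.ones(10)]})
    y = np.r_[np.zeros(10), np.ones(10)]
    with pytest.raises(SeparationError):
        logistic_fit(x, y)


def test_collinear_design_names_terms():
    rng = np.random.default_rng(10)
    a = rng.standard_normal(60)
    x = pd.DataFrame({"a": a, "b": 2 * a, "c": rng.standard_normal(60)})
    y = (rng.random(60) < 0.5).astype(float)
    with pytest.raises(CollinearityError) as exc:
        logistic_fit(x, y)
    assert set(exc.value.terms) == {"a", "b"}


# ---------------------------------------------------------------------------
# backward stepwise

def test_stepwise_alpha_extremes_and_monotone_trace():
    """alpha_remove = 1 keeps the full model; alpha -> 0 empties it; the
    number of removals is monotone in between on fixed data."""
    rng = np.random.default_rng(11)
    x = pd.DataFrame(rng.standard_normal((150, 4)), columns=list("abcd"))
    y = (rng.random(150) < 0.5).astype(float)
    full, trace_full = backward_stepwise(x, y, alpha_remove=1.0)
    assert set(full.terms) == set("abcd") and trace_full.removals == ()
    empty, trace_empty = backward_stepwise(x, y, alpha_remove=1e-12)
    assert empty.terms == () and len(trace_empty.removals) == 4
    lengths = [
        len(backward_stepwise(x, y, alpha_remove=a)[1].removals)
        for a in (1e-12, 0.01, 0.10, 0.5, 1.0)
    ]
    assert lengths == sorted(lengths, reverse=True)


def test_stepwise_selects_true_predictors():
    """With 2 strong real effects among 6 candidates (n=1000) the final
    model contains both in at least 95% of seeded replicates."""
    hits = 0
    reps = 200
    for seed in range(reps):
        rng = np.random.default_rng(1000 + seed)
        x = pd.DataFrame(rng.standard_normal((1000, 6)),
                         columns=[f"x{i}" for i in range(6)])
        lin = 1.2 * x["x0"] - 1.0 * x["x3"]
        y = (rng.random(1000) < 1 / (1 + np.exp(-lin))).astype(float)
        fit, _ = backward_stepwise(x, y, alpha_remove=0.10)
        if {"x0", "x3"} <= set(fit.terms):
            hits += 1
    assert hits / reps >= 0.95


def test_stepwise_null_retention_rate():
    """Pure-noise candidates each survive with probability near the
    removal threshold alpha = 0.10."""
    retained = 0
    total = 0
    for seed in range(200):
        rng = np.random.default_rng(2000 + seed)
        x = pd.DataFrame(rng.standard_normal((500, 4)), columns=list("abcd"))
        y = (rng.random(500) < 0.5).astype(float)
        fit, _ = backward_stepwise(x, y, alpha_remove=0.10)
        retained += len(fit.terms)
        total += 4
    assert 0.04 <= retained / total <= 0.17


def test_stepwise_matches_exhaustive_oracle_small():
    """Final model equals the subset-enumeration oracle's selection on
    seeded datasets with <= 5 candidates (spot check; the full 100-dataset
    sweep runs in the acceptance suite)."""
    for seed in range(10):
        rng = np.random.default_rng(3000 + seed)
        k = int(rng.integers(2, 6))
        x = pd.DataFrame(rng.standard_normal((150, k)),
                         columns=[f"x{i}" for i in range(k)])
        beta = rng.normal(0, 0.6, k) * (rng.random(k) < 0.5)
        y = (rng.random(150) < 1 / (1 + np.exp(-(x.to_numpy() @ beta)))).astype(float)
        fit, _ = backward_stepwise(x, y, alpha_remove=0.10)
        oracle = exhaustive_backward_selection(x, y, alpha_remove=0.10)
        assert set(fit.terms) == set(oracle)


# ---------------------------------------------------------------------------
# ROC

def test_roc_perfect_separation():
    rc = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1], direction="higher")
    assert rc.auc == 1.0


def test_roc_null_auc_near_half():
    rng = np.random.default_rng(12)
    scores = rng.standard_normal(1000)
    labels = (rng.random(1000) < 0.5).astype(int)
    rc = roc_auc(scores, labels, direction="higher")
    assert rc.auc == pytest.approx(0.5, abs=0.05)


def test_roc_equals_pairwise_oracle_with_ties():
    """Trapezoidal AUC equals the proportion of correctly ordered
    positive-negative pairs (ties 1/2) computed by brute force."""
    rng = np.random.default_rng(13)
    for _ in range(20):
        scores = rng.integers(0, 8, 60).astype(float)  # heavy ties
        labels = (rng.random(60) < 0.4).astype(int)
        if labels.sum() in (0, 60):
            continue
        rc = roc_auc(scores, labels, direction="higher")
        assert rc.auc == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)


def test_roc_auto_direction_flips_lower_scores():
    """When low scores mark the positive class, auto orientation reports
    direction='lower' and AUC above one half."""
    rng = np.random.default_rng(14)
    pos = rng.normal(0.95, 0.09, 80)
    neg = rng.normal(1.05, 0.14, 50)
    scores = np.r_[pos, neg]
    labels = np.r_[np.ones(80), np.zeros(50)]
    rc = roc_auc(scores, labels, direction="auto")
    assert rc.direction == "lower"
    assert rc.auc > 0.5
    assert rc.auc == pytest.approx(pairwise_auc(-scores, labels), abs=1e-12)


def test_roc_single_class_rejected():
    with pytest.raises(StatsError):
        roc_auc([1.0, 2.0], [1, 1])


def test_auc_u_identity():
    """AUC = U / (n1 n2) with the midrank tie convention, exactly."""
    rng = np.random.default_rng(15)
    for _ in range(25):
        scores = rng.integers(0, 12, 80).astype(float)
        labels = (rng.random(80) < 0.5).astype(int)
        if labels.sum() in (0, 80):
            continue
        u = mann_whitney(scores[labels == 1], scores[labels == 0]).statistic
        rc = roc_auc(scores, labels, direction="higher")
        assert rc.auc == pytest.approx(u / (labels.sum() * (80 - labels.sum())), abs=1e-12)


# ---------------------------------------------------------------------------
# linear models

def test_vif_one_for_orthogonal_predictors():
    n = 64
    t = np.arange(n)
    x = pd.DataFrame({
        "a": np.cos(2 * np.pi * t / n),
        "b": np.sin(2 * np.pi * t / n),
        "c": np.cos(4 * np.pi * t / n),
    })
    y = x["a"] + np.random.default_rng(16).standard_normal(n)
    fit = linear_fit(x, y)
    for v in fit.vif.values():
        assert v == pytest.approx(1.0, abs=1e-9)


def test_exact_linear_relation_zero_width_interval():
    x = pd.DataFrame({"x": np.linspace(0, 1, 30)})
    fit = linear_fit(x, 2.0 * x["x"])
    assert fit.coef[1] == pytest.approx(2.0, abs=1e-10)
    assert fit.ci_high[0] - fit.ci_low[0] == pytest.approx(0.0, abs=1e-8)


def test_linear_recovery_on_cognition_scale():
    """y = 16*ALPS + 0.68*edu + noise at n=500 recovers both coefficients
    within 3 SE, on the scale of the adjusted MoCA model."""
    rng = np.random.default_rng(17)
    alps = rng.normal(1.0, 0.13, 500)
    edu = rng.normal(9.0, 4.0, 500)
    y = 16.0 * alps + 0.68 * edu + rng.normal(0, 3.0, 500)
    fit = linear_fit(pd.DataFrame({"alps": alps, "edu": edu}), y)
    for b, se, truth in zip(fit.coef[1:], fit.se[1:], (16.0, 0.68)):
        assert abs(b - truth) < 3 * se
    assert all(v >= 1.0 for v in fit.vif.values())


def test_linear_collinearity_reports_infinite_vif():
    rng = np.random.default_rng(18)
    a = rng.standard_normal(40)
    x = pd.DataFrame({"a": a, "b": -a})
    with pytest.raises(CollinearityError) as exc:
        linear_fit(x, rng.standard_normal(40))
    assert np.isinf(exc.value.vif["a"]) and np.isinf(exc.value.vif["b"])
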