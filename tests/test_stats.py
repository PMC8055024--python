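"""Beta-binomial likelihood, regression, Laplace mixed model and the
auxiliary inference helpers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from domhier.stats import (
    betabin_mixed_loglik,
    betabinom_logpmf,
    fit_betabin_mixed,
    fit_betabin_regression,
    mixture_lrt,
    pearson_correlation,
    pseudo_r2_lr,
    summarize_across_runs,
)
from domhier.synth import simulate_betabin_dataset

# frozen oracle: numeric quadrature of Binomial(10, p) against Beta(2, 3)
QUAD_LOGPMF_3_10 = -1.9389414797392202


def test_logpmf_uniform_special_case():
    # theta = 2, mu = 0.5 is Beta(1,1): all outcomes of n = 2 equally likely
    for k in (0, 1, 2):
        assert betabinom_logpmf(k, 2, 0.5, 2.0) == pytest.approx(math.log(1 / 3))


def test_logpmf_matches_quadrature_oracle():
    assert betabinom_logpmf(3, 10, 0.4, 5.0) == pytest.approx(
        QUAD_LOGPMF_3_10, abs=1e-8
    )


def test_logpmf_matches_scipy_reference():
    rng = np.random.default_rng(8)
    for _ in range(50):
        n = int(rng.integers(1, 200))
        k = int(rng.integers(0, n + 1))
        mu = rng.uniform(0.05, 0.95)
        th = rng.uniform(0.1, 50)
        ref = sps.betabinom.logpmf(k, n, mu * th, (1 - mu) * th)
        assert betabinom_logpmf(k, n, mu, th) == pytest.approx(ref, abs=1e-10)


def test_logpmf_binomial_limit():
    k, n, mu = 7, 20, 0.35
    assert betabinom_logpmf(k, n, mu, 1e8) == pytest.approx(
        sps.binom.logpmf(k, n, mu), abs=1e-4
    )


def test_logpmf_domain_errors():
    with pytest.raises(ValueError):
        betabinom_logpmf(5, 3, 0.5, 1.0)
    with pytest.raises(ValueError):
        betabinom_logpmf(1, 3, 0.5, -1.0)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.integers(1, 40),
    st.floats(0.05, 0.95),
    st.floats(0.2, 100.0),
)
def test_logpmf_normalizes(n, mu, theta):
    total = np.exp(betabinom_logpmf(np.arange(n + 1), n, mu, theta)).sum()
    assert total == pytest.approx(1.0, abs=1e-10)


def test_intercept_only_fit_recovers_logit_half():
    k = np.full(30, 10)
    n = np.full(30, 20)
    fit = fit_betabin_regression(k, n, np.ones((30, 1)))
    assert fit.coef[0] == pytest.approx(0.0, abs=1e-6)
    assert fit.converged


def test_binomial_limit_matches_logistic_oracle():
    """With theta fixed huge on binomial data the fit equals an ordinary
    logistic regression (statsmodels GLM oracle)."""
    import statsmodels.api as sm

    rng = np.random.default_rng(5)
    x = rng.uniform(-1, 1, 150)
    X = np.column_stack([np.ones(150), x])
    n = np.full(150, 25)
    mu = 1 / (1 + np.exp(-(0.4 + 1.2 * x)))
    k = rng.binomial(n, mu)
    fit = fit_betabin_regression(k, n, X, theta_fixed=1e9)
    glm = sm.GLM(np.column_stack([k, n - k]), X, family=sm.families.Binomial()).fit()
    assert fit.coef == pytest.approx(glm.params, abs=1e-3)
    assert fit.se == pytest.approx(glm.bse, rel=0.01)


def test_regression_recovery_wald_coverage():
    """The true slope lies inside its 95 percent Wald interval in at least
    90 percent of replicates."""
    rng = np.random.default_rng(99)
    hits = 0
    reps = 100
    for _ in range(reps):
        x = rng.uniform(0, 1, 200)
        X = np.column_stack([np.ones(200), x])
        n = np.full(200, 20)
        k, _ = simulate_betabin_dataset([0.0, 2.0], 10.0, X, n, seed=rng)
        fit = fit_betabin_regression(k, n, X)
        lo, hi = fit.coef[1] - 1.96 * fit.se[1], fit.coef[1] + 1.96 * fit.se[1]
        hits += lo <= 2.0 <= hi
    assert hits >= 90


def test_non_full_rank_design_rejected():
    X = np.column_stack([np.ones(10), np.ones(10)])
    with pytest.raises(ValueError):
        fit_betabin_regression(np.ones(10), np.full(10, 5), X)


def test_laplace_matches_exact_quadrature_oracle():
    """Laplace marginal log-likelihood vs exact 1-D quadrature on a tiny
    one-factor model (frozen oracle; difference is the approximation error,
    small even at two observations per group)."""
    kv = np.array([3, 5, 1, 4])
    nv = np.array([8, 9, 6, 10])
    X = np.column_stack([np.ones(4), [0.1, 0.6, 0.3, 0.9]])
    grouping = {"g": np.array([0, 0, 1, 1])}
    ll = betabin_mixed_loglik(kv, nv, X, grouping, [0.3, 0.8], 6.0, {"g": 0.7})
    assert ll == pytest.approx(-8.945700089713835, abs=0.05)


def test_mixed_equals_fixed_at_zero_variance():
    """As the random-intercept SD goes to zero the Laplace marginal equals
    the fixed-effects log-likelihood."""
    rng = np.random.default_rng(17)
    x = rng.uniform(0, 1, 40)
    X = np.column_stack([np.ones(40), x])
    n = np.full(40, 15)
    k, _ = simulate_betabin_dataset([0.2, 1.0], 8.0, X, n, seed=rng)
    fixed = fit_betabin_regression(k, n, X)
    grouping = {"g": np.repeat(np.arange(8), 5)}
    ll0 = betabin_mixed_loglik(
        k, n, X, grouping, fixed.coef, fixed.theta, {"g": 1e-5}
    )
    assert ll0 == pytest.approx(fixed.loglik, abs=1e-6)
    # an empty grouping degenerates to the fixed fit exactly
    same = fit_betabin_mixed(k, n, X, {}, names=["i", "x"])
    assert same.loglik == pytest.approx(fixed.loglik, abs=1e-9)


def test_mixed_fit_recovers_variance_component():
    rng = np.random.default_rng(31)
    pop = np.repeat(np.arange(60), 5)
    m = len(pop)
    x = rng.uniform(0, 1, m)
    X = np.column_stack([np.ones(m), x])
    n = np.full(m, 20)
    k, _ = simulate_betabin_dataset(
        [0.0, 1.0], 10.0, X, n, {"pop": pop}, {"pop": 1.0}, seed=rng
    )
    fit = fit_betabin_mixed(k, n, X, {"pop": pop}, names=["i", "x"])
    assert fit.converged
    assert 0.5 <= fit.variance_components["pop"] ** 0.5 <= 1.5


@pytest.mark.parametrize(
    "x2,weights,expected",
    [
        (1.51, {0: 0.5, 1: 0.5}, 0.11),  # overdispersion at the boundary
        (0.031, {0: 0.25, 1: 0.5, 2: 0.25}, 0.68),  # two variance components
    ],
)
def test_mixture_lrt_closed_forms(x2, weights, expected):
    res = mixture_lrt(x2 / 2, 0.0, weights)
    assert round(res.p_value, 2) == expected


def test_mixture_lrt_boundaries():
    assert mixture_lrt(0.0, 0.0, {0: 0.5, 1: 0.5}).p_value == 1.0
    with pytest.raises(ValueError):
        mixture_lrt(0.0, 1.0, {0: 0.5, 1: 0.5})
    with pytest.raises(ValueError):
        mixture_lrt(1.0, 0.0, {0: 0.5, 1: 0.4})


def test_mixture_lrt_boundary_type_I_error():
    """For a parameter on the boundary the LRT statistic is max(0, z)^2 and
    the half-half chi-bar-square mixture gives nominal 5 percent size."""
    rng = np.random.default_rng(123)
    z = rng.normal(size=1000)
    x2 = np.maximum(0.0, z) ** 2
    rej = sum(
        mixture_lrt(v / 2, 0.0, {0: 0.5, 1: 0.5}).p_value < 0.05 for v in x2
    )
    assert abs(rej / 1000 - 0.05) <= 0.02


def test_wald_z_squared_tracks_lrt_for_single_slope():
    rng = np.random.default_rng(6)
    m = 2000
    x = rng.uniform(0, 1, m)
    X = np.column_stack([np.ones(m), x])
    n = np.full(m, 20)
    k, _ = simulate_betabin_dataset([0.0, 0.5], 8.0, X, n, seed=rng)
    full = fit_betabin_regression(k, n, X)
    null = fit_betabin_regression(k, n, X[:, :1])
    lrt = 2 * (full.loglik - null.loglik)
    assert 0.8 <= full.z[1] ** 2 / lrt <= 1.2


def test_pseudo_r2():
    assert pseudo_r2_lr(-10.0, -10.0, 20) == 0.0
    n = 30
    assert pseudo_r2_lr(-5.0, -5.0 - n / 2, n) == pytest.approx(1 - math.exp(-1))
    # hand formula on arbitrary likelihoods
    assert pseudo_r2_lr(-12.3, -20.7, 14) == pytest.approx(
        1 - math.exp(-(2 / 14) * 8.4), abs=1e-10
    )
    capped = pseudo_r2_lr(-12.3, -20.7, 14, rescale=True)
    assert capped > pseudo_r2_lr(-12.3, -20.7, 14)


def test_pearson_correlation():
    x = np.arange(10.0)
    r, p = pearson_correlation(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    with pytest.raises(ValueError):
        pearson_correlation(np.ones(5), np.arange(5.0))


def test_pearson_p_matches_permutation_null():
    rng = np.random.default_rng(44)
    x = rng.normal(size=9)
    y = rng.normal(size=9)
    r, p = pearson_correlation(x, y)
    perm = np.array(
        [pearson_correlation(x, rng.permutation(y))[0] for _ in range(4000)]
    )
    p_perm = np.mean(np.abs(perm) >= abs(r))
    assert abs(p - p_perm) < 0.05


def test_summarize_across_runs():
    rng = np.random.default_rng(2)
    # construct slopes with exactly the reported mean and s.e.m.
    raw = rng.normal(size=40)
    raw = (raw - raw.mean()) / (raw.std(ddof=1) / math.sqrt(40))  # mean 0, sem 1
    slopes = 1.31 + 0.47 * raw
    s = summarize_across_runs(slopes)
    assert s.mean == pytest.approx(1.31) and s.sem == pytest.approx(0.47)
    assert s.t == pytest.approx(1.31 / 0.47, abs=1e-9)
    assert s.t == pytest.approx(2.80, abs=0.02)
    # symmetric slopes: t = 0
    sym = summarize_across_runs(np.array([-2.0, -1.0, 1.0, 2.0]))
    assert sym.t == 0.0
    # identical slopes: flagged degenerate
    deg = summarize_across_runs(np.array([1.5, 1.5, 1.5]))
    assert deg.degenerate and np.isnan(deg.t)


def test_run_summary_p_uniform_under_null():
    """One-sample t p-values across meta-replicates of null slopes are
    uniform (KS test)."""
    rng = np.random.default_rng(10)
    ps = [
        summarize_across_runs(rng.normal(size=40)).p_value for _ in range(200)
    ]
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_aic_invariant_to_column_shift():
    rng = np.random.default_rng(21)
    x = rng.uniform(0, 1, 60)
    X = np.column_stack([np.ones(60), x])
    n = np.full(60, 12)
    k, _ = simulate_betabin_dataset([0.3, 0.8], 6.0, X, n, seed=rng)
    f1 = fit_betabin_regression(k, n, X)
    X2 = np.column_stack([np.ones(60), x + 5.0])
    f2 = fit_betabin_regression(k, n, X2)
    assert f1.aic == pytest.approx(f2.aic, abs=1e-5)
    assert f1.coef[1] == pytest.approx(f2.coef[1], abs=1e-4)
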