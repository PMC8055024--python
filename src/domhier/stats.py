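"""Beta-binomial regression and mixed-model inference for grouped proportions.

The beta-binomial model handles overdispersed binomial counts: conditional on
a Beta(mu*theta, (1-mu)*theta) draw p, k ~ Binomial(n, p).  ``mu`` is the mean
proportion, modelled through a logit link on a linear predictor, and
``theta`` (the precision, the sum of the two Beta shapes) controls
overdispersion — the binomial is recovered as theta -> infinity.

Fitting is by maximum likelihood (quasi-Newton with analytic gradients).
Random intercepts for hierarchical grouping factors are integrated out with
a Laplace approximation (one quadrature point), which is accurate at the
group sizes used here.  Variance components are permitted to sit at the zero
boundary; likelihood-ratio tests of boundary parameters use chi-bar-square
mixtures of chi-square distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "BetaBinFit",
    "MixtureLRTResult",
    "RunCoefficientSummary",
    "betabinom_logpmf",
    "fit_betabin_regression",
    "fit_betabin_mixed",
    "mixture_lrt",
    "pseudo_r2_lr",
    "pearson_correlation",
    "summarize_across_runs",
]

_LOGTHETA_BOUNDS = (-10.0, 20.0)
_LOGSIGMA_BOUNDS = (-9.0, 5.0)  # sigma in [1.2e-4, 148]; lower bound ~ zero boundary


def betabinom_logpmf(k, n, mu, theta):
    """Log pmf of the beta-binomial via log-gamma; stable for n up to ~1e4.

    ``P(k) = C(n, k) B(k + mu*theta, n - k + (1-mu)*theta) / B(mu*theta, (1-mu)*theta)``.
    """
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    mu = np.asarray(mu, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if np.any(k < 0) or np.any(k > n):
        raise ValueError("require 0 <= k <= n")
    if np.any(theta <= 0):
        raise ValueError("theta must be > 0")
    if np.any(mu <= 0) or np.any(mu >= 1):
        raise ValueError("mu must be in (0, 1)")
    a = mu * theta
    b = (1.0 - mu) * theta
    return (
        special.gammaln(n + 1)
        - special.gammaln(k + 1)
        - special.gammaln(n - k + 1)
        + special.betaln(k + a, n - k + b)
        - special.betaln(a, b)
    )


def _binom_logpmf(k, n, mu):
    return (
        special.gammaln(n + 1)
        - special.gammaln(k + 1)
        - special.gammaln(n - k + 1)
        + k * np.log(mu)
        + (n - k) * np.log1p(-mu)
    )


def _sigmoid(eta):
    return special.expit(eta)


def _dl_deta(k, n, mu, theta):
    """d logpmf / d eta (logit scale), beta-binomial or binomial limit."""
    if np.isinf(theta):
        return k - n * mu
    a = mu * theta
    b = (1.0 - mu) * theta
    g = theta * (
        special.digamma(k + a)
        - special.digamma(a)
        - special.digamma(n - k + b)
        + special.digamma(b)
    )
    return mu * (1.0 - mu) * g


def _d2l_deta2(k, n, mu, theta):
    if np.isinf(theta):
        return -n * mu * (1.0 - mu)
    a = mu * theta
    b = (1.0 - mu) * theta
    g = theta * (
        special.digamma(k + a)
        - special.digamma(a)
        - special.digamma(n - k + b)
        + special.digamma(b)
    )
    gp = theta**2 * (
        special.polygamma(1, k + a)
        - special.polygamma(1, a)
        + special.polygamma(1, n - k + b)
        - special.polygamma(1, b)
    )
    m1 = mu * (1.0 - mu)
    return m1 * (1.0 - 2.0 * mu) * g + m1**2 * gp


def _dl_dlogtheta(k, n, mu, theta):
    a = mu * theta
    b = (1.0 - mu) * theta
    d = (
        mu * (special.digamma(k + a) - special.digamma(a))
        + (1.0 - mu) * (special.digamma(n - k + b) - special.digamma(b))
        + special.digamma(theta)
        - special.digamma(n + theta)
    )
    return theta * d


@dataclass
class BetaBinFit:
    """A fitted (possibly mixed) beta-binomial regression."""

    names: list[str]
    coef: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    loglik: float
    theta: float
    variance_components: dict = field(default_factory=dict)  # name -> sigma^2
    aic: float = np.nan
    n_obs: int = 0
    n_params: int = 0
    converged: bool = False
    theta_fixed: bool = False
    message: str = ""
    cov: Optional[np.ndarray] = None  # covariance of the coefficient block

    def summary(self) -> str:
        lines = [
            f"beta-binomial fit: n_obs={self.n_obs}, logLik={self.loglik:.3f}, "
            f"AIC={self.aic:.1f}, theta={self.theta:.4g}"
            f"{' (fixed)' if self.theta_fixed else ''}, converged={self.converged}"
        ]
        for comp, v in self.variance_components.items():
            lines.append(f"  var({comp}) = {v:.4g}")
        lines.append(f"  {'term':<16}{'coef':>10}{'se':>10}{'z':>8}{'p':>10}")
        for i, nm in enumerate(self.names):
            se = self.se[i]
            lines.append(
                f"  {nm:<16}{self.coef[i]:>10.4f}"
                + (f"{se:>10.4f}{self.z[i]:>8.2f}{self.p[i]:>10.4g}"
                   if np.isfinite(se) else f"{'--':>10}{'--':>8}{'--':>10}")
            )
        return "\n".join(lines)


def _prepare_design(k, n, X, offset, names):
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != k.shape[0]:
        X = X.T
    if X.shape[0] != k.shape[0] or n.shape[0] != k.shape[0]:
        raise ValueError("k, n and X row counts must agree")
    if np.any(k < 0) or np.any(k > n) or np.any(n <= 0):
        raise ValueError("require 0 <= k <= n and n > 0")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is not full column rank")
    off = np.zeros_like(k) if offset is None else np.asarray(offset, dtype=float)
    if names is None:
        names = [f"x{j}" for j in range(X.shape[1])]
    return k, n, X, off, list(names)


def _start_beta(k, n, X, off):
    """Empirical-logit least-squares start."""
    p_emp = (k + 0.5) / (n + 1.0)
    z = special.logit(p_emp) - off
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    return beta


def fit_betabin_regression(
    k,
    n,
    X,
    offset=None,
    names: Optional[Sequence[str]] = None,
    theta_fixed: Optional[float] = None,
    max_iter: int = 500,
) -> BetaBinFit:
    """ML beta-binomial regression of successes ``k`` out of ``n`` on ``X``.

    The linear predictor is ``X @ beta + offset`` under a logit link.  With
    ``theta_fixed=np.inf`` an ordinary binomial regression is fitted (used as
    the reduced model in dispersion tests).  Returns Wald standard errors
    from the inverse observed information; non-convergence is flagged, never
    silent.
    """
    k, n, X, off, names = _prepare_design(k, n, X, offset, names)
    p = X.shape[1]
    free_theta = theta_fixed is None
    binom = theta_fixed is not None and np.isinf(theta_fixed)

    def unpack(psi):
        beta = psi[:p]
        theta = math.exp(psi[p]) if free_theta else float(theta_fixed)
        return beta, theta

    def nll_grad(psi):
        beta, theta = unpack(psi)
        eta = X @ beta + off
        mu = np.clip(_sigmoid(eta), 1e-12, 1 - 1e-12)
        if binom:
            ll = _binom_logpmf(k, n, mu)
        else:
            ll = betabinom_logpmf(k, n, mu, theta)
        deta = _dl_deta(k, n, mu, theta)
        grad = np.empty(len(psi))
        grad[:p] = X.T @ deta
        if free_theta:
            grad[p] = np.sum(_dl_dlogtheta(k, n, mu, theta))
        return -np.sum(ll), -grad

    psi0 = np.zeros(p + (1 if free_theta else 0))
    psi0[:p] = _start_beta(k, n, X, off)
    if free_theta:
        psi0[p] = math.log(10.0)

    bounds = [(None, None)] * p + ([_LOGTHETA_BOUNDS] if free_theta else [])
    best = None
    rng = np.random.default_rng(0)
    for attempt in range(3):
        start = psi0 if attempt == 0 else psi0 + rng.normal(0, 0.5, size=psi0.shape)
        res = optimize.minimize(
            nll_grad,
            start,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-12, "gtol": 1e-7},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if best.success:
            break
    res = best
    beta, theta = unpack(res.x)
    loglik = -res.fun
    # L-BFGS-B can stop with a pessimistic status flag at a stationary point;
    # judge convergence by the gradient itself (bound dimensions excluded)
    grad_at_opt = nll_grad(res.x)[1]
    interior = np.ones(len(res.x), dtype=bool)
    if free_theta and (
        abs(res.x[p] - _LOGTHETA_BOUNDS[0]) < 1e-6
        or abs(res.x[p] - _LOGTHETA_BOUNDS[1]) < 1e-6
    ):
        interior[p] = False
    converged = bool(res.success) or float(
        np.max(np.abs(grad_at_opt[interior]), initial=0.0)
    ) < 1e-3 * max(1.0, abs(res.fun))

    hess = _numeric_hessian(lambda psi: nll_grad(psi)[1], res.x)
    se_full, cov_beta = _se_from_hessian(hess, p)
    se = se_full[:p]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    pvals = 2 * stats.norm.sf(np.abs(z))
    n_params = p + (1 if free_theta else 0)
    return BetaBinFit(
        names=names,
        coef=beta,
        se=se,
        z=z,
        p=pvals,
        loglik=float(loglik),
        theta=float(theta),
        variance_components={},
        aic=2 * n_params - 2 * loglik,
        n_obs=len(k),
        n_params=n_params,
        converged=converged,
        theta_fixed=not free_theta,
        message=str(res.message),
        cov=cov_beta,
    )


def _numeric_hessian(grad_fn, x, eps=1e-5):
    """Central-difference Hessian of a scalar objective from its gradient."""
    d = len(x)
    H = np.empty((d, d))
    for j in range(d):
        step = eps * max(1.0, abs(x[j]))
        xp = x.copy()
        xm = x.copy()
        xp[j] += step
        xm[j] -= step
        H[:, j] = (grad_fn(xp) - grad_fn(xm)) / (2 * step)
    return 0.5 * (H + H.T)


def _se_from_hessian(hess, p):
    """SEs from the inverse observed information; NaN where singular.

    Returns the full SE vector and the covariance of the first ``p``
    (coefficient) entries.
    """
    try:
        cov = np.linalg.inv(hess)
        d = np.diag(cov).copy()
        d[d < 0] = np.nan
        return np.sqrt(d), cov[:p, :p]
    except np.linalg.LinAlgError:
        return np.full(hess.shape[0], np.nan), None


# ---------------------------------------------------------------------------
# Laplace-approximated random-intercept model


class _FactorCoding:
    def __init__(self, name: str, labels: Sequence) -> None:
        self.name = name
        levels, codes = np.unique(np.asarray(labels), return_inverse=True)
        self.levels = levels
        self.codes = codes
        self.n_levels = len(levels)


def _random_eta(u, factors, offsets_q, n_rows):
    eta = np.zeros(n_rows)
    for fi, f in enumerate(factors):
        eta += u[offsets_q[fi] + f.codes]
    return eta


def _curvature(k, n, mu, theta, factors, offsets_q, q, inv_var):
    """-(Hessian) of the joint log-density over the random effects."""
    w = -_d2l_deta2(k, n, mu, theta)
    H = np.zeros((q, q))
    for fi, f in enumerate(factors):
        for fj, g in enumerate(factors):
            blk = np.zeros((f.n_levels, g.n_levels))
            np.add.at(blk, (f.codes, g.codes), w)
            H[offsets_q[fi]: offsets_q[fi + 1], offsets_q[fj]: offsets_q[fj + 1]] += blk
    return H + np.diag(inv_var)


def _laplace_neg_marginal(k, n, eta_fix, factors, beta_unused, theta, sigmas, u0, binom):
    """Laplace-approximated negative marginal log-likelihood and the mode.

    Inner maximization over the random effects by damped Newton with the
    analytic gradient and Hessian.
    """
    q = sum(f.n_levels for f in factors)
    offsets_q = np.cumsum([0] + [f.n_levels for f in factors])
    inv_var = np.concatenate(
        [np.full(f.n_levels, 1.0 / sigmas[fi] ** 2) for fi, f in enumerate(factors)]
    )
    u = u0.copy()

    def joint(u):
        mu = np.clip(
            _sigmoid(eta_fix + _random_eta(u, factors, offsets_q, len(k))),
            1e-12, 1 - 1e-12,
        )
        ll = _binom_logpmf(k, n, mu) if binom else betabinom_logpmf(k, n, mu, theta)
        return float(np.sum(ll) - 0.5 * np.sum(inv_var * u * u)), mu

    fval, mu = joint(u)
    for _ in range(100):
        deta = _dl_deta(k, n, mu, theta)
        grad = np.empty(q)
        for fi, f in enumerate(factors):
            grad[offsets_q[fi]: offsets_q[fi + 1]] = np.bincount(
                f.codes, weights=deta, minlength=f.n_levels
            )
        grad -= inv_var * u
        if np.max(np.abs(grad)) < 1e-9:
            break
        H = _curvature(k, n, mu, theta, factors, offsets_q, q, inv_var)
        lam = 0.0
        for _ in range(10):
            try:
                step = np.linalg.solve(H + lam * np.eye(q), grad)
            except np.linalg.LinAlgError:
                lam = max(1e-6, lam * 10)
                continue
            f_new, mu_new = joint(u + step)
            if f_new >= fval - 1e-12:
                u = u + step
                fval, mu = f_new, mu_new
                break
            lam = max(1e-6, lam * 10)
        else:
            break
    H = _curvature(k, n, mu, theta, factors, offsets_q, q, inv_var)
    log_prior_norm = -sum(
        f.n_levels * math.log(sigmas[fi]) for fi, f in enumerate(factors)
    ) - 0.5 * q * math.log(2 * math.pi)
    sign, logdet = np.linalg.slogdet(H)
    if sign <= 0:
        return 1e10, u
    marg = fval + log_prior_norm + 0.5 * q * math.log(2 * math.pi) - 0.5 * logdet
    return -marg, u


def betabin_mixed_loglik(
    k, n, X, grouping: dict, beta, theta: float, sigmas: dict, offset=None
) -> float:
    """Laplace marginal log-likelihood at fixed parameters (no fitting).

    ``sigmas`` maps each grouping-factor name to its random-intercept SD.
    Exposed for validation against exact quadrature on small problems.
    """
    k, n, X, off, _ = _prepare_design(k, n, X, offset, None)
    factors = [_FactorCoding(nm, labels) for nm, labels in grouping.items()]
    sig = np.array([float(sigmas[f.name]) for f in factors])
    q = sum(f.n_levels for f in factors)
    eta_fix = X @ np.asarray(beta, dtype=float) + off
    neg, _ = _laplace_neg_marginal(
        k, n, eta_fix, factors, None, float(theta), sig, np.zeros(q), False
    )
    return -neg


def fit_betabin_mixed(
    k,
    n,
    X,
    grouping: dict,
    offset=None,
    names: Optional[Sequence[str]] = None,
    theta_fixed: Optional[float] = None,
    max_iter: int = 500,
) -> BetaBinFit:
    """Beta-binomial regression with random intercepts per grouping factor.

    ``grouping`` maps a factor name to its per-row labels; each factor
    contributes i.i.d. N(0, sigma_f^2) intercepts which are integrated out by
    a Laplace approximation.  Estimation is ML over (beta, log theta,
    log sigma_f); variance-component estimates may sit at the (numerical)
    zero boundary.  With an empty ``grouping`` this is exactly
    :func:`fit_betabin_regression`.
    """
    if not grouping:
        return fit_betabin_regression(
            k, n, X, offset=offset, names=names, theta_fixed=theta_fixed,
            max_iter=max_iter,
        )
    k, n, X, off, names = _prepare_design(k, n, X, offset, names)
    p = X.shape[1]
    free_theta = theta_fixed is None
    binom = theta_fixed is not None and np.isinf(theta_fixed)
    factors = [_FactorCoding(nm, labels) for nm, labels in grouping.items()]
    q = sum(f.n_levels for f in factors)
    u_warm = {"u": np.zeros(q)}

    def unpack(psi):
        beta = psi[:p]
        i = p
        if free_theta:
            theta = math.exp(psi[i])
            i += 1
        else:
            theta = float(theta_fixed)
        sigmas = np.exp(psi[i:])
        return beta, theta, sigmas

    def neg_marginal(psi):
        beta, theta, sigmas = unpack(psi)
        neg, u = _laplace_neg_marginal(
            k, n, X @ beta + off, factors, None, theta, sigmas, u_warm["u"], binom
        )
        u_warm["u"] = u
        return neg

    n_sig = len(factors)
    psi0 = np.zeros(p + (1 if free_theta else 0) + n_sig)
    psi0[:p] = _start_beta(k, n, X, off)
    i = p
    if free_theta:
        psi0[i] = math.log(10.0)
        i += 1
    psi0[i:] = math.log(0.5)
    bounds = (
        [(None, None)] * p
        + ([_LOGTHETA_BOUNDS] if free_theta else [])
        + [_LOGSIGMA_BOUNDS] * n_sig
    )
    best = None
    rng = np.random.default_rng(0)
    for attempt in range(3):
        start = psi0 if attempt == 0 else psi0 + rng.normal(0, 0.3, size=psi0.shape)
        u_warm["u"] = np.zeros(q)
        res = optimize.minimize(
            neg_marginal,
            start,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-11},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if best.success:
            break
    res = best
    beta, theta, sigmas = unpack(res.x)
    loglik = -res.fun

    def grad_num(psi, eps=1e-4):
        g = np.empty(len(psi))
        for j in range(len(psi)):
            step = eps * max(1.0, abs(psi[j]))
            xp, xm = psi.copy(), psi.copy()
            xp[j] += step
            xm[j] -= step
            g[j] = (neg_marginal(xp) - neg_marginal(xm)) / (2 * step)
        return g

    # judge convergence by the gradient, ignoring bound-active coordinates
    interior = np.array(
        [lo is None or (res.x[j] - lo > 1e-6 and hi - res.x[j] > 1e-6)
         for j, (lo, hi) in enumerate(bounds)]
    )
    g_opt = grad_num(res.x)
    converged = bool(res.success) or float(
        np.max(np.abs(g_opt[interior]), initial=0.0)
    ) < 1e-3 * max(1.0, abs(res.fun))

    hess = _numeric_hessian(grad_num, res.x, eps=1e-3)
    se_full, cov_beta = _se_from_hessian(hess, p)
    se = se_full[:p]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.nan)
    pvals = 2 * stats.norm.sf(np.abs(z))
    n_params = p + (1 if free_theta else 0) + n_sig
    var_comps = {
        f.name: float(sigmas[fi] ** 2) for fi, f in enumerate(factors)
    }
    return BetaBinFit(
        names=names,
        coef=beta,
        se=se,
        z=z,
        p=pvals,
        loglik=float(loglik),
        theta=float(theta),
        variance_components=var_comps,
        aic=2 * n_params - 2 * loglik,
        n_obs=len(k),
        n_params=n_params,
        converged=converged,
        theta_fixed=not free_theta,
        message=str(res.message),
        cov=cov_beta,
    )


# ---------------------------------------------------------------------------
# Auxiliary tests and summaries


@dataclass(frozen=True)
class MixtureLRTResult:
    """Likelihood-ratio test against a chi-bar-square mixture null."""

    statistic: float
    weights: dict
    p_value: float


def mixture_lrt(
    loglik_full: float,
    loglik_reduced: float,
    df_weights: dict,
    tol: float = 1e-6,
) -> MixtureLRTResult:
    """LRT whose null is a weighted mixture of chi-square distributions.

    Used for parameters on the boundary of their space (variance components,
    overdispersion): ``X^2 = 2 * (loglik_full - loglik_reduced)`` and
    ``p = sum_d w_d P(chi2_d > X^2)``, with 0 df meaning a point mass at 0.
    Small negative ``X^2`` from numerical noise (within ``tol``) is clipped
    to 0.
    """
    weights = {int(d): float(w) for d, w in df_weights.items()}
    if abs(sum(weights.values()) - 1.0) > 1e-9:
        raise ValueError("mixture weights must sum to 1")
    x2 = 2.0 * (loglik_full - loglik_reduced)
    if x2 < -tol:
        raise ValueError(
            f"full-model log-likelihood below reduced ({x2 / 2:.6g}); fits inconsistent"
        )
    x2 = max(0.0, x2)
    if x2 == 0.0:
        p = 1.0
    else:
        p = sum(
            w * (stats.chi2.sf(x2, d) if d > 0 else 0.0) for d, w in weights.items()
        )
    return MixtureLRTResult(statistic=x2, weights=weights, p_value=float(p))


def pseudo_r2_lr(
    loglik_full: float, loglik_null: float, n_obs: int, rescale: bool = False
) -> float:
    """Likelihood-ratio pseudo-R^2 (Cox-Snell; Nagelkerke-rescaled if asked)."""
    if n_obs < 1:
        raise ValueError("n_obs must be >= 1")
    r2 = 1.0 - math.exp(-(2.0 / n_obs) * (loglik_full - loglik_null))
    if rescale:
        cap = 1.0 - math.exp((2.0 / n_obs) * loglik_null)
        r2 = r2 / cap if cap > 0 else float("nan")
    return r2


def pearson_correlation(x, y, rank: bool = False) -> tuple[float, float]:
    """Product-moment correlation with its two-sided t-based p-value.

    With ``rank=True`` the correlation is computed on the ranks of the data
    (i.e. Spearman's coefficient).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    if rank:
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


@dataclass
class RunCoefficientSummary:
    """One-sample t summary of a coefficient estimated once per run."""

    slopes: np.ndarray
    mean: float
    sem: float
    t: float
    p_value: float
    df: int
    degenerate: bool = False  # all slopes identical: t undefined


def summarize_across_runs(slopes: Sequence[float]) -> RunCoefficientSummary:
    slopes = np.asarray(slopes, dtype=float)
    slopes = slopes[np.isfinite(slopes)]
    if len(slopes) < 2:
        raise ValueError("need at least 2 finite per-run estimates")
    mean = float(np.mean(slopes))
    sem = float(np.std(slopes, ddof=1) / math.sqrt(len(slopes)))
    df = len(slopes) - 1
    if sem == 0:
        return RunCoefficientSummary(slopes, mean, 0.0, np.nan, np.nan, df, True)
    t = mean / sem
    p = 2 * stats.t.sf(abs(t), df)
    return RunCoefficientSummary(slopes, mean, sem, float(t), float(p), df)
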