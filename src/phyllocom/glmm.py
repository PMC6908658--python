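"""Random-intercept generalized linear mixed models by maximum likelihood.

Fits the model

    y_ij | b_j  ~  family(g^{-1}(x_ij' beta + b_j)),     b_j ~ N(0, sigma^2)

for a single grouping factor (here: time of collection), with canonical
links (logit for Bernoulli detection outcomes, log for Poisson richness).
The marginal likelihood integrates the random intercept out of each group's
contribution with Gauss-Hermite quadrature (default 25 nodes, more accurate
than a one-point Laplace approximation), and is maximised with L-BFGS-B
using the analytic score.  Wald tests use the numerically differentiated
observed information at the optimum.

Convergence failures — optimizer failure, coefficients running to the
boundary (quasi-separation), or a singular information matrix — are
reported in the result, never raised: a failed fit is a data point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, gammaln
from scipy.stats import norm
from statsmodels.tools.numdiff import approx_hess1

_ETA_MAX = 30.0  # linear-predictor clip: keeps exp() finite in Poisson steps
_COEF_MAX = 15.0  # |beta| beyond this is treated as separation


@dataclass
class GLMMResult:
    """Fitted fixed effects, Wald inference and bookkeeping for one model."""

    params: pd.Series
    se: pd.Series
    pvalues: pd.Series
    sigma_re: float
    loglike: float
    converged: bool
    message: str = ""
    n_obs: int = 0
    n_groups: int = 0
    family: str = "binomial"

    def wald_z(self) -> pd.Series:
        return self.params / self.se


def _family_funcs(family: str):
    if family == "binomial":

        def loglik(y, eta):
            return y * eta - np.logaddexp(0.0, eta)

        def mean(eta):
            return expit(eta)

    elif family == "poisson":

        def loglik(y, eta):
            return y * eta - np.exp(eta) - gammaln(y + 1.0)

        def mean(eta):
            return np.exp(eta)

    else:
        raise ValueError(f"unknown family: {family}")
    return loglik, mean


def fit_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    family: str = "binomial",
    exog_names: list[str] | None = None,
    n_quad: int = 25,
    start_params: np.ndarray | None = None,
) -> GLMMResult:
    """Fit a random-intercept GLMM by marginal maximum likelihood.

    Parameters
    ----------
    y, X, groups:
        Response vector, fixed-effect design matrix (including an intercept
        column), and grouping labels for the random intercept, all of length
        ``n``.
    family:
        ``"binomial"`` (Bernoulli, logit link) or ``"poisson"`` (log link).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    names = exog_names or [f"x{i}" for i in range(p)]
    _, group_codes = np.unique(np.asarray(groups), return_inverse=True)
    order = np.argsort(group_codes, kind="stable")
    y, X, group_codes = y[order], X[order], group_codes[order]
    n_groups = group_codes.max() + 1
    starts = np.searchsorted(group_codes, np.arange(n_groups))

    nodes, weights = hermgauss(n_quad)
    log_w = np.log(weights) - 0.5 * np.log(np.pi)
    loglik, mean = _family_funcs(family)

    nan = pd.Series(np.nan, index=names)

    def fail(msg: str) -> GLMMResult:
        return GLMMResult(
            params=nan.copy(), se=nan.copy(), pvalues=nan.copy(), sigma_re=np.nan,
            loglike=np.nan, converged=False, message=msg, n_obs=n,
            n_groups=int(n_groups), family=family,
        )

    if family == "binomial" and (y.min() == y.max()):
        return fail("degenerate response: all outcomes identical")

    def negloglike_and_grad(theta: np.ndarray):
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        b = np.sqrt(2.0) * sigma * nodes  # (K,)
        eta = np.clip(X @ beta, -_ETA_MAX, _ETA_MAX)[:, None] + b[None, :]  # (n,K)
        ll = loglik(y[:, None], eta)  # (n,K)
        l_jk = np.add.reduceat(ll, starts, axis=0)  # (J,K)
        a = l_jk + log_w[None, :]
        a_max = a.max(axis=1, keepdims=True)
        lse = a_max[:, 0] + np.log(np.exp(a - a_max).sum(axis=1))
        nll = -lse.sum()
        # score
        w_post = np.exp(a - lse[:, None])  # (J,K) posterior quadrature weights
        resid = y[:, None] - mean(eta)  # (n,K)
        grad = np.empty(len(theta))
        for j in range(len(beta)):
            g_jk = np.add.reduceat(resid * X[:, j : j + 1], starts, axis=0)
            grad[j] = -(w_post * g_jk).sum()
        g_sig = np.add.reduceat(resid, starts, axis=0) * (np.sqrt(2.0) * nodes * sigma)
        grad[-1] = -(w_post * g_sig).sum()
        return nll, grad

    if start_params is None:
        beta0 = _glm_start(y, X, family)
    else:
        beta0 = np.asarray(start_params, dtype=float)
    theta0 = np.concatenate([beta0, [np.log(0.5)]])
    bounds = [(-_COEF_MAX * 2, _COEF_MAX * 2)] * p + [(-8.0, 4.0)]
    try:
        opt = minimize(
            negloglike_and_grad, theta0, jac=True, method="L-BFGS-B",
            bounds=bounds, options={"maxiter": 300},
        )
    except (FloatingPointError, np.linalg.LinAlgError) as exc:
        return fail(f"optimizer error: {exc}")

    beta_hat = opt.x[:-1]
    sigma_hat = float(np.exp(opt.x[-1]))
    if not opt.success and "ABNORMAL" in str(opt.message):
        return fail(f"optimizer failed: {opt.message}")
    if not np.all(np.isfinite(opt.x)) or np.abs(beta_hat).max() > _COEF_MAX:
        return fail("coefficients at boundary (possible complete separation)")

    def nll_only(theta):
        return negloglike_and_grad(theta)[0]

    try:
        H = approx_hess1(opt.x, nll_only)
        cov = np.linalg.inv(H)
        var = np.diag(cov)[:p]
        if np.any(var <= 0) or not np.all(np.isfinite(var)):
            return fail("non-positive-definite information matrix")
        se = np.sqrt(var)
    except np.linalg.LinAlgError:
        return fail("singular information matrix")

    params = pd.Series(beta_hat, index=names)
    se_s = pd.Series(se, index=names)
    pvals = pd.Series(2.0 * norm.sf(np.abs(beta_hat) / se), index=names)
    return GLMMResult(
        params=params, se=se_s, pvalues=pvals, sigma_re=sigma_hat,
        loglike=-float(opt.fun), converged=True, message="ok", n_obs=n,
        n_groups=int(n_groups), family=family,
    )


def _glm_start(y: np.ndarray, X: np.ndarray, family: str) -> np.ndarray:
    """Fixed-effect starting values from a plain GLM fit."""
    import warnings

    import statsmodels.api as sm

    fam = sm.families.Binomial() if family == "binomial" else sm.families.Poisson()
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation in the *starting* GLM is expected and harmless: the
            # clipped estimate only seeds the mixed-model optimizer
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=fam).fit(maxiter=50)
        beta = np.asarray(res.params, dtype=float)
        if np.all(np.isfinite(beta)):
            return np.clip(beta, -_COEF_MAX, _COEF_MAX)
    except Exception:
        pass
    return np.zeros(X.shape[1])
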