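"""Mixed-model fitting: random-intercept logistic and Gaussian models.

The binomial (logit) mixed model with a single random intercept is fitted by
maximising the Gauss-Hermite-quadrature marginal likelihood -- the same
adaptive-free nAGQ approach used by standard mixed-model software -- with
analytic gradients and L-BFGS-B.  Wald standard errors come from the
observed information of the fixed effects at the optimum, conditional on the
estimated random-intercept SD (the usual mixed-model convention).  The
variance component is tested by a likelihood-ratio against the no-random-
effect GLM, with the 0.5*chi2(1) boundary mixture.

Gaussian mixed models are delegated to statsmodels MixedLM (ML fit, so the
same boundary LRT applies); a Gaussian offset simply shifts the response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import chi2, norm


@dataclass
class MixedFitResult:
    """Raw fitted quantities of a random-intercept mixed model."""

    params: np.ndarray
    bse: np.ndarray
    statistics: np.ndarray
    pvalues: np.ndarray
    term_names: list[str]
    random_sd: float
    random_p: float | None
    loglik: float
    converged: bool
    cov_params: np.ndarray
    model_type: str
    scale: float | None = None  # residual variance (Gaussian only)


@dataclass
class ModelFit:
    """Term table plus model-level summaries, mirroring a results table.

    ``terms`` has columns Variables, Type, Est, SE, t, p; fixed rows carry
    coefficients, the single Random row carries the variance-component LRT
    p-value.  ``deviance_explained_pct`` is 100*(1 - residual deviance of
    the fixed linear predictor / null deviance), i.e. conditional on the
    random effects set to zero.
    """

    terms: pd.DataFrame
    random_variance: float
    deviance_explained_pct: float | None
    model_type: str
    loglik: float | None = None
    converged: bool = True
    metadata: dict = field(default_factory=dict)
    raw: MixedFitResult | None = None


def _binom_loglik_parts(theta, X, y, offset, gidx, n_groups, nodes, logw):
    beta = theta[:-1]
    sigma = theta[-1]
    eta0 = X @ beta + offset
    shift = np.sqrt(2.0) * sigma * nodes
    eta = eta0[:, None] + shift[None, :]
    ll = y[:, None] * eta - np.logaddexp(0.0, eta)
    S = np.zeros((n_groups, nodes.size))
    np.add.at(S, gidx, ll)
    A = logw[None, :] + S
    Lg = logsumexp(A, axis=1)
    W = np.exp(A - Lg[:, None])
    resid = (y[:, None] - expit(eta)) * W[gidx]
    grad_beta = X.T @ resid.sum(axis=1)
    grad_sigma = float(resid.sum(axis=0) @ (np.sqrt(2.0) * nodes))
    return float(Lg.sum()), np.append(grad_beta, grad_sigma)


def fit_binomial_glmm(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    offset: np.ndarray | None = None,
    term_names: list[str] | None = None,
    n_quad: int = 25,
) -> MixedFitResult:
    """Random-intercept logistic regression by GH-quadrature ML.

    ``groups`` may be any label array; it is factorised internally.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    offset = np.zeros(n) if offset is None else np.asarray(offset, dtype=float)
    gidx, glabels = pd.factorize(np.asarray(groups))
    n_groups = len(glabels)
    if term_names is None:
        term_names = [f"x{j}" for j in range(p)]

    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    logw = np.log(weights) - 0.5 * np.log(np.pi)

    # fixed-effect start values from the plain GLM; also the sigma=0 reference
    import statsmodels.api as sm

    glm = sm.GLM(y, X, family=sm.families.Binomial(), offset=offset)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        glm_res = glm.fit()
    beta0 = np.asarray(glm_res.params)
    ll_glm = float(glm_res.llf)

    def objective(theta):
        ll, grad = _binom_loglik_parts(theta, X, y, offset, gidx, n_groups, nodes, logw)
        return -ll, -grad

    theta0 = np.append(beta0, 0.5)
    bounds = [(None, None)] * p + [(0.0, None)]
    opt = minimize(objective, theta0, jac=True, method="L-BFGS-B", bounds=bounds)
    theta = opt.x
    beta, sigma = theta[:-1], float(theta[-1])
    loglik = -float(opt.fun)

    # observed information of beta at (beta_hat, sigma_hat)
    hess = np.empty((p, p))
    eps = 1e-5 * np.maximum(1.0, np.abs(beta))
    for j in range(p):
        tp = theta.copy()
        tp[j] += eps[j]
        tm = theta.copy()
        tm[j] -= eps[j]
        _, gp = _binom_loglik_parts(tp, X, y, offset, gidx, n_groups, nodes, logw)
        _, gm = _binom_loglik_parts(tm, X, y, offset, gidx, n_groups, nodes, logw)
        hess[:, j] = -(gp[:p] - gm[:p]) / (2.0 * eps[j])
    hess = 0.5 * (hess + hess.T)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = np.where(bse > 0, beta / bse, np.nan)
    pvals = 2.0 * norm.sf(np.abs(zvals))

    if np.any((np.abs(beta) > 15) & (bse > 15)):
        warnings.warn(
            "possible complete separation: a coefficient and its SE are both huge",
            RuntimeWarning,
            stacklevel=2,
        )

    lrt = max(0.0, 2.0 * (loglik - ll_glm))
    random_p = 0.5 * float(chi2.sf(lrt, 1)) if sigma > 0 else 1.0

    return MixedFitResult(
        params=beta,
        bse=bse,
        statistics=zvals,
        pvalues=pvals,
        term_names=list(term_names),
        random_sd=sigma,
        random_p=random_p,
        loglik=loglik,
        converged=bool(opt.success),
        cov_params=cov,
        model_type="binomial",
    )


def fit_gaussian_lmm(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    offset: np.ndarray | None = None,
    term_names: list[str] | None = None,
) -> MixedFitResult:
    """Random-intercept Gaussian mixed model via statsmodels MixedLM (ML)."""
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if offset is not None:
        y = y - np.asarray(offset, dtype=float)
    if term_names is None:
        term_names = [f"x{j}" for j in range(p)]
    gidx, _ = pd.factorize(np.asarray(groups))

    # centre the response for optimizer stability; only the intercept shifts
    y_shift = float(np.mean(y))
    yc = y - y_shift
    intercept_col = int(np.argmax(np.all(X == 1.0, axis=0))) if np.any(
        np.all(X == 1.0, axis=0)
    ) else None

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(yc, X, groups=gidx)
        res = model.fit(reml=False)
        ols = sm.OLS(yc, X).fit()

    # the mixed model nests OLS at zero variance, so its ML log-likelihood
    # can never be lower; if it is, the optimiser failed on a boundary case
    # and the OLS fit *is* the ML fit
    use_ols = (
        not np.all(np.isfinite(np.asarray(res.fe_params)))
        or not np.isfinite(float(res.llf))
        or float(res.llf) < float(ols.llf) - 1e-6
    )
    if use_ols:
        params = np.asarray(ols.params)
        cov = np.asarray(ols.cov_params())
        re_var = 0.0
        loglik = float(ols.llf)
        scale = float(ols.scale)
        converged = True
    else:
        params = np.asarray(res.fe_params)
        cov = np.asarray(res.cov_params())[:p, :p]
        re_var = float(np.asarray(res.cov_re)[0, 0])
        loglik = float(res.llf)
        scale = float(res.scale)
        converged = bool(res.converged)

    if intercept_col is not None:
        params = params.copy()
        params[intercept_col] += y_shift
    bse = np.sqrt(np.diag(cov))
    tvals = params / bse
    pvals = 2.0 * norm.sf(np.abs(tvals))
    lrt = max(0.0, 2.0 * (loglik - float(ols.llf)))
    random_p = 0.5 * float(chi2.sf(lrt, 1)) if re_var > 0 else 1.0

    return MixedFitResult(
        params=params,
        bse=bse,
        statistics=tvals,
        pvalues=pvals,
        term_names=list(term_names),
        random_sd=float(np.sqrt(re_var)),
        random_p=random_p,
        loglik=loglik,
        converged=converged,
        cov_params=cov,
        model_type="gaussian",
        scale=scale,
    )


def binomial_deviance_explained(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, offset: np.ndarray | None = None
) -> float:
    """100*(1 - residual/null deviance) of the fixed linear predictor."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    offset = np.zeros(len(y)) if offset is None else np.asarray(offset, dtype=float)
    eta = X @ beta + offset
    dev_res = -2.0 * float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    # null: intercept-only logit with the same offset
    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        null = sm.GLM(
            y, np.ones((len(y), 1)), family=sm.families.Binomial(), offset=offset
        ).fit()
    dev_null = float(null.deviance)
    if dev_null <= 0:
        return 0.0
    return 100.0 * (1.0 - dev_res / dev_null)


def gaussian_deviance_explained(
    X: np.ndarray, y: np.ndarray, beta: np.ndarray, offset: np.ndarray | None = None
) -> float:
    """Fixed-part R**2 (in %) against the intercept-plus-offset null."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if offset is not None:
        y = y - np.asarray(offset, dtype=float)
    ssr = float(np.sum((y - X @ beta) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        return 0.0
    return 100.0 * (1.0 - ssr / sst)


def result_table(fit: MixedFitResult, random_label: str = "Random intercept") -> pd.DataFrame:
    """Results-table frame (Variables, Type, Est, SE, t, p) from a raw fit."""
    rows = [
        {
            "Variables": name,
            "Type": "Fixed",
            "Est": est,
            "SE": se,
            "t": stat,
            "p": p,
        }
        for name, est, se, stat, p in zip(
            fit.term_names, fit.params, fit.bse, fit.statistics, fit.pvalues
        )
    ]
    rows.append(
        {
            "Variables": random_label,
            "Type": "Random",
            "Est": np.nan,
            "SE": np.nan,
            "t": np.nan,
            "p": fit.random_p,
        }
    )
    return pd.DataFrame(rows)
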