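"""Random-intercept logistic regression via Gauss-Hermite quadrature.

Fits  y_ij ~ Bernoulli( sigmoid(x_ij' beta + u_j) ),  u_j ~ N(0, sigma^2)
with one random intercept per cluster (village), by maximising the
marginal likelihood.  The cluster integral is evaluated with fixed
Gauss-Hermite quadrature (default 25 nodes), which is accurate for the
moderate cluster sizes and intercept variances arising in village
cohorts.  Standard errors come from the numerical Hessian of the
marginal log-likelihood at the optimum; Wald z tests give p-values.

This is the maximum-likelihood counterpart of lme4::glmer with
``nAGQ`` quadrature; a cross-check against glmer lives in the test
suite.  Linear mixed models are delegated to statsmodels MixedLM
elsewhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = ["MixedLogitResult", "fit_logistic_random_intercept"]

_GH_POINTS = 25
_OPT_TOL = 1e-8


@dataclass
class MixedLogitResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    sigma_re: float
    loglike: float
    converged: bool
    n_obs: int
    n_groups: int
    flags: list[str] = field(default_factory=list)


def _group_starts(groups: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    order = np.argsort(groups, kind="mergesort")
    g = groups[order]
    starts = np.flatnonzero(np.r_[True, g[1:] != g[:-1]])
    return order, starts


def fit_logistic_random_intercept(
    X: pd.DataFrame,
    y,
    groups,
    n_points: int = _GH_POINTS,
    tol: float = _OPT_TOL,
) -> MixedLogitResult:
    """Fit the random-intercept logistic model by marginal ML.

    Parameters
    ----------
    X : design matrix including an intercept column
    y : binary outcome (0/1)
    groups : cluster labels (one random intercept level per label)
    """
    names = list(X.columns)
    Xm = np.asarray(X, dtype=float)
    yv = np.asarray(y, dtype=float)
    gv = pd.factorize(np.asarray(groups))[0]
    n, p = Xm.shape
    if n != len(yv) or n != len(gv):
        raise ValueError("X, y, groups must have equal length")
    if len(np.unique(gv)) < 2:
        raise ValueError("random intercept needs at least 2 clusters")
    rank = np.linalg.matrix_rank(Xm)
    if rank < p:
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {p} columns); "
            "a control duplicates another predictor"
        )

    order, starts = _group_starts(gv)
    Xo, yo = Xm[order], yv[order]
    sgn = (2.0 * yo - 1.0)[:, None]
    t_nodes, w_nodes = np.polynomial.hermite_e.hermegauss(n_points)
    # probabilists' Hermite: int f(u) phi(u) du ~ sum w_g/sqrt(2 pi) f(t_g)
    log_w = np.log(w_nodes) - 0.5 * np.log(2.0 * np.pi)

    def nll(theta: np.ndarray) -> float:
        beta, sigma = theta[:p], abs(theta[p])
        eta = Xo @ beta
        M = eta[:, None] + sigma * t_nodes[None, :]
        ll = -np.logaddexp(0.0, -sgn * M)              # n x G
        L = np.add.reduceat(ll, starts, axis=0)        # groups x G
        return -float(special.logsumexp(L + log_w[None, :], axis=1).sum())

    # start from the pooled logistic fit
    beta0 = _pooled_logistic(Xo, yo)
    theta0 = np.r_[beta0, 0.5]
    res = optimize.minimize(
        nll, theta0, method="L-BFGS-B",
        bounds=[(None, None)] * p + [(0.0, None)],
        options={"ftol": tol, "gtol": 1e-6, "maxiter": 500},
    )
    theta = res.x
    flags: list[str] = []
    if not res.success:
        flags.append(f"non_convergence:{res.message}")

    H = _num_hessian(nll, theta)
    bse = np.full(p + 1, np.nan)
    try:
        cov = np.linalg.inv(H)
        d = np.diag(cov)
        if (d <= 0).any():
            flags.append("hessian_not_pd")
        bse = np.sqrt(np.where(d > 0, d, np.nan))
    except np.linalg.LinAlgError:
        flags.append("singular_hessian")
    if np.abs(theta[:p]).max() > 15 or np.nanmax(bse[:p]) > 50:
        flags.append("possible_separation")

    z = theta[:p] / bse[:p]
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return MixedLogitResult(
        params=pd.Series(theta[:p], index=names),
        bse=pd.Series(bse[:p], index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma_re=float(abs(theta[p])),
        loglike=-float(res.fun),
        converged=bool(res.success),
        n_obs=n,
        n_groups=int(len(starts)),
        flags=flags,
    )


def _pooled_logistic(X: np.ndarray, y: np.ndarray, n_iter: int = 25) -> np.ndarray:
    """Newton iterations for a plain logistic fit (starting values)."""
    beta = np.zeros(X.shape[1])
    for _ in range(n_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu) + 1e-10
        grad = X.T @ (y - mu)
        H = (X * W[:, None]).T @ X + 1e-8 * np.eye(X.shape[1])
        step = np.linalg.solve(H, grad)
        beta = beta + step
        if np.abs(step).max() < 1e-10:
            break
        np.clip(beta, -20, 20, out=beta)
    return beta


def _num_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Central-difference Hessian (parameters are O(1) after standardization)."""
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    steps = eps * np.maximum(1.0, np.abs(x))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = steps[i]
            ej = np.zeros(k); ej[j] = steps[j]
            fpp = f(x + ei + ej)
            fpm = f(x + ei - ej)
            fmp = f(x - ei + ej)
            fmm = f(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * steps[i] * steps[j])
    _ = f0
    return H
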