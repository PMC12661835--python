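"""Random-intercept logistic regression by Gauss-Hermite quadrature.

Fits the mixed model  y_ij ~ Bernoulli(sigmoid(x_ij' beta + u_i)),
u_i ~ N(0, sigma^2) i.i.d. per cluster, by maximizing the marginal
likelihood with the cluster-level integral evaluated by Gauss-Hermite
quadrature.  Wald standard errors come from the numerically differentiated
observed information at the optimum.  This is the estimation core behind the
augmentation-benefit model, where the dataset is the clustering factor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import norm


@dataclass
class MixedLogitResult:
    names: list[str]
    estimates: np.ndarray  # fixed effects, intercept first
    std_errors: np.ndarray
    p_values: np.ndarray
    sigma_u: float  # random-intercept SD
    loglik: float
    converged: bool
    flagged_separation: bool

    def odds_ratios(self, level: float = 0.95) -> dict[str, tuple[float, float, float]]:
        """Per-coefficient (OR, lower, upper) from Wald CIs on the link scale."""
        z = norm.ppf(0.5 + level / 2.0)
        out = {}
        for name, est, se in zip(self.names, self.estimates, self.std_errors):
            out[name] = (
                float(np.exp(est)),
                float(np.exp(est - z * se)),
                float(np.exp(est + z * se)),
            )
        return out


def _neg_loglik(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                cluster_slices: list[np.ndarray], nodes: np.ndarray,
                log_weights: np.ndarray) -> float:
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    eta = X @ beta
    total = 0.0
    for idx in cluster_slices:
        # (n_i, K) linear predictor with each quadrature offset
        shifted = eta[idx, None] + sigma * nodes[None, :]
        ll = y[idx, None] * shifted - np.logaddexp(0.0, shifted)
        total += logsumexp(log_weights + ll.sum(axis=0))
    return -total


def _neg_loglik_grad(theta: np.ndarray, X: np.ndarray, y: np.ndarray,
                     cluster_slices: list[np.ndarray], nodes: np.ndarray,
                     log_weights: np.ndarray) -> tuple[float, np.ndarray]:
    """Value and analytic gradient of the negative marginal log-likelihood."""
    beta, log_sigma = theta[:-1], theta[-1]
    sigma = np.exp(log_sigma)
    eta = X @ beta
    total = 0.0
    grad = np.zeros_like(theta)
    for idx in cluster_slices:
        shifted = eta[idx, None] + sigma * nodes[None, :]
        p = expit(shifted)
        ll = y[idx, None] * shifted - np.logaddexp(0.0, shifted)
        log_terms = log_weights + ll.sum(axis=0)
        li = logsumexp(log_terms)
        total += li
        alpha = np.exp(log_terms - li)  # posterior quadrature weights
        resid = y[idx, None] - p  # (n_i, K)
        grad[:-1] += X[idx].T @ (resid @ alpha)
        grad[-1] += sigma * float(alpha @ (nodes * resid.sum(axis=0)))
    return -total, -grad


def _numeric_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    p = len(x)
    H = np.zeros((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = eps
            ej = np.zeros(p); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps * eps)
    return H


def fit_mixed_logit(
    X: np.ndarray,
    y: np.ndarray,
    clusters: np.ndarray,
    names: list[str] | None = None,
    n_quad: int = 25,
    add_intercept: bool = True,
) -> MixedLogitResult:
    """Maximum (marginal) likelihood fit of the random-intercept logit.

    ``X`` excludes the intercept column unless ``add_intercept`` is False.
    Requires >= 2 clusters and both outcome values present.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    clusters = np.asarray(clusters)
    uniq = np.unique(clusters)
    if len(uniq) < 2:
        raise ValueError("at least 2 clusters are required")
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome values must be present")
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["intercept"] + list(names or [f"x{i+1}" for i in range(X.shape[1] - 1)])
    else:
        names = list(names or [f"x{i+1}" for i in range(X.shape[1])])

    cluster_slices = [np.flatnonzero(clusters == c) for c in uniq]
    # probabilists' Hermite nodes integrate against the standard normal density
    nodes, weights = hermegauss(n_quad)
    log_weights = np.log(weights) - 0.5 * np.log(2 * np.pi)

    # start at the pooled logistic fit, sigma = 0.5
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression(C=np.inf, max_iter=2000).fit(X[:, 1:] if add_intercept else X, y)
    beta0 = (
        np.concatenate([lr.intercept_, lr.coef_.ravel()])
        if add_intercept
        else lr.coef_.ravel()
    )
    theta0 = np.concatenate([beta0, [np.log(0.5)]])

    nll = lambda t: _neg_loglik(t, X, y, cluster_slices, nodes, log_weights)
    obj = lambda t: _neg_loglik_grad(t, X, y, cluster_slices, nodes, log_weights)
    res = minimize(obj, theta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": 500, "gtol": 1e-7, "ftol": 1e-12})

    theta = res.x
    H = _numeric_hessian(nll, theta)
    p = X.shape[1]
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0, None))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    est = theta[:p]
    zstat = np.divide(est, se, out=np.full(p, np.nan), where=se > 0)
    pvals = 2 * norm.sf(np.abs(zstat))
    flagged = bool(np.max(np.abs(est)) > 30 or np.any(~np.isfinite(se)))
    return MixedLogitResult(
        names=names,
        estimates=est,
        std_errors=se,
        p_values=pvals,
        sigma_u=float(np.exp(theta[-1])),
        loglik=float(-res.fun),
        converged=bool(res.success),
        flagged_separation=flagged,
    )
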