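"""Gaussian multilevel interval regression (censoring-aware mixed model).

The model is

    y_ij = x_ij' beta + b_i + eps_ij,  b_i ~ N(0, sd_b^2),  eps ~ N(0, sd^2)

where observation j of group (participant) i is either *exact* (the density
contributes) or known only to lie in an interval [lower, upper] (the normal
probability of the interval contributes; either bound may be infinite).
The marginal likelihood integrates the random intercept with Gauss-Hermite
quadrature and is maximized directly with L-BFGS-B on
(beta, log sd, log sd_b). Fixed-effect covariances come from the inverse
observed information (numerical Hessian) at the optimum; per-group random
effects are reported as posterior means under the fitted parameters.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize
from scipy.special import log_ndtr, logsumexp
from scipy.stats import truncnorm
from sklearn.base import BaseEstimator
from statsmodels.tools.numdiff import approx_hess

_LOG_2PI = np.log(2.0 * np.pi)


def _log_interval_prob(zl: np.ndarray, zu: np.ndarray) -> np.ndarray:
    """log(Phi(zu) - Phi(zl)), numerically stable in both tails."""
    # exploit symmetry: P(zl < Z < zu) = P(-zu < Z < -zl)
    flip = (zl + zu) > 0
    zl_, zu_ = np.where(flip, -zu, zl), np.where(flip, -zl, zu)
    hi = log_ndtr(zu_)
    lo = log_ndtr(zl_)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = hi + np.log1p(-np.exp(np.minimum(lo - hi, 0.0)))
    return np.where(np.isneginf(zl_) & np.isposinf(zu_), 0.0, out)


def truncated_normal_mean(mu, sigma, lower, upper):
    """Mean of N(mu, sigma^2) truncated to [lower, upper] (bounds may be inf)."""
    mu = np.asarray(mu, dtype=float)
    a = (np.asarray(lower, dtype=float) - mu) / sigma
    b = (np.asarray(upper, dtype=float) - mu) / sigma
    with np.errstate(all="ignore"):
        m = truncnorm.mean(a, b, loc=mu, scale=sigma)
    # numerical fallback deep in a tail: clamp to the nearer bound
    bad = ~np.isfinite(m)
    if np.any(bad):
        lo = np.broadcast_to(lower, mu.shape)
        hi = np.broadcast_to(upper, mu.shape)
        near_lo = np.abs(mu - lo) >= np.abs(mu - hi)
        m = np.where(bad & near_lo, hi, m)
        m = np.where(bad & ~near_lo, lo, m)
    return m


class IntervalRegression(BaseEstimator):
    """Multilevel interval regression with a Gaussian random intercept.

    Parameters
    ----------
    n_quad : int
        Adaptive Gauss-Hermite nodes for the random-effect integral.
    fit_intercept : bool
        Prepend an unpenalized intercept column.
    tol : float
        Relative log-likelihood convergence tolerance.

    Attributes (after fit)
    ----------------------
    intercept_, coef_ : fixed effects
    sigma_ : residual SD
    group_sd_ : random-intercept SD
    loglik_ : maximized marginal log-likelihood
    coef_cov_ : covariance of (intercept, coef) from the observed information
    ranef_ : dict group -> posterior mean random effect
    """

    def __init__(
        self,
        n_quad: int = 15,
        fit_intercept: bool = True,
        tol: float = 1e-8,
        max_iter: int = 500,
    ):
        self.n_quad = n_quad
        self.fit_intercept = fit_intercept
        self.tol = tol
        self.max_iter = max_iter

    # ---- likelihood ---------------------------------------------------
    def _design(self, X):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X

    def _loglik_terms(self, mu, sigma, b_obs_nodes, exact, lower, upper):
        """(N, K) per-observation log-likelihood at each (group-specific)
        quadrature node position."""
        shift = mu[:, None] + b_obs_nodes
        terms = np.empty_like(shift)
        if exact.any():
            z = (lower[exact, None] - shift[exact]) / sigma  # y == lower
            terms[exact] = -0.5 * z**2 - np.log(sigma) - 0.5 * _LOG_2PI
        if (~exact).any():
            zl = (lower[~exact, None] - shift[~exact]) / sigma
            zu = (upper[~exact, None] - shift[~exact]) / sigma
            terms[~exact] = _log_interval_prob(zl, zu)
        return terms

    def _group_node_loglik(self, theta, X, exact, lower, upper, starts, gidx):
        """Adaptive Gauss-Hermite: (G, K) log-integrand at group-centred
        nodes, plus the node positions and Jacobian terms.

        Nodes are centred at a closed-form Laplace approximation of each
        group's posterior mode (from its exact observations), which keeps
        the quadrature accurate when the posterior is much narrower than
        the random-effect prior. Rows must be sorted by group."""
        p = X.shape[1]
        sigma = np.exp(theta[p])
        sd_b = np.exp(theta[p + 1])
        nodes, logw = self._nodes
        mu = X @ theta[:p]

        resid = np.where(exact, lower - mu, 0.0)
        n_exact = np.add.reduceat(exact.astype(float), starts)
        sum_resid = np.add.reduceat(resid, starts)
        prec = 1.0 / sd_b**2 + n_exact / sigma**2
        b_hat = (sum_resid / sigma**2) / prec
        s_hat = 1.0 / np.sqrt(prec)

        b_gk = b_hat[:, None] + np.sqrt(2.0) * s_hat[:, None] * nodes[None, :]
        terms = self._loglik_terms(mu, sigma, b_gk[gidx], exact, lower, upper)
        group_sums = np.add.reduceat(terms, starts, axis=0)
        log_prior = (
            -0.5 * (b_gk / sd_b) ** 2 - np.log(sd_b) - 0.5 * _LOG_2PI
        )
        log_integrand = (
            logw[None, :]
            + nodes[None, :] ** 2
            + log_prior
            + group_sums
            + 0.5 * np.log(2.0)
            + np.log(s_hat)[:, None]
        )
        return log_integrand, b_gk

    def _negloglik(self, theta, X, exact, lower, upper, starts, gidx):
        per_group, _ = self._group_node_loglik(
            theta, X, exact, lower, upper, starts, gidx
        )
        return -float(logsumexp(per_group, axis=1).sum())

    # ---- API ----------------------------------------------------------
    def fit(self, X, lower, upper, groups):
        """Fit by maximum marginal likelihood.

        ``lower == upper`` marks an exact observation; otherwise the
        observation contributes P(lower < y < upper).
        """
        Xd = self._design(X)
        lower = np.asarray(lower, dtype=float)
        upper = np.asarray(upper, dtype=float)
        groups = np.asarray(groups)
        if np.any(lower > upper):
            raise ValueError("interval lower bound exceeds upper bound")
        exact_all = np.isfinite(lower) & (lower == upper)
        if not exact_all.any():
            raise ValueError(
                "all observations are censored; the model is not identifiable"
            )

        nodes, weights = np.polynomial.hermite.hermgauss(self.n_quad)
        self._nodes = (nodes, np.log(weights))

        # sort rows by group so block sums can use reduceat
        order = np.argsort(groups, kind="stable")
        Xs, lo, up = Xd[order], lower[order], upper[order]
        exact = exact_all[order]
        gsorted = groups[order]
        group_ids, starts, gidx = np.unique(
            gsorted, return_index=True, return_inverse=True
        )

        # pseudo-values for starting betas
        pseudo = np.where(
            exact,
            lo,
            np.where(
                np.isfinite(lo) & np.isfinite(up),
                (lo + up) / 2.0,
                np.where(np.isfinite(lo), lo + 1.0, up - 1.0),
            ),
        )
        beta0, *_ = np.linalg.lstsq(Xs, pseudo, rcond=None)
        resid = pseudo - Xs @ beta0
        sd0 = max(float(np.std(resid)), 1e-2)
        gmeans = np.array([resid[gsorted == g].mean() for g in group_ids])
        sdb0 = max(float(np.std(gmeans)), 1e-2)

        theta0 = np.concatenate([beta0, [np.log(sd0), np.log(sdb0)]])
        p = Xd.shape[1]
        args = (Xs, exact, lo, up, starts, gidx)
        bounds = [(None, None)] * p + [(np.log(1e-4), np.log(1e3)),
                                       (np.log(1e-6), np.log(1e3))]
        result = minimize(
            self._negloglik,
            theta0,
            args=args,
            method="L-BFGS-B",
            bounds=bounds,
            options={
                "maxiter": self.max_iter,
                "ftol": self.tol,
                "gtol": 1e-8,
                "maxfun": 20000,
            },
        )
        # polish with higher-order finite differences near the optimum;
        # judged by gradient norm, not the (precision-limited) status flag
        polish = minimize(
            self._negloglik,
            result.x,
            args=args,
            method="L-BFGS-B",
            jac="3-point",
            bounds=bounds,
            options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-10, "maxfun": 20000},
        )
        if polish.fun <= result.fun:
            result = polish
        grad_norm = float(np.max(np.abs(result.jac)))
        if not result.success and grad_norm > 1e-2:
            raise RuntimeError(
                f"interval regression did not converge: {result.message}; "
                f"|grad|={grad_norm:.3g}, theta={result.x}"
            )
        theta = result.x
        self.n_features_in_ = Xd.shape[1] - int(self.fit_intercept)
        if self.fit_intercept:
            self.intercept_ = float(theta[0])
            self.coef_ = theta[1:p].copy()
        else:
            self.intercept_ = 0.0
            self.coef_ = theta[:p].copy()
        self.sigma_ = float(np.exp(theta[p]))
        self.group_sd_ = float(np.exp(theta[p + 1]))
        self.loglik_ = -float(result.fun)
        self.converged_ = True

        # observed information for the fixed effects
        try:
            H = approx_hess(theta, self._negloglik, args=args)
            cov = np.linalg.pinv(H)
            self.coef_cov_ = cov[:p, :p]
        except np.linalg.LinAlgError:
            self.coef_cov_ = np.full((p, p), np.nan)

        # posterior mean random effects
        per_group, b_gk = self._group_node_loglik(theta, *args)
        w = np.exp(per_group - logsumexp(per_group, axis=1, keepdims=True))
        post_mean = np.sum(w * b_gk, axis=1)
        self.ranef_ = {g: float(m) for g, m in zip(group_ids, post_mean)}
        self.groups_ = group_ids
        return self

    def predict(self, X, groups=None):
        """Conditional prediction x'beta (+ posterior-mean random effect)."""
        Xd = self._design(X)
        mu = Xd @ np.concatenate([[self.intercept_], self.coef_]) if self.fit_intercept \
            else Xd @ self.coef_
        if groups is not None:
            mu = mu + np.array([self.ranef_.get(g, 0.0) for g in np.asarray(groups)])
        return mu

    def adjustment_variance(self, X):
        """Variance of x' beta_hat (slope part only, intercept excluded)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            cov = self.coef_cov_[1:, 1:]
        else:
            cov = self.coef_cov_
        return np.einsum("ij,jk,ik->i", X, cov, X)
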