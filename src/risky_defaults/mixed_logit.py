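"""Logistic mixed-effects regression via a Laplace-approximate marginal
likelihood.

Model: y_it ~ Bernoulli(logit^-1(x_it' b + z_it' g_i)), with per-subject
random effects g_i ~ N(0, D), D diagonal (uncorrelated random intercept and
slopes).  The marginal log-likelihood integrates g_i out with a Laplace
approximation around the per-subject posterior mode (the same approximation
lme4::glmer uses at nAGQ=1); the outer optimisation over fixed effects and
random-effect SDs is deterministic (L-BFGS-B from a pooled-GLM start).

The fit exposes the maximised marginal log-likelihood, so nested models can
be compared with likelihood-ratio tests, which the backward model-selection
procedure requires.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = ["MixedLogitResult", "ConvergenceError", "fit_mixed_logit"]


class ConvergenceError(RuntimeError):
    """Optimiser failed; consider simplifying the random-effects structure
    (e.g. dropping random slopes) or checking for complete separation."""


@dataclass
class MixedLogitResult:
    fe_names: list[str]
    coef: np.ndarray
    se: np.ndarray
    zvalues: np.ndarray
    pvalues: np.ndarray
    re_names: list[str]
    re_sd: np.ndarray
    loglik: float
    n_obs: int
    n_groups: int
    converged: bool

    def coef_table(self):
        import pandas as pd

        return pd.DataFrame(
            {"coef": self.coef, "se": self.se, "z": self.zvalues, "p": self.pvalues},
            index=self.fe_names,
        )


def _expit(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _group_sums(gidx, n_groups, *vals):
    return [np.bincount(gidx, weights=v, minlength=n_groups) for v in vals]


def _bernoulli_ll(eta, y):
    # sum y*log(sigma(eta)) + (1-y)*log(1-sigma(eta)), overflow-safe
    return -np.sum(np.logaddexp(0.0, eta) - y * eta)


def _laplace_loglik(beta, sd, X, Z, y, gidx, n_groups, b):
    """Laplace marginal log-likelihood; refines b (S x q) in place."""
    q = Z.shape[1]
    sd = np.maximum(sd, _SD_FLOOR)
    d_inv = 1.0 / (sd * sd)
    xb = X @ beta

    def pen_ll(bmat):
        eta = xb + np.einsum("ij,ij->i", Z, bmat[gidx])
        return _bernoulli_ll(eta, y) - 0.5 * np.sum(bmat * bmat * d_inv[None, :])

    cur = pen_ll(b)
    for _ in range(200):
        eta = xb + np.einsum("ij,ij->i", Z, b[gidx])
        mu = _expit(eta)
        w = mu * (1.0 - mu) + 1e-12
        resid = y - mu
        grad = np.column_stack(
            _group_sums(gidx, n_groups, *(Z[:, j] * resid for j in range(q)))
        ) - b * d_inv[None, :]
        H = np.empty((n_groups, q, q))
        for j in range(q):
            for k in range(j, q):
                s = np.bincount(gidx, weights=Z[:, j] * Z[:, k] * w, minlength=n_groups)
                H[:, j, k] = s
                H[:, k, j] = s
        H[:, np.arange(q), np.arange(q)] += d_inv[None, :]
        step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
        # damped Newton
        alpha = 1.0
        for _ in range(12):
            cand = b + alpha * step
            new = pen_ll(cand)
            if new >= cur - 1e-12:
                break
            alpha *= 0.5
        b[...] = b + alpha * step
        moved = np.max(np.abs(alpha * step))
        cur = pen_ll(b)
        if moved < 1e-9:
            break

    # Laplace: pen_ll(b_hat) - S * sum(log sd) - 1/2 sum_g log det H_g
    eta = xb + np.einsum("ij,ij->i", Z, b[gidx])
    mu = _expit(eta)
    w = mu * (1.0 - mu) + 1e-12
    H = np.empty((n_groups, q, q))
    for j in range(q):
        for k in range(j, q):
            s = np.bincount(gidx, weights=Z[:, j] * Z[:, k] * w, minlength=n_groups)
            H[:, j, k] = s
            H[:, k, j] = s
    H[:, np.arange(q), np.arange(q)] += d_inv[None, :]
    sign, logdet = np.linalg.slogdet(H)
    ll = cur - n_groups * np.sum(np.log(sd)) - 0.5 * np.sum(logdet)
    return ll


_SD_FLOOR = 1e-6
_SD_BOUNDS = (0.0, 20.0)


def fit_mixed_logit(
    y,
    X,
    Z,
    groups,
    fe_names=None,
    re_names=None,
    start=None,
) -> MixedLogitResult:
    """Fit the logistic GLMM.

    Parameters
    ----------
    y : (n,) 0/1 responses.
    X : (n, p) fixed-effects design (include the intercept column).
    Z : (n, q) random-effects design per subject (include the intercept).
    groups : (n,) subject labels.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    _, gidx = np.unique(np.asarray(groups), return_inverse=True)
    n_groups = int(gidx.max()) + 1
    n, p = X.shape
    q = Z.shape[1]
    if not (set(np.unique(y)) <= {0.0, 1.0}):
        raise ValueError("responses must be coded 0/1")
    if len({0.0, 1.0} & set(np.unique(y))) < 2:
        raise ValueError("both choice values (0 and 1) must be present")
    fe_names = list(fe_names) if fe_names is not None else [f"x{j}" for j in range(p)]
    re_names = list(re_names) if re_names is not None else [f"z{j}" for j in range(q)]

    if start is None:
        # pooled logistic regression start (IRLS, few steps)
        beta0 = np.zeros(p)
        for _ in range(25):
            mu = _expit(X @ beta0)
            w = mu * (1.0 - mu) + 1e-9
            try:
                delta = np.linalg.solve(
                    X.T @ (X * w[:, None]) + 1e-8 * np.eye(p), X.T @ (y - mu)
                )
            except np.linalg.LinAlgError:
                break
            beta0 += delta
            if np.max(np.abs(delta)) < 1e-8:
                break
        x0 = np.concatenate([beta0, np.full(q, 0.5)])
    else:
        x0 = np.asarray(start, dtype=float)

    b_cache = np.zeros((n_groups, q))

    def nll(theta):
        beta, sd = theta[:p], np.clip(theta[p:], *_SD_BOUNDS)
        ll = _laplace_loglik(beta, sd, X, Z, y, gidx, n_groups, b_cache)
        return -ll if np.isfinite(ll) else 1e12

    bounds = [(None, None)] * p + [list(_SD_BOUNDS)] * q
    opts = {"maxiter": 300, "ftol": 1e-12, "gtol": 1e-8}
    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds, options=opts)
    # polish: restart once from the solution (escapes premature termination
    # on the flat variance ridge)
    res2 = optimize.minimize(nll, res.x, method="L-BFGS-B", bounds=bounds, options=opts)
    if res2.fun <= res.fun:
        res = res2
    gmax = np.max(np.abs(res.jac)) if res.jac is not None else np.inf
    converged = bool(res.success or gmax < 5e-3 * max(1.0, abs(res.fun)))
    if not np.isfinite(res.fun) or not converged:
        raise ConvergenceError(
            f"mixed logistic fit did not converge ({res.message}; "
            f"max|grad|={gmax:.3g}); try dropping random slopes or check "
            "for complete separation"
        )

    theta = res.x
    # observed-information SEs from a finite-difference Hessian of nll
    m = p + q
    h = 1e-4 * np.maximum(np.abs(theta), 1.0)
    Hm = np.zeros((m, m))
    f0 = nll(theta)
    fp_ = np.zeros(m)
    for i in range(m):
        ti = theta.copy()
        ti[i] += h[i]
        fp_[i] = nll(ti)
    for i in range(m):
        for j in range(i, m):
            tij = theta.copy()
            tij[i] += h[i]
            tij[j] += h[j]
            fij = nll(tij)
            Hm[i, j] = Hm[j, i] = (fij - fp_[i] - fp_[j] + f0) / (h[i] * h[j])
    try:
        cov = np.linalg.pinv(Hm)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0.0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
    coef = theta[:p]
    with np.errstate(divide="ignore", invalid="ignore"):
        z = coef / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return MixedLogitResult(
        fe_names=fe_names,
        coef=coef,
        se=se,
        zvalues=z,
        pvalues=pvals,
        re_names=re_names,
        re_sd=np.clip(theta[p:], *_SD_BOUNDS),
        loglik=float(-res.fun),
        n_obs=n,
        n_groups=n_groups,
        converged=converged,
    )
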