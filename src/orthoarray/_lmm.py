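"""Gaussian random-intercept linear mixed model, fit by maximum likelihood.

The fitting scheme is an alternation between generalized-least-squares
updates of the fixed effects given the variance components and exact
(balanced case) or EM (unbalanced case) updates of the variance components
given the fixed effects, iterated until the log-likelihood is stationary.
The grouped covariance structure (sigma2_eps * I + sigma2_ind * J per
group) admits closed-form inverses and determinants, so no generic matrix
factorizations of the full covariance are ever formed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

VAR_FLOOR = 1e-8


@dataclass
class LmmFit:
    """Result of one maximum-likelihood random-intercept fit."""

    beta: np.ndarray
    sigma2_ind: float
    sigma2_eps: float
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int

    @property
    def n_params(self) -> int:
        return self.beta.size + 2


def _group_stats(groups: np.ndarray):
    """Return (n_groups, group_sizes) for a 0..I-1 coded group vector."""
    n_groups = int(groups.max()) + 1 if groups.size else 0
    sizes = np.bincount(groups, minlength=n_groups).astype(float)
    return n_groups, sizes


def _loglik(e: np.ndarray, groups: np.ndarray, sizes: np.ndarray,
            s2g: float, s2e: float) -> float:
    n = e.size
    gsum = np.bincount(groups, weights=e, minlength=sizes.size)
    sq = float(e @ e)
    lam = s2e + sizes * s2g
    ssb = float(np.sum(gsum ** 2 / sizes))
    ssw = sq - ssb
    quad = ssw / s2e + float(np.sum(gsum ** 2 / sizes ** 2 * sizes / lam))
    logdet = float(np.sum((sizes - 1.0) * np.log(s2e) + np.log(lam)))
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet + quad)


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    *,
    tol: float = 1e-8,
    max_iter: int = 200,
    var_floor: float = VAR_FLOOR,
    fixed_variances: tuple[float, float] | None = None,
) -> LmmFit:
    """Maximize the Gaussian likelihood of ``y = X beta + gamma[group] + eps``.

    Parameters
    ----------
    y, X, groups
        Response vector, full-column-rank design matrix, and integer group
        codes (0..I-1) for the random intercept.
    fixed_variances
        Optional ``(sigma2_ind, sigma2_eps)``; when given, only the GLS fixed
        effects are computed (single pass), which is the profiled-likelihood
        oracle used in the tests.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    n = y.size
    n_groups, sizes = _group_stats(groups)
    balanced = bool(np.all(sizes == sizes[0]))

    # group sums of X columns and of y
    S = np.zeros((n_groups, X.shape[1]))
    np.add.at(S, groups, X)
    XtX = X.T @ X
    Xty = X.T @ y

    def gls_beta(s2g, s2e):
        c = s2g / (s2e + sizes * s2g)  # shrinkage weight per group
        t = np.bincount(groups, weights=y, minlength=n_groups)
        A = XtX - S.T @ (c[:, None] * S)
        b = Xty - S.T @ (c * t)
        try:
            return np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return np.linalg.lstsq(A, b, rcond=None)[0]

    if fixed_variances is not None:
        s2g, s2e = (max(fixed_variances[0], var_floor),
                    max(fixed_variances[1], var_floor))
        beta = gls_beta(s2g, s2e)
        e = y - X @ beta
        ll = _loglik(e, groups, sizes, s2g, s2e)
        return LmmFit(beta, s2g, s2e, ll, True, 1, n)

    # init from OLS
    beta = np.linalg.lstsq(X, y, rcond=None)[0]
    e = y - X @ beta
    v0 = max(float(e @ e) / max(n, 1), 10 * var_floor)
    s2e, s2g = max(0.9 * v0, var_floor), max(0.1 * v0, var_floor)

    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        beta = gls_beta(s2g, s2e)
        e = y - X @ beta
        gsum = np.bincount(groups, weights=e, minlength=n_groups)
        ssw = float(e @ e) - float(np.sum(gsum ** 2 / sizes))

        if balanced:
            # exact joint ML of the variance components given beta
            m = sizes[0]
            s2e = max(ssw / max(n - n_groups, 1), var_floor)
            lam = float(np.sum(gsum ** 2 / sizes)) / n_groups  # = mean m*ebar^2
            if (lam - s2e) / m > var_floor:
                s2g = (lam - s2e) / m
            else:
                # boundary: sigma2_ind at the floor, residual takes all of it
                s2g = var_floor
                s2e = max(float(e @ e) / n, var_floor)
        else:
            # one EM step on the variance components
            lam = s2e + sizes * s2g
            gam = s2g * gsum / lam          # BLUP of the random intercepts
            vcond = s2g * s2e / lam         # conditional variances
            s2g = max(float(np.mean(gam ** 2 + vcond)), var_floor)
            resid2 = float(e @ e) - 2.0 * float(gam @ gsum) \
                + float(np.sum(sizes * gam ** 2))
            s2e = max((resid2 + float(np.sum(sizes * vcond))) / n, var_floor)

        ll = _loglik(e, groups, sizes, s2g, s2e)
        if abs(ll - ll_old) < tol:
            converged = True
            ll_old = ll
            break
        ll_old = ll

    return LmmFit(beta, float(s2g), float(s2e), float(ll_old), converged, it, n)
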