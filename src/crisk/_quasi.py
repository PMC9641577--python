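"""Logit-link estimating equations for pseudo-value responses.

Pseudo-values can lie outside [0, 1], so a binomial likelihood is
inapplicable.  With a constant working variance the GEE score
X' diag(mu'(eta)) (theta - mu) = 0 is exactly the gradient of the nonlinear
least-squares objective sum (theta_i - expit(x_i'gamma))^2, which is solved
with scipy's trust-region least-squares machinery.  Standard errors come
from the robust sandwich estimator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, special


@dataclass
class QuasiFit:
    coef: np.ndarray
    cov: np.ndarray
    converged: bool
    grad_norm: float
    n_iter: int

    @property
    def se(self):
        return np.sqrt(np.diag(self.cov))


def fit_pseudo_glm(X, theta, start=None, tol=1e-12):
    """Solve the logit-link, constant-working-variance estimating equations.

    X includes any intercept column.  Raises RuntimeError on failure to
    reduce the score below a loose threshold.
    """
    X = np.asarray(X, dtype=float)
    theta = np.asarray(theta, dtype=float)
    n, p = X.shape
    if start is None:
        mbar = float(np.clip(theta.mean(), 1e-6, 1 - 1e-6))
        start = np.zeros(p)
        # crude intercept start if a constant column exists
        const = np.where(np.all(X == X[0], axis=0) & (np.abs(X[0]) > 0))[0]
        if const.size:
            start[const[0]] = special.logit(mbar) / X[0, const[0]]

    def resid(g):
        return theta - special.expit(X @ g)

    def jac(g):
        mu = special.expit(X @ g)
        return -(mu * (1 - mu))[:, None] * X

    sol = optimize.least_squares(resid, start, jac=jac, xtol=tol, ftol=tol,
                                 gtol=tol, method="lm" if n >= p else "trf")
    g = sol.x
    mu = special.expit(X @ g)
    w = mu * (1 - mu)
    score_i = (w * (theta - mu))[:, None] * X
    grad_norm = float(np.linalg.norm(score_i.sum(axis=0)))
    if grad_norm > 1e-4 * max(1.0, float(np.abs(theta).sum())):
        raise RuntimeError(
            f"estimating equations not solved; final score norm {grad_norm:.3e}")
    # sandwich: B^{-1} M B^{-1} with bread B = X' diag(w^2) X (Gauss-Newton
    # approximation of the derivative of the score) and meat M = sum g_i g_i'
    bread = (X * (w ** 2)[:, None]).T @ X
    meat = score_i.T @ score_i
    try:
        binv = np.linalg.inv(bread)
        cov = binv @ meat @ binv
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return QuasiFit(coef=g, cov=cov, converged=bool(sol.success),
                    grad_norm=grad_norm, n_iter=int(sol.nfev))
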