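"""Random-effects meta-analysis of per-cluster performance metrics.

Between-practice heterogeneity tau^2 is estimated by restricted maximum
likelihood; pooled estimates are inverse-variance means with weights
1/(se_k^2 + tau^2).  Each metric is pooled on the scale on which its
sampling distribution is closest to normal: ln(O/E) for the
observed:expected ratio, logit(C) with delta-method SEs for the
concordance statistic, and the identity scale for Royston's D.  95%
prediction intervals use the t_{k-2} convention, widening the confidence
interval by tau^2 to describe performance expected in a new practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "reml_random_effects",
    "prediction_interval",
    "pool_metric",
    "MetaResult",
]


def _restricted_loglik(tau2, y, v):
    w = 1.0 / (v + tau2)
    mu = np.sum(w * y) / np.sum(w)
    return -0.5 * (np.sum(np.log(v + tau2)) + np.log(np.sum(w))
                   + np.sum(w * (y - mu) ** 2))


def reml_random_effects(effects, ses):
    """REML estimate of (pooled effect, SE of pooled, tau^2).

    ``effects`` and ``ses`` are per-cluster estimates and standard errors on
    the pooling scale.  tau^2 maximises the restricted log-likelihood over
    [0, upper]; the boundary value 0 is returned whenever the observed
    dispersion does not exceed sampling dispersion.
    """
    y = np.asarray(effects, dtype=float)
    v = np.asarray(ses, dtype=float) ** 2
    if len(y) < 2:
        raise ValueError("need at least 2 clusters")
    if np.any(v <= 0) or np.any(~np.isfinite(v)) or np.any(~np.isfinite(y)):
        raise ValueError("standard errors must be positive and finite")
    upper = max(10.0 * float(np.var(y, ddof=1)), 10.0 * float(np.max(v)),
                1e-8)
    res = optimize.minimize_scalar(
        lambda t2: -_restricted_loglik(t2, y, v),
        bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-12})
    tau2 = float(res.x)
    # snap to the boundary when the likelihood is flat toward zero
    if _restricted_loglik(0.0, y, v) >= _restricted_loglik(tau2, y, v) - 1e-10:
        tau2 = 0.0
    w = 1.0 / (v + tau2)
    pooled = float(np.sum(w * y) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return pooled, se, tau2


def tau2_profile_ci(effects, ses, level=0.95):
    """Profile-likelihood CI for tau^2 from the restricted log-likelihood."""
    y = np.asarray(effects, dtype=float)
    v = np.asarray(ses, dtype=float) ** 2
    _, _, tau2 = reml_random_effects(effects, ses)
    ll_max = _restricted_loglik(tau2, y, v)
    cut = ll_max - stats.chi2.ppf(level, 1) / 2.0

    def g(t2):
        return _restricted_loglik(t2, y, v) - cut

    lo = 0.0
    if tau2 > 0 and g(0.0) < 0:
        lo = float(optimize.brentq(g, 0.0, tau2))
    hi = tau2 if tau2 > 0 else 1e-10
    step = max(tau2, float(np.var(y, ddof=1)), 1e-6)
    while g(hi + step) > 0 and step < 1e6:
        hi += step
        step *= 2
    hi = float(optimize.brentq(g, max(tau2, 1e-12), hi + step))
    return lo, hi


def prediction_interval(pooled, se, tau2, k, level=0.95):
    """95% prediction interval pooled +/- t_{k-2} sqrt(tau^2 + se^2)."""
    if k < 3:
        raise ValueError("prediction interval requires k >= 3 clusters")
    tcrit = stats.t.ppf(0.5 + level / 2.0, k - 2)
    half = tcrit * np.sqrt(tau2 + se ** 2)
    return pooled - half, pooled + half


@dataclass
class MetaResult:
    metric: str
    scale: str
    pooled: float
    ci: tuple
    pi: tuple
    tau2: float
    tau2_ci: tuple
    k: int
    n_excluded: int = 0

    def as_row(self):
        return {
            "metric": self.metric, "scale": self.scale, "pooled": self.pooled,
            "ci_lower": self.ci[0], "ci_upper": self.ci[1],
            "pi_lower": self.pi[0], "pi_upper": self.pi[1],
            "tau2": self.tau2, "tau2_ci_lower": self.tau2_ci[0],
            "tau2_ci_upper": self.tau2_ci[1], "k": self.k,
            "n_excluded": self.n_excluded,
        }


_SCALES = {
    "oe": ("log", "oe", "se_ln_oe"),
    "c": ("logit", "c", "se_c"),
    "d": ("identity", "d", "se_d"),
}


def pool_metric(per_practice: pd.DataFrame, metric: str, level=0.95):
    """Pool a per-practice metric on its conventional scale.

    ``metric`` is one of 'oe' (pooled on the natural log scale), 'c'
    (logit scale with delta-method SEs, SE(logit C) = SE(C)/(C(1-C))) or
    'd' (identity scale).  Practices whose transform is undefined (O <= 0,
    C in {0, 1}, missing SEs) are excluded and counted.
    """
    if metric not in _SCALES:
        raise KeyError(f"unknown metric {metric!r}")
    scale, col, se_col = _SCALES[metric]
    est = per_practice[col].to_numpy(dtype=float)
    se = per_practice[se_col].to_numpy(dtype=float)

    ok = np.isfinite(est) & np.isfinite(se) & (se > 0)
    if scale == "log":
        ok &= est > 0
    elif scale == "logit":
        ok &= (est > 0) & (est < 1)
    n_excl = int(len(est) - ok.sum())
    if n_excl:
        warnings.warn(f"{n_excl} practices excluded from pooling of "
                      f"{metric!r}")
    est, se = est[ok], se[ok]
    if len(est) < 2:
        raise ValueError("fewer than 2 poolable practices")

    if scale == "log":
        y, s = np.log(est), se    # se already on the log scale
    elif scale == "logit":
        y = special.logit(est)
        s = se / (est * (1.0 - est))
    else:
        y, s = est, se

    pooled, pse, tau2 = reml_random_effects(y, s)
    z = stats.norm.ppf(0.5 + level / 2.0)
    ci = (pooled - z * pse, pooled + z * pse)
    pi = prediction_interval(pooled, pse, tau2, len(y), level) \
        if len(y) >= 3 else (float("nan"), float("nan"))
    try:
        t2ci = tau2_profile_ci(y, s, level)
    except (ValueError, RuntimeError):
        t2ci = (float("nan"), float("nan"))

    back = {"log": np.exp, "logit": special.expit,
            "identity": lambda x: x}[scale]
    return MetaResult(
        metric=metric, scale=scale, pooled=float(back(pooled)),
        ci=tuple(float(back(x)) for x in ci),
        pi=tuple(float(back(x)) for x in pi),
        tau2=float(tau2), tau2_ci=t2ci, k=int(len(y)), n_excluded=n_excl,
    )
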