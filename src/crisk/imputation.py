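"""Multiple imputation by chained equations with competing-risks covariates.

The imputation models include, besides all model covariates, the
Nelson-Aalen estimates of the cumulative baseline cause-specific hazards
for the primary and the competing event evaluated at each patient's own
follow-up time, together with binary event indicators -- the standard way
of carrying a censored competing-risks outcome into the imputation model.

Continuous variables are imputed by stochastic linear regression with
Bayesian parameter draws (predictive-mean-matching offered as a variant);
categorical variables by multinomial logistic draws.  Results are pooled
with Rubin's rules, or summarised by the median and interquartile range
when the normal-approximation pooling does not apply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "nelson_aalen_covariates",
    "mice_impute",
    "rubin_pool",
    "median_iqr_pool",
    "ImputedStack",
    "PooledEstimate",
]


def nelson_aalen_covariates(outcomes: pd.DataFrame) -> pd.DataFrame:
    """Cumulative cause-specific hazards at each patient's follow-up time.

    H_k(t) = sum over cause-k event times t_j <= t of d_kj / n_j with n_j
    the at-risk count.  Returns a frame aligned with ``outcomes`` holding
    H1(T_i), H2(T_i) and the binary event indicators d1_i, d2_i.
    """
    time = outcomes["time"].to_numpy(dtype=float)
    event = outcomes["event"].to_numpy()
    if np.any(time <= 0):
        raise ValueError("follow-up times must be positive")
    order = np.argsort(time, kind="stable")
    t_s = time[order]
    uniq, start = np.unique(t_s, return_index=True)
    n_risk = len(t_s) - start
    bounds = np.append(start, len(t_s))
    e_s = event[order]
    h = {}
    for k in (1, 2):
        d = np.array([np.sum(e_s[bounds[j]:bounds[j + 1]] == k)
                      for j in range(len(uniq))], dtype=float)
        cum = np.cumsum(d / n_risk)
        idx = np.searchsorted(uniq, time, side="right") - 1
        h[k] = np.where(idx >= 0, cum[np.clip(idx, 0, None)], 0.0)
    return pd.DataFrame({
        "na_hazard_1": h[1], "na_hazard_2": h[2],
        "event_1": (event == 1).astype(int),
        "event_2": (event == 2).astype(int),
    }, index=outcomes.index)


@dataclass
class ImputedStack:
    """m completed copies of a cohort plus the per-variable method record."""

    m: int
    copies: list
    methods: dict = field(default_factory=dict)
    seed: int | None = None

    def __iter__(self):
        return iter(self.copies)


def _design_matrix(df, columns):
    """Numeric design from mixed columns (categoricals one-hot, drop-first)."""
    parts = [np.ones((len(df), 1))]
    for c in columns:
        col = df[c]
        if col.dtype.kind in "ifb":
            parts.append(col.to_numpy(dtype=float)[:, None])
        else:
            dummies = pd.get_dummies(col.astype("object"), drop_first=True)
            parts.append(dummies.to_numpy(dtype=float))
    return np.hstack(parts)


def _impute_continuous(y, X, miss, rng, pmm=False, pmm_k=5):
    """Stochastic linear imputation with Bayesian parameter draws."""
    obs = ~miss
    Xo, yo = X[obs], y[obs]
    beta, _, _, _ = np.linalg.lstsq(Xo, yo, rcond=None)
    resid = yo - Xo @ beta
    dof = max(len(yo) - X.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    # draw sigma^2 from its scaled inverse chi^2, then beta | sigma^2
    sigma2_star = sigma2 * dof / rng.chisquare(dof)
    xtx_inv = np.linalg.pinv(Xo.T @ Xo)
    beta_star = rng.multivariate_normal(beta, sigma2_star * xtx_inv,
                                        method="svd")
    pred_mis = X[miss] @ beta_star
    if pmm:
        pred_obs = Xo @ beta_star
        out = np.empty(pred_mis.shape)
        for i, pm in enumerate(pred_mis):
            near = np.argsort(np.abs(pred_obs - pm))[:pmm_k]
            out[i] = yo[rng.choice(near)]
        return out
    return pred_mis + rng.normal(0.0, np.sqrt(sigma2_star), miss.sum())


def _impute_categorical(y, X, miss, rng, ridge=1e-4, n_iter=100):
    """Multinomial logistic imputation via ridge-stabilised Newton IRLS."""
    obs = ~miss
    levels, y_codes = np.unique(y[obs].astype(str), return_inverse=True)
    k = len(levels)
    if k == 1:
        return np.repeat(levels[0], miss.sum())
    Xo = X[obs]
    n, p = Xo.shape
    W = np.zeros((p, k - 1))
    Y = np.zeros((n, k - 1))
    for j in range(k - 1):
        Y[:, j] = y_codes == j + 1
    for _ in range(n_iter):
        eta = Xo @ W
        ex = np.exp(eta - eta.max(axis=1, keepdims=True) * 0)
        denom = 1.0 + ex.sum(axis=1, keepdims=True)
        P = ex / denom
        grad = Xo.T @ (Y - P) - ridge * W
        # diagonal-block Newton step per class (working approximation)
        step = np.empty_like(W)
        for j in range(k - 1):
            w = P[:, j] * (1 - P[:, j]) + 1e-10
            H = (Xo * w[:, None]).T @ Xo + ridge * np.eye(p)
            step[:, j] = np.linalg.solve(H, grad[:, j])
        W += step
        if np.max(np.abs(step)) < 1e-8:
            break
    eta_m = X[miss] @ W
    ex = np.exp(eta_m)
    denom = 1.0 + ex.sum(axis=1, keepdims=True)
    probs = np.hstack([1.0 / denom, ex / denom])
    draws = np.array([rng.choice(k, p=pr / pr.sum()) for pr in probs])
    # column order: class 0 (reference) first, then classes 1..k-1
    return levels[draws]


def mice_impute(cohort: pd.DataFrame, m=10, predictors=None,
                extra_covariates=None, seed=0, n_cycles=10,
                methods=None) -> ImputedStack:
    """Chained-equation multiple imputation.

    Parameters
    ----------
    cohort : frame with missing values confined to predictor variables.
    m : number of completed copies (default 10).
    predictors : columns usable as imputation-model covariates; defaults to
        every column except identifiers.
    extra_covariates : optional frame (e.g. the Nelson-Aalen hazard
        covariates and event indicators) appended to every imputation model.
    methods : optional per-variable override, 'pmm' selects
        predictive-mean matching for a continuous variable.

    Each copy starts from random draws of the observed values and runs
    ``n_cycles`` chained cycles; observed cells are identical across copies.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    with_missing = [c for c in cohort.columns if cohort[c].isna().any()]
    for c in with_missing:
        if cohort[c].isna().all():
            raise ValueError(f"variable {c!r} is 100% missing")
    if predictors is None:
        predictors = [c for c in cohort.columns
                      if c not in ("patient_id", "practice_id")]
    methods = dict(methods or {})
    extra = extra_covariates.reset_index(drop=True) \
        if extra_covariates is not None else None

    rng = np.random.default_rng(seed)
    copies = []
    method_record = {}
    for _ in range(m):
        work = cohort.reset_index(drop=True).copy()
        miss_masks = {c: work[c].isna().to_numpy() for c in with_missing}
        # initial fill: random draws from the observed margin
        for c in with_missing:
            obs_vals = work[c].dropna().to_numpy()
            fill = rng.choice(obs_vals, size=miss_masks[c].sum())
            work.loc[miss_masks[c], c] = fill
        for _cycle in range(n_cycles):
            for c in with_missing:
                miss = miss_masks[c]
                covs = [p for p in predictors if p != c and p in work]
                X = _design_matrix(work, covs)
                if extra is not None:
                    X = np.hstack([X, extra.to_numpy(dtype=float)])
                if cohort[c].dtype.kind in "if" and methods.get(c) != "multinomial":
                    y = work[c].to_numpy(dtype=float)
                    work.loc[miss, c] = _impute_continuous(
                        y, X, miss, rng, pmm=methods.get(c) == "pmm")
                    method_record[c] = methods.get(c, "stochastic_linear")
                else:
                    y = work[c].to_numpy()
                    vals = _impute_categorical(y, X, miss, rng)
                    work.loc[miss, c] = vals
                    method_record[c] = "multinomial_logistic"
        # restore integer-like dtypes where the source was integer
        for c in with_missing:
            if cohort[c].dtype.kind == "i":
                work[c] = work[c].astype(cohort[c].dtype)
        copies.append(work)
    return ImputedStack(m=m, copies=copies, methods=method_record, seed=seed)


@dataclass
class PooledEstimate:
    """Rubin's-rules combination of m estimates.

    T = W + (1 + 1/m) B with W the mean within-imputation variance and B
    the between-imputation variance of the estimates; degrees of freedom
    follow the classical (m-1)(1 + W/((1+1/m)B))^2 formula.
    """

    estimate: float
    within: float
    between: float
    total: float
    df: float
    m: int

    @property
    def se(self):
        return float(np.sqrt(self.total))


def rubin_pool(estimates, variances) -> PooledEstimate:
    """Pool m point estimates and their variances by Rubin's rules."""
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    m = len(est)
    if m < 2:
        raise ValueError("Rubin's rules require m >= 2")
    qbar = float(np.mean(est))
    w = float(np.mean(var))
    b = float(np.var(est, ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b > 0:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
    else:
        df = float("inf")
    return PooledEstimate(estimate=qbar, within=w, between=b, total=t,
                          df=df, m=m)


def median_iqr_pool(values):
    """Median and interquartile range across imputations."""
    v = np.asarray(values, dtype=float)
    if len(v) < 1:
        raise ValueError("need at least one value")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    return float(med), float(q3 - q1)
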