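"""Fine-Gray subdistribution hazard model.

Estimates the effect of covariates on the cumulative incidence of a primary
event (cause 1) in the presence of a competing event (cause 2), following the
subdistribution-hazard formulation: subjects who experience the competing
event remain in the risk set after their event time, down-weighted by the
inverse probability of censoring w_i(t) = G(t-)/G(min(T_i, t)-), where G is
the Kaplan-Meier estimate of the censoring survival function.

The weighted partial likelihood is maximised by damped Newton iterations
starting at beta = 0; ties among cause-1 event times use the Breslow
approximation, matching the Breslow-type baseline cumulative-incidence
estimator returned alongside the coefficients.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StepFunction",
    "FpTransform",
    "FineGrayResult",
    "censoring_km",
    "fit_finegray",
    "predict_cif",
    "select_fractional_polynomial",
    "schoenfeld_check",
    "fp_basis",
    "FP_POWERS",
]

FP_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


class ConvergenceError(RuntimeError):
    pass


class StepFunction:
    """Right-continuous step function with optional left limits.

    ``times`` are the jump locations (sorted); ``values`` the value attained
    at and after each jump.  Before the first jump the function equals
    ``init``.
    """

    def __init__(self, times, values, init=1.0):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        self.init = float(init)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-d and aligned")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("times must be sorted")

    def __call__(self, t, side="right"):
        """Evaluate at t; side='left' gives the left limit f(t-)."""
        t = np.asarray(t, dtype=float)
        which = "right" if side == "right" else "left"
        idx = np.searchsorted(self.times, t, side=which) - 1
        out = np.where(idx >= 0, self.values[np.clip(idx, 0, None)], self.init)
        return out if out.ndim else float(out)


def censoring_km(time, event):
    """Kaplan-Meier estimate of the censoring survival function G(t).

    Censoring (event == 0) is treated as the event of interest; actual
    events of either cause act as censoring of the censoring process.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    uniq, start = np.unique(t_s, return_index=True)
    n = len(t_s)
    surv = []
    g = 1.0
    at_risk = n
    bounds = np.append(start, n)
    for j, tj in enumerate(uniq):
        block = e_s[bounds[j]:bounds[j + 1]]
        d_cens = int(np.sum(block == 0))
        if d_cens > 0 and at_risk > 0:
            g *= 1.0 - d_cens / at_risk
        surv.append(g)
        at_risk -= len(block)
    return StepFunction(uniq, np.array(surv), init=1.0)


# ---------------------------------------------------------------------------
# fractional polynomials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FpTransform:
    """Fractional-polynomial transform of one continuous variable.

    ``powers`` is a tuple of one (FP1) or two (FP2) powers from the standard
    set {-2, -1, -0.5, 0, 0.5, 1, 2, 3}; power 0 denotes ln(x) and a repeated
    power (p, p) denotes {x^p, x^p * ln(x)}.  ``shift`` and ``scale`` map the
    raw variable onto a strictly positive range before the transform.
    """

    variable: str
    powers: tuple = (1.0,)
    shift: float = 0.0
    scale: float = 1.0

    def column_names(self):
        return [f"{self.variable}__fp{i + 1}" for i in range(len(self.powers))]

    def __post_init__(self):
        if not 1 <= len(self.powers) <= 2:
            raise ValueError("powers must have length 1 or 2")
        for p in self.powers:
            if p not in FP_POWERS:
                raise ValueError(f"power {p} not in standard FP set")


def _fp_term(x, p):
    return np.log(x) if p == 0 else x ** p


def fp_basis(x, powers, shift=0.0, scale=1.0):
    """Evaluate FP basis columns at x; returns array (n, len(powers))."""
    x = (np.asarray(x, dtype=float) + shift) / (scale if scale else 1.0)
    powers = tuple(powers)
    # positive domain needed for logs, roots, negative powers, and for the
    # repeated-power ln(x) factor; plain positive integer powers are global
    needs_positive = len(set(powers)) < len(powers) or any(
        p not in (1.0, 2.0, 3.0) for p in powers)
    if needs_positive and np.any(x <= 0):
        raise ValueError(
            "fractional polynomial requires strictly positive values; "
            "supply a shift"
        )
    cols = [_fp_term(x, powers[0])]
    if len(powers) == 2:
        if powers[1] == powers[0]:
            cols.append(_fp_term(x, powers[0]) * np.log(x))
        else:
            cols.append(_fp_term(x, powers[1]))
    return np.column_stack(cols)


def _all_power_sets(max_degree=2):
    sets = [(p,) for p in FP_POWERS]
    if max_degree >= 2:
        sets += [tuple(c) for c in
                 itertools.combinations_with_replacement(FP_POWERS, 2)]
    return sets


# ---------------------------------------------------------------------------
# model fit
# ---------------------------------------------------------------------------

@dataclass
class FineGrayResult:
    """Fitted subdistribution-hazard model.

    ``coef`` holds log subdistribution hazard ratios for the (centred,
    transformed) design columns; ``baseline_hazard`` is the Breslow-type
    cumulative subdistribution hazard H0(t) at the covariate centring point,
    so the baseline cumulative incidence is CIF0(t) = 1 - exp(-H0(t)).
    """

    columns: list
    coef: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    centering: np.ndarray
    baseline_hazard: StepFunction
    transforms: dict = field(default_factory=dict)
    n: int = 0
    n_events: int = 0
    loglik: float = float("nan")
    n_iter: int = 0
    grad_norm: float = float("nan")

    @property
    def shr(self):
        return np.exp(self.coef)

    def baseline_cif(self, t):
        return 1.0 - np.exp(-np.asarray(self.baseline_hazard(t)))

    def linear_predictor(self, X):
        X = np.asarray(X, dtype=float)
        return (X - self.centering) @ self.coef

    def summary(self):
        return pd.DataFrame(
            {"coef": self.coef, "shr": self.shr, "se": self.se},
            index=self.columns,
        )


def build_design(df, covariates, transforms=None, exclude=()):
    """Assemble the model design matrix, applying FP transforms.

    ``transforms`` maps variable name -> FpTransform; transformed variables
    contribute their FP basis columns in place of the raw column.
    ``exclude`` drops covariates (the explicit, user-controlled pruning used
    instead of any automated selection).
    """
    transforms = transforms or {}
    cols, names = [], []
    for var in covariates:
        if var in exclude:
            continue
        if var in transforms:
            tr = transforms[var]
            basis = fp_basis(df[var].to_numpy(), tr.powers, tr.shift, tr.scale)
            for j, nm in enumerate(tr.column_names()):
                cols.append(basis[:, j])
                names.append(nm)
        else:
            cols.append(df[var].to_numpy(dtype=float))
            names.append(var)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


def _fg_sums(X, time_s, event_s, eta_s, ginv_left, g_left_at_event,
             ev_pos_first):
    """Risk-set sums S0/S1/S2 at each distinct cause-1 event time.

    Exploits the separability of the IPC weights: a cause-2 subject with
    event at s < t contributes G(t-)/G(s-) * exp(eta), so the weighted tail
    factorises into G(t-) times a running sum of exp(eta)/G(s-).
    """
    e = np.exp(eta_s)
    eX = e[:, None] * X
    eXX = eX[:, :, None] * X[:, None, :]

    # natural risk set: subjects with T_i >= t (reverse cumulative sums)
    r0 = np.cumsum(e[::-1])[::-1]
    r1 = np.cumsum(eX[::-1], axis=0)[::-1]
    r2 = np.cumsum(eXX[::-1], axis=0)[::-1]

    # cause-2 tail: subjects with cause-2 event strictly before t
    is2 = event_s == 2
    tail_w = np.where(is2, e * ginv_left, 0.0)
    a0c = np.cumsum(tail_w)
    a1c = np.cumsum(tail_w[:, None] * X, axis=0)
    a2c = np.cumsum((tail_w[:, None] * X)[:, :, None] * X[:, None, :], axis=0)

    j = ev_pos_first            # first sorted index at each distinct event time
    # subjects strictly before t_j in sorted order: indices < j; but sorted
    # ties share times, so "strictly before t_j" means index < first index
    # with that time.
    prev = j - 1
    a0 = np.where(prev >= 0, a0c[np.clip(prev, 0, None)], 0.0)
    a1 = np.where(prev[:, None] >= 0, a1c[np.clip(prev, 0, None)], 0.0)
    a2 = np.where(prev[:, None, None] >= 0, a2c[np.clip(prev, 0, None)], 0.0)

    g = g_left_at_event
    s0 = r0[j] + g * a0
    s1 = r1[j] + g[:, None] * a1
    s2 = r2[j] + g[:, None, None] * a2
    return s0, s1, s2


def _fg_loglik_parts(X_s, time_s, event_s, beta, ginv_left, g_left_at_event):
    """Breslow partial log-likelihood, score and information."""
    n, p = X_s.shape
    eta = X_s @ beta
    eta = np.clip(eta, -200, 200)

    is1 = event_s == 1
    ev_times = time_s[is1]
    uniq_t, first_idx_in_ev = np.unique(ev_times, return_index=True)
    # position of first sorted record with time >= each distinct event time
    ev_pos_first = np.searchsorted(time_s, uniq_t, side="left")
    d_counts = np.diff(np.append(first_idx_in_ev, len(ev_times)))

    s0, s1, s2 = _fg_sums(X_s, time_s, event_s, eta, ginv_left,
                          g_left_at_event, ev_pos_first)

    # sums over events at each distinct time
    xb_events = float(np.sum(eta[is1]))
    x_events = X_s[is1]
    # accumulate per distinct time
    grp = np.searchsorted(uniq_t, ev_times)
    x_sum = np.zeros((len(uniq_t), p))
    np.add.at(x_sum, grp, x_events)

    ll = xb_events - float(np.sum(d_counts * np.log(s0)))
    mean = s1 / s0[:, None]
    score = np.sum(x_sum - d_counts[:, None] * mean, axis=0)
    info = np.einsum(
        "j,jkl->kl", d_counts,
        s2 / s0[:, None, None] - mean[:, :, None] * mean[:, None, :],
    )
    return ll, score, info, (uniq_t, d_counts, s0)


def fit_finegray(df, duration_col, event_col, covariates, transforms=None,
                 exclude=(), max_iter=100, tol=1e-9):
    """Fit the subdistribution-hazard model by IPCW-weighted partial likelihood.

    Parameters
    ----------
    df : DataFrame with one row per patient; no missing values in the model
        columns (run once per imputed copy).
    duration_col, event_col : follow-up time (> 0) and event code
        {0 censored, 1 primary, 2 competing}.
    covariates : list of column names entering the linear predictor.
    transforms : optional dict of FpTransform for continuous variables.
    exclude : covariates dropped by the explicit pruning list.

    Returns FineGrayResult with coefficients (log-SHRs), model-based SEs from
    the inverse observed information, and the Breslow-type baseline
    cumulative subdistribution hazard at the centring point.
    """
    X, names = build_design(df, covariates, transforms, exclude)
    time = df[duration_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy()
    if np.any(time <= 0):
        raise ValueError("durations must be positive")
    if not np.any(event == 1):
        raise ValueError("at least one cause-1 event required")
    center = X.mean(axis=0)
    Xc = X - center

    order = np.argsort(time, kind="stable")
    X_s, time_s, event_s = Xc[order], time[order], np.asarray(event)[order]

    # collinearity check
    if X_s.shape[1]:
        rank = np.linalg.matrix_rank(X_s)
        if rank < X_s.shape[1]:
            u, s, vt = np.linalg.svd(X_s, full_matrices=False)
            bad = np.where(np.abs(vt[-1]) > 1e-6)[0]
            raise np.linalg.LinAlgError(
                "collinear covariates: " + ", ".join(names[i] for i in bad)
            )

    G = censoring_km(time, event)
    g_left = np.asarray(G(time_s, side="left"))
    ginv_left = np.where(g_left > 0, 1.0 / np.clip(g_left, 1e-300, None), 0.0)

    is1 = event_s == 1
    uniq_t = np.unique(time_s[is1])
    g_left_ev = np.asarray(G(uniq_t, side="left"))

    p = X_s.shape[1]
    beta = np.zeros(p)
    ll, score, info, _ = _fg_loglik_parts(X_s, time_s, event_s, beta,
                                          ginv_left, g_left_ev)
    it = 0
    for it in range(1, max_iter + 1):
        gnorm = float(np.linalg.norm(score))
        if gnorm < tol:
            break
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # damped Newton with step halving on the partial likelihood
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new, score_new, info_new, tail = _fg_loglik_parts(
                X_s, time_s, event_s, cand, ginv_left, g_left_ev)
            if ll_new >= ll - 1e-12:
                break
            scale *= 0.5
        else:
            raise ConvergenceError(
                f"step halving failed; gradient norm {gnorm:.3e}")
        stalled = (ll_new - ll) < 1e-13 * (abs(ll) + 1.0) \
            and float(np.linalg.norm(score_new)) < 1e-3
        beta, ll, score, info = cand, ll_new, score_new, info_new
        if stalled:
            # likelihood at its float64 plateau; score is at rounding floor
            break
    else:
        raise ConvergenceError(
            f"no convergence in {max_iter} iterations; "
            f"gradient norm {float(np.linalg.norm(score)):.3e}")

    cov = np.linalg.inv(info) if p else np.zeros((0, 0))
    se = np.sqrt(np.diag(cov)) if p else np.zeros(0)

    uniq_t, d_counts, s0 = _fg_loglik_parts(
        X_s, time_s, event_s, beta, ginv_left, g_left_ev)[3]
    h0 = np.cumsum(d_counts / s0)
    baseline = StepFunction(uniq_t, h0, init=0.0)

    return FineGrayResult(
        columns=names, coef=beta, se=se, cov=cov, centering=center,
        baseline_hazard=baseline, transforms=dict(transforms or {}),
        n=len(df), n_events=int(np.sum(event == 1)), loglik=ll, n_iter=it,
        grad_norm=float(np.linalg.norm(score)),
    )


def predict_cif(model: FineGrayResult, X=None, t=10.0, lp=None):
    """Predicted cumulative incidence F1(t|x) = 1 - (1 - CIF0(t))^exp(LP).

    Either a design matrix ``X`` (same columns/order the model was fitted
    with, untransformed values already expanded) or a precomputed linear
    predictor ``lp`` may be given.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("t must be non-negative")
    if lp is None:
        if X is None:
            raise ValueError("supply X or lp")
        lp = model.linear_predictor(X)
    lp = np.asarray(lp, dtype=float)
    h0 = np.asarray(model.baseline_hazard(t_arr))
    return 1.0 - np.exp(-h0 * np.exp(lp))


def design_from_frame(model: FineGrayResult, df, covariates, exclude=()):
    """Expand a raw frame into the fitted model's design columns."""
    X, names = build_design(df, covariates, model.transforms, exclude)
    if names != model.columns:
        missing = set(model.columns) - set(names)
        if missing:
            raise KeyError(f"missing design columns: {sorted(missing)}")
        X = X[:, [names.index(c) for c in model.columns]]
    return X


def select_fractional_polynomial(frames, duration_col, event_col, covariates,
                                 variable, max_degree=2, shift=0.0,
                                 scale=1.0, transforms=None, alpha=0.05):
    """Choose the best-fitting FP transform for one continuous variable.

    Every FP1 (8) and, when ``max_degree`` is 2, FP2 (36) power set is
    fitted on each supplied frame (typically the imputed copies) and scored
    by deviance (-2 x partial log-likelihood).  Within each frame the
    closed-test procedure keeps lower order whenever possible: the best FP2
    must beat the linear term by a chi-square(3) deviance drop at level
    ``alpha`` for any non-linear transform to be kept, and must beat the
    best FP1 by chi-square(2) to be preferred over it.  Per-frame winners
    are combined by majority vote; remaining ties break toward lower order,
    then toward the linear transform.
    """
    if isinstance(frames, pd.DataFrame):
        frames = [frames]
    transforms = dict(transforms or {})
    x0 = frames[0][variable].to_numpy(dtype=float)
    if np.any((x0 + shift) / (scale or 1.0) <= 0):
        raise ValueError(
            f"{variable} has non-positive values after shift={shift}; "
            "increase the shift")

    def deviance(frame, powers):
        tr = FpTransform(variable, powers, shift, scale)
        trs = {**transforms, variable: tr}
        try:
            res = fit_finegray(frame, duration_col, event_col, covariates,
                               transforms=trs)
        except (ConvergenceError, np.linalg.LinAlgError):
            return None
        return -2.0 * res.loglik

    fp1_sets = [s for s in _all_power_sets(1)]
    fp2_sets = [s for s in _all_power_sets(max_degree) if len(s) == 2]
    crit2 = stats.chi2.ppf(1 - alpha, 2)
    crit3 = stats.chi2.ppf(1 - alpha, 3)

    winners = []
    for frame in frames:
        devs1 = {p: d for p in fp1_sets
                 if (d := deviance(frame, p)) is not None}
        if (1.0,) not in devs1:
            continue
        dev_lin = devs1[(1.0,)]
        best1 = min(devs1, key=devs1.get)
        choice = best1 if devs1[best1] < dev_lin else (1.0,)
        if fp2_sets:
            devs2 = {p: d for p in fp2_sets
                     if (d := deviance(frame, p)) is not None}
            if devs2:
                best2 = min(devs2, key=devs2.get)
                if dev_lin - devs2[best2] > crit3:
                    # non-linearity established; FP2 only if it beats FP1
                    if devs1[best1] - devs2[best2] > crit2:
                        choice = best2
                    else:
                        choice = best1
                else:
                    choice = (1.0,)
        winners.append(choice)
    if not winners:
        raise ConvergenceError("no candidate transform could be fitted")
    counts = {}
    for w in winners:
        counts[w] = counts.get(w, 0) + 1
    top = max(counts.values())
    tied = [w for w, c in counts.items() if c == top]
    tied.sort(key=lambda w: (len(w), w != (1.0,), w))
    return FpTransform(variable, tied[0], shift, scale)


def schoenfeld_check(model: FineGrayResult, df, duration_col, event_col,
                     covariates, exclude=(), alpha=0.05):
    """Proportional-subdistribution-hazards diagnostic.

    Computes weighted Schoenfeld-type residuals x_i - E[x | risk set] at each
    cause-1 event and tests the Pearson correlation of each covariate's
    residuals with the event-time rank.  Returns a DataFrame with the
    correlation, p-value, and a flag at level ``alpha``.
    """
    X = design_from_frame(model, df, covariates, exclude)
    Xc = X - model.centering
    time = df[duration_col].to_numpy(dtype=float)
    event = df[event_col].to_numpy()
    if int(np.sum(event == 1)) < 2:
        raise ValueError("need at least 2 cause-1 events")

    order = np.argsort(time, kind="stable")
    X_s, time_s, event_s = Xc[order], time[order], np.asarray(event)[order]
    G = censoring_km(time, event)
    g_left = np.asarray(G(time_s, side="left"))
    ginv_left = np.where(g_left > 0, 1.0 / np.clip(g_left, 1e-300, None), 0.0)
    is1 = event_s == 1
    uniq_t = np.unique(time_s[is1])
    g_left_ev = np.asarray(G(uniq_t, side="left"))

    _, _, _, (ut, d_counts, s0) = _fg_loglik_parts(
        X_s, time_s, event_s, model.coef, ginv_left, g_left_ev)
    eta = np.clip(X_s @ model.coef, -200, 200)
    ev_pos_first = np.searchsorted(time_s, ut, side="left")
    s0_, s1_, _ = _fg_sums(X_s, time_s, event_s, eta, ginv_left, g_left_ev,
                           ev_pos_first)
    mean_at = s1_ / s0_[:, None]

    ev_times = time_s[is1]
    grp = np.searchsorted(ut, ev_times)
    resid = X_s[is1] - mean_at[grp]
    ranks = stats.rankdata(ev_times)
    rows = []
    for j, name in enumerate(model.columns):
        r_j = resid[:, j]
        if np.allclose(r_j, r_j[0]) or len(r_j) < 3:
            rho, pval = 0.0, 1.0
        else:
            rho, pval = stats.pearsonr(r_j, ranks)
        rows.append({"covariate": name, "rho": rho, "p": pval,
                     "flag": pval < alpha})
    return pd.DataFrame(rows).set_index("covariate")
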