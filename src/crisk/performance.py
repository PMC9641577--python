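"""Validation metrics against pseudo-value observed outcomes.

All metrics take per-patient pseudo-values as the "observed" outcome, which
keeps them consistent under right censoring and competing risks:

* observed:expected ratio -- mean pseudo-value over mean predicted risk,
  with the SE reported on the log scale;
* Harrell's C -- pairwise concordance between pseudo-values and predicted
  risks over pairs with distinct pseudo-values, prediction ties scoring 1/2;
* Royston's D -- prognostic separation: the slope of the pseudo-value
  logit-link regression on scaled rankits of the linear predictor, with
  R^2_D = (D^2/kappa^2) / (pi^2/6 + D^2/kappa^2), kappa^2 = 8/pi;
* calibration curves -- decile group points plus a lowess smooth with a
  pointwise 95% band.

Per-practice variants feed the random-effects meta-analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from ._quasi import fit_pseudo_glm
from .pseudo import PseudoValueSet

__all__ = [
    "observed_expected_ratio",
    "harrell_c",
    "royston_d",
    "r2_from_d",
    "calibration_curve",
    "per_practice_performance",
    "CalibrationCurve",
    "KAPPA_SQ",
    "SIGMA_SQ",
]

KAPPA_SQ = 8.0 / np.pi        # Royston-Sauerbrei rankit scaling, squared
SIGMA_SQ = np.pi ** 2 / 6.0   # residual variance constant for R^2_D


def _theta_of(pseudo):
    return pseudo.theta if isinstance(pseudo, PseudoValueSet) else \
        np.asarray(pseudo, dtype=float)


def observed_expected_ratio(pseudo, predicted):
    """O:E ratio with the SE of ln(O/E).

    O = mean pseudo-value, E = mean predicted risk; the log-scale SE treats
    E as fixed: SE = sd(theta) / (O * sqrt(n)).
    """
    theta = _theta_of(pseudo)
    predicted = np.asarray(predicted, dtype=float)
    if len(theta) != len(predicted):
        raise ValueError("inputs misaligned")
    e = float(np.mean(predicted))
    if e <= 0:
        raise ValueError("mean predicted risk must be positive")
    o = float(np.mean(theta))
    ratio = o / e
    if o <= 0:
        warnings.warn("non-positive mean pseudo-value; log-scale SE undefined")
        return ratio, float("nan")
    se_ln = float(np.std(theta, ddof=1) / (o * np.sqrt(len(theta))))
    return ratio, se_ln


class _Fenwick:
    def __init__(self, size):
        self.t = np.zeros(size + 1, dtype=np.int64)

    def add(self, i):
        i += 1
        t = self.t
        while i < len(t):
            t[i] += 1
            i += i & (-i)

    def prefix(self, i):
        # count of items with rank <= i
        s = 0
        t = self.t
        i += 1
        while i > 0:
            s += t[i]
            i -= i & (-i)
        return int(s)


def _concordance_counts(theta, pred):
    """Per-subject (concordant, pred-tie, usable) pair counts.

    Usable pairs have distinct pseudo-values; computed in O(n log n) with a
    Fenwick tree over compressed prediction ranks, one ascending and one
    descending pass over blocks of tied pseudo-values.
    """
    n = len(theta)
    pr = np.unique(pred, return_inverse=True)[1]
    n_ranks = int(pr.max()) + 1
    order = np.argsort(theta, kind="stable")
    conc = np.zeros(n, dtype=np.int64)
    tie = np.zeros(n, dtype=np.int64)
    usable = np.zeros(n, dtype=np.int64)

    for direction in (1, -1):
        seq = order if direction == 1 else order[::-1]
        tree = _Fenwick(n_ranks)
        processed = 0
        i = 0
        th = theta[seq]
        while i < n:
            j = i
            while j < n and th[j] == th[i]:
                j += 1
            for k in range(i, j):
                idx = seq[k]
                r = int(pr[idx])
                below = tree.prefix(r - 1) if r > 0 else 0
                upto = tree.prefix(r)
                eq = upto - below
                above = processed - upto
                usable[idx] += processed
                tie[idx] += eq
                conc[idx] += below if direction == 1 else above
            for k in range(i, j):
                tree.add(int(pr[seq[k]]))
            processed += j - i
            i = j
    return conc, tie, usable


def harrell_c(pseudo, predicted):
    """Concordance between pseudo-values and predicted risks, with SE.

    C = P(larger pseudo-value goes with larger prediction) over pairs with
    distinct pseudo-values; prediction ties count 1/2.  The SE is the
    U-statistic (DeLong-type) estimate from per-subject mean concordance
    contributions: Var(C) ~ 4 Var(c_i) / n.
    """
    theta = _theta_of(pseudo)
    pred = np.asarray(predicted, dtype=float)
    n = len(theta)
    if n < 2 or len(pred) != n:
        raise ValueError("need >= 2 aligned subjects")
    if np.ptp(pred) == 0:
        warnings.warn("all predictions identical; C = 0.5 by convention")
        return 0.5, float("nan")
    if np.ptp(theta) == 0:
        warnings.warn("no variation in pseudo-values; C undefined")
        return float("nan"), float("nan")
    conc, tie, usable = _concordance_counts(theta, pred)
    num = conc + 0.5 * tie
    c = float(num.sum() / usable.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        c_i = np.where(usable > 0, num / np.where(usable == 0, 1, usable),
                       np.nan)
    c_i = c_i[np.isfinite(c_i)]
    se = float(np.sqrt(4.0 * np.var(c_i, ddof=1) / len(c_i)))
    return c, se


def royston_d(pseudo, lp):
    """Royston's D from the pseudo-value regression on scaled rankits.

    Rankits z_i = Phi^-1((rank(lp_i) - 3/8)/(n + 1/4)) are divided by
    kappa = sqrt(8/pi); D is the slope of the logit-link estimating-equation
    regression of the pseudo-values on z/kappa.  Returns (D, SE, R^2_D).
    """
    theta = _theta_of(pseudo)
    lp = np.asarray(lp, dtype=float)
    n = len(theta)
    if n < 10:
        raise ValueError("need n >= 10")
    if np.ptp(lp) == 0:
        warnings.warn("constant linear predictor; D = 0")
        return 0.0, float("nan"), 0.0
    ranks = stats.rankdata(lp)
    z = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    q = z / np.sqrt(KAPPA_SQ)
    X = np.column_stack([np.ones(n), q])
    fit = fit_pseudo_glm(X, theta)
    d = float(fit.coef[1])
    se = float(fit.se[1])
    return d, se, r2_from_d(d)


def r2_from_d(d):
    """Explained-variation transform R^2_D of Royston's D."""
    num = d ** 2 / KAPPA_SQ
    return num / (SIGMA_SQ + num)


@dataclass
class CalibrationCurve:
    horizon: float
    group_pred: np.ndarray
    group_obs: np.ndarray
    curve_x: np.ndarray
    curve_y: np.ndarray
    band_lower: np.ndarray
    band_upper: np.ndarray
    hist_edges: np.ndarray
    hist_counts: np.ndarray


def calibration_curve(pseudo, predicted, n_groups=10, frac=0.75,
                      horizon=float("nan"), n_bands=20):
    """Grouped calibration points plus a lowess smooth with 95% bands.

    Group points are means of predictions and pseudo-values within
    equal-count groups of predicted risk; the smooth is a local linear
    (lowess) regression of pseudo-values on predictions, with a pointwise
    band from binned standard errors of the pseudo-values.
    """
    theta = _theta_of(pseudo)
    pred = np.asarray(predicted, dtype=float)
    n = len(theta)
    if n_groups > n:
        raise ValueError("more groups than subjects")
    if isinstance(pseudo, PseudoValueSet) and np.isnan(horizon):
        horizon = pseudo.horizon

    order = np.argsort(pred, kind="stable")
    splits = np.array_split(order, n_groups)
    gp = np.array([pred[s].mean() for s in splits if len(s)])
    go = np.array([theta[s].mean() for s in splits if len(s)])

    if np.ptp(pred) == 0:
        x = np.array([pred[0]])
        y = np.array([theta.mean()])
        se = np.array([np.std(theta, ddof=1) / np.sqrt(n)]) if n > 1 else \
            np.array([0.0])
        hist, edges = np.histogram(pred, bins=10)
        return CalibrationCurve(horizon, gp, go, x, y, y - 1.96 * se,
                                y + 1.96 * se, edges, hist)

    sm = lowess(theta, pred, frac=frac, it=0)
    x, y = sm[:, 0], sm[:, 1]
    # pointwise band from binned SEs, interpolated along the curve
    bins = np.array_split(order, min(n_bands, max(n // 2, 1)))
    bx, bse = [], []
    for b in bins:
        if len(b) > 1:
            bx.append(pred[b].mean())
            bse.append(np.std(theta[b], ddof=1) / np.sqrt(len(b)))
    se = np.interp(x, bx, bse) if bx else np.zeros_like(x)
    hist, edges = np.histogram(pred, bins=min(50, max(10, n // 20)))
    return CalibrationCurve(horizon, gp, go, x, y, y - 1.96 * se,
                            y + 1.96 * se, edges, hist)


def per_practice_performance(practice_ids, events, pseudo, predicted, lp,
                             min_events=2, min_n=20):
    """Per-cluster O:E, C, D and R^2_D with SEs.

    Practices with fewer than ``min_events`` cause-1 events or ``min_n``
    patients are excluded (reasons returned separately), mirroring the
    minimum-data rules used before meta-analysis.

    Returns (metrics DataFrame indexed by practice, exclusions DataFrame).
    """
    theta = _theta_of(pseudo)
    practice_ids = np.asarray(practice_ids)
    events = np.asarray(events)
    predicted = np.asarray(predicted, dtype=float)
    lp = np.asarray(lp, dtype=float)

    rows, excluded = [], []
    for pid in pd.unique(practice_ids):
        m = practice_ids == pid
        n = int(m.sum())
        ev1 = int(np.sum(events[m] == 1))
        if n < min_n or ev1 < min_events:
            excluded.append({"practice_id": pid, "n": n, "events": ev1,
                             "reason": "too few patients" if n < min_n
                             else "too few events"})
            continue
        oe, se_ln_oe = observed_expected_ratio(theta[m], predicted[m])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            c, se_c = harrell_c(theta[m], predicted[m])
            try:
                d, se_d, r2 = royston_d(theta[m], lp[m])
            except (ValueError, RuntimeError):
                d, se_d, r2 = np.nan, np.nan, np.nan
        rows.append({"practice_id": pid, "n": n, "events": ev1,
                     "oe": oe, "se_ln_oe": se_ln_oe, "c": c, "se_c": se_c,
                     "d": d, "se_d": se_d, "r2_d": r2})
    metrics = pd.DataFrame(rows)
    if len(metrics):
        metrics = metrics.set_index("practice_id")
    return metrics, pd.DataFrame(excluded)
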