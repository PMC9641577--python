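"""Net-benefit decision-curve analysis under competing risks.

Net benefit at threshold p_t offsets true positives against false
positives weighted by the odds of the threshold:

    NB = (TP - FP * p_t / (1 - p_t)) / n.

Event probabilities among the treated are estimated from pseudo-values, so
the curves remain consistent under right censoring and competing risks.
Model-based treatment is compared against treating everyone and treating
no one; treat-none has NB identically 0 and treat-all crosses 0 at the
event prevalence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pseudo import PseudoValueSet

__all__ = ["net_benefit", "decision_curve_analysis", "cross_classify",
           "DecisionCurve", "default_threshold_grid"]


def _theta_of(pseudo):
    return pseudo.theta if isinstance(pseudo, PseudoValueSet) else \
        np.asarray(pseudo, dtype=float)


def default_threshold_grid(step=0.005, upper=0.5):
    return np.round(np.arange(step, upper + step / 2, step), 10)


def net_benefit(pseudo, predicted, p_t):
    """Net benefit of treating patients with predicted risk >= p_t."""
    if not 0.0 < p_t < 1.0:
        raise ValueError("p_t must lie in (0, 1)")
    theta = _theta_of(pseudo)
    pred = np.asarray(predicted, dtype=float)
    n = len(theta)
    treated = pred >= p_t
    n_t = int(treated.sum())
    if n_t == 0:
        return 0.0
    p_event = float(np.mean(theta[treated]))
    tp = n_t * p_event
    fp = n_t * (1.0 - p_event)
    return float((tp - fp * p_t / (1.0 - p_t)) / n)


@dataclass
class DecisionCurve:
    horizon: float
    thresholds: np.ndarray
    table: pd.DataFrame        # one NB column per strategy
    n: int
    dominant_from: dict        # model -> lowest grid p_t from which the
    #                            model beats both comparators onwards


def decision_curve_analysis(pseudo, risks, thresholds=None,
                            horizon=float("nan")):
    """Net-benefit curves for one or more model variants plus comparators.

    ``risks`` maps variant name -> per-patient predicted risks.  For each
    variant the lowest grid threshold from which the model's NB stays >=
    both treat-all and treat-none for the rest of the grid is reported
    (NaN when no such threshold exists).
    """
    theta = _theta_of(pseudo)
    if isinstance(pseudo, PseudoValueSet) and np.isnan(horizon):
        horizon = pseudo.horizon
    if isinstance(risks, (np.ndarray, list)):
        risks = {"model": np.asarray(risks)}
    if thresholds is None:
        thresholds = default_threshold_grid()
    thresholds = np.asarray(thresholds, dtype=float)

    n = len(theta)
    prev = float(np.mean(theta))
    cols = {"treat_all": np.array(
        [prev - (1 - prev) * pt / (1 - pt) for pt in thresholds]),
        "treat_none": np.zeros(len(thresholds))}
    for name, r in risks.items():
        cols[name] = np.array([net_benefit(theta, r, pt)
                               for pt in thresholds])
    table = pd.DataFrame(cols, index=pd.Index(thresholds, name="threshold"))

    dominant = {}
    best_comp = np.maximum(cols["treat_all"], 0.0)
    for name in risks:
        ge = cols[name] >= best_comp - 1e-12
        # lowest threshold from which dominance holds for the whole tail
        dominant[name] = float("nan")
        tail_ok = np.logical_and.accumulate(ge[::-1])[::-1]
        idx = np.where(tail_ok)[0]
        if idx.size:
            dominant[name] = float(thresholds[idx[0]])
    return DecisionCurve(horizon=horizon, thresholds=thresholds, table=table,
                         n=n, dominant_from=dominant)


def cross_classify(falls_risks, cvd_risks, threshold=0.10):
    """2x2 cross-classification of falls risk against CVD risk.

    Returns a DataFrame of counts with rows (falls high/low) and columns
    (cvd high/low), where high means risk > threshold, plus percentage
    columns rounded to one decimal.
    """
    f = np.asarray(falls_risks, dtype=float)
    c = np.asarray(cvd_risks, dtype=float)
    if len(f) != len(c):
        raise ValueError("risk vectors have different lengths")
    fh, ch = f > threshold, c > threshold
    n = len(f)
    counts = pd.DataFrame(
        [[int(np.sum(fh & ch)), int(np.sum(fh & ~ch))],
         [int(np.sum(~fh & ch)), int(np.sum(~fh & ~ch))]],
        index=pd.Index(["falls_high", "falls_low"]),
        columns=["cvd_high", "cvd_low"],
    )
    pct = (100.0 * counts / n).round(1) if n else counts * np.nan
    return counts, pct
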