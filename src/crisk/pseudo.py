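"""Aalen-Johansen cumulative incidence and jack-knife pseudo-values.

Pseudo-values turn a censored competing-risks outcome into a per-patient
response theta_i = n*F1(t) - (n-1)*F1^(-i)(t) that can be regressed or
averaged like an uncensored binary outcome.  Pseudo-values may fall outside
[0, 1]; that is expected and they are never clipped.

Grouping by linear-predictor quantiles (default 50 equal-count groups)
computes pseudo-values within homogeneous risk strata for numerical
stability of downstream calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "aalen_johansen_cif",
    "aalen_johansen_curve",
    "jackknife_pseudovalues",
    "grouped_pseudovalues",
    "PseudoValueSet",
]


def _aj_tables(time, event):
    """Per-unique-time counts: at-risk n_j, all-cause d_j, cause-1 d1_j."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    order = np.argsort(time, kind="stable")
    t_s, e_s = time[order], event[order]
    uniq, start = np.unique(t_s, return_index=True)
    bounds = np.append(start, len(t_s))
    n = len(t_s)
    n_risk = n - start
    d_all = np.empty(len(uniq), dtype=float)
    d1 = np.empty(len(uniq), dtype=float)
    for j in range(len(uniq)):
        block = e_s[bounds[j]:bounds[j + 1]]
        d_all[j] = np.sum(block != 0)
        d1[j] = np.sum(block == 1)
    return uniq, n_risk.astype(float), d_all, d1


def aalen_johansen_curve(time, event):
    """Cause-1 cumulative incidence step function F1 over all event times.

    F1(t) = sum_{t_j <= t} S(t_j-) d1_j / n_j with S the all-cause
    Kaplan-Meier survival.  Returns (times, values) arrays.
    """
    if len(np.asarray(time)) == 0:
        raise ValueError("empty data")
    uniq, n_risk, d_all, d1 = _aj_tables(time, event)
    surv_left = np.cumprod(np.concatenate(([1.0], 1.0 - d_all / n_risk)))[:-1]
    incr = surv_left * d1 / n_risk
    return uniq, np.cumsum(incr)


def aalen_johansen_cif(time, event, t):
    """Aalen-Johansen estimate F1(t) of the cause-1 cumulative incidence."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("t must be positive")
    times, values = aalen_johansen_curve(time, event)
    idx = np.searchsorted(times, t, side="right") - 1
    out = np.where(idx >= 0, values[np.clip(idx, 0, None)], 0.0)
    return out if out.ndim else float(out)


def _aj_at(uniq, n_risk, d_all, d1, t):
    surv_left = np.cumprod(np.concatenate(([1.0], 1.0 - d_all / n_risk)))[:-1]
    incr = surv_left * d1 / n_risk
    cum = np.cumsum(incr)
    idx = np.searchsorted(uniq, t, side="right") - 1
    return float(cum[idx]) if idx >= 0 else 0.0


def jackknife_pseudovalues(time, event, t):
    """Exact leave-one-out pseudo-values of the cause-1 CIF at horizon t.

    theta_i = n*F1(t) - (n-1)*F1^(-i)(t).  Subjects sharing the same
    (time, event) pair have identical leave-one-out estimates, so the
    recomputation runs once per unique pair; the result equals the naive
    per-subject brute force exactly.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    n = len(time)
    if n < 2:
        raise ValueError("need at least 2 subjects")
    t = float(t)
    uniq, n_risk, d_all, d1 = _aj_tables(time, event)
    full = _aj_at(uniq, n_risk, d_all, d1, t)

    theta = np.empty(n, dtype=float)
    cache = {}
    for i in range(n):
        key = (time[i], int(event[i]))
        if key not in cache:
            # remove one subject with this (time, event) pattern
            j = np.searchsorted(uniq, time[i])
            n_risk_i = n_risk.copy()
            n_risk_i[: j + 1] -= 1.0
            d_all_i = d_all.copy()
            d1_i = d1.copy()
            if event[i] != 0:
                d_all_i[j] -= 1.0
            if event[i] == 1:
                d1_i[j] -= 1.0
            keep = n_risk_i > 0
            cache[key] = _aj_at(uniq[keep], n_risk_i[keep], d_all_i[keep],
                                d1_i[keep], t)
        theta[i] = n * full - (n - 1) * cache[key]
    return theta


@dataclass
class PseudoValueSet:
    """Per-patient pseudo-values at one horizon, with their grouping.

    ``theta`` is aligned with the input patient order; ``group`` gives each
    patient's linear-predictor quantile group and ``group_cif`` the group's
    own Aalen-Johansen estimate at the horizon.
    """

    horizon: float
    theta: np.ndarray
    group: np.ndarray
    group_cif: np.ndarray

    @property
    def n_groups(self):
        return len(self.group_cif)


def grouped_pseudovalues(time, event, lp, t, n_groups=50):
    """Pseudo-values computed separately within linear-predictor groups.

    Patients are ranked by ``lp`` (stable ties) and split into ``n_groups``
    equal-count groups (sizes differing by at most one); groups that end up
    with fewer than 2 members are merged with a neighbour.  Horizons beyond
    a group's last observed time fall back to the group's last attainable
    time with a warning.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    lp = np.asarray(lp, dtype=float)
    n = len(time)
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    n_groups = min(n_groups, n // 2)
    n_groups = max(n_groups, 1)

    order = np.argsort(lp, kind="stable")
    splits = np.array_split(order, n_groups)
    splits = [s for s in splits if len(s)]
    # merge undersized groups with their neighbour
    merged = []
    for s in splits:
        if merged and (len(s) < 2 or len(merged[-1]) < 2):
            merged[-1] = np.concatenate([merged[-1], s])
        else:
            merged.append(s)
    if len(merged) >= 2 and len(merged[0]) < 2:
        merged[1] = np.concatenate([merged[0], merged[1]])
        merged = merged[1:]

    theta = np.empty(n, dtype=float)
    group = np.empty(n, dtype=int)
    group_cif = np.empty(len(merged), dtype=float)
    for g, idx in enumerate(merged):
        tg, eg = time[idx], event[idx]
        horizon = float(t)
        t_max = float(np.max(tg))
        if horizon > t_max:
            warnings.warn(
                f"group {g}: horizon {t} beyond last observed time "
                f"{t_max:.4g}; using the last attainable time")
            horizon = t_max
        theta[idx] = jackknife_pseudovalues(tg, eg, horizon)
        group[idx] = g
        group_cif[g] = aalen_johansen_cif(tg, eg, horizon)
    return PseudoValueSet(horizon=float(t), theta=theta, group=group,
                          group_cif=group_cif)
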