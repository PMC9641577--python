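"""Pseudo-value recalibration of predicted risks.

When calibration plots show systematic miscalibration at a horizon, the
original model's predictions are recalibrated by regressing observed
pseudo-values on the original linear predictor through a logit-link mean
function.  The linear predictor is the only covariate; optionally its
functional form is relaxed with fractional-polynomial terms.  Individual
predictor coefficients are never re-estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

from ._quasi import fit_pseudo_glm
from .finegray import _all_power_sets, fp_basis
from .pseudo import PseudoValueSet

__all__ = ["RecalibrationModel", "fit_recalibration", "apply_recalibration"]


@dataclass
class RecalibrationModel:
    """Fitted map from original linear predictor to recalibrated risk.

    r*(lp) = expit(gamma0 + sum_k gamma_k * fp_k(lp + shift)); with the
    default identity term this is the usual intercept/slope update.
    """

    horizon: float
    intercept: float
    coef: np.ndarray
    powers: tuple = (1.0,)
    shift: float = 0.0
    cov: np.ndarray | None = None
    grad_norm: float = float("nan")

    def logits(self, lp):
        basis = fp_basis(np.asarray(lp, dtype=float), self.powers,
                         shift=self.shift)
        return self.intercept + basis @ self.coef


def _design(lp, powers, shift):
    basis = fp_basis(lp, powers, shift=shift)
    return np.column_stack([np.ones(len(lp)), basis])


def fit_recalibration(pseudo, lp, horizon=None, fp_search=False):
    """Fit the logit-link recalibration model to observed pseudo-values.

    Parameters
    ----------
    pseudo : PseudoValueSet or array of pseudo-values aligned with ``lp``.
    lp : original-model linear predictor per patient.
    fp_search : when True, search FP1/FP2 power sets of the (shifted) linear
        predictor by residual sum of squares; default keeps the identity
        term only.
    """
    if isinstance(pseudo, PseudoValueSet):
        theta = pseudo.theta
        horizon = pseudo.horizon if horizon is None else horizon
    else:
        theta = np.asarray(pseudo, dtype=float)
    lp = np.asarray(lp, dtype=float)
    if len(lp) != len(theta):
        raise ValueError("pseudo-values and linear predictor misaligned")
    if np.ptp(lp) == 0:
        raise ValueError("linear predictor is constant")
    # shift so FP transforms act on a strictly positive range
    shift = float(1.0 - np.min(lp))

    def _fit(powers):
        X = _design(lp, powers, shift)
        fit = fit_pseudo_glm(X, theta)
        rss = float(np.sum((theta - special.expit(X @ fit.coef)) ** 2))
        return fit, rss

    candidates = [(1.0,)]
    if fp_search:
        candidates = _all_power_sets(2)
    best = None
    for powers in candidates:
        try:
            fit, rss = _fit(powers)
        except RuntimeError:
            continue
        if best is None or rss < best[2] - 1e-12:
            best = (powers, fit, rss)
    if best is None:
        raise RuntimeError("recalibration failed to converge for all "
                           "candidate transforms")
    powers, fit, _ = best
    return RecalibrationModel(
        horizon=float(horizon) if horizon is not None else float("nan"),
        intercept=float(fit.coef[0]), coef=fit.coef[1:], powers=powers,
        shift=shift, cov=fit.cov, grad_norm=fit.grad_norm,
    )


def apply_recalibration(model: RecalibrationModel, lp):
    """Recalibrated risks expit(gamma0 + gamma' fp(lp)); always in (0, 1)."""
    return special.expit(model.logits(lp))
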