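"""End-to-end development and external-validation workflows.

``run_development`` takes a cohort with (possibly missing) predictors and a
competing-risks outcome and produces a pooled subdistribution-hazard model:
chained-equation imputation (m copies), a Fine-Gray fit per copy, Rubin's
rules pooling of the log-SHRs, a baseline cumulative incidence averaged
across copies at the pooled coefficients' scale, and pseudo-value
recalibration at the requested horizons.

``run_external_validation`` applies a (pooled) model to a new cohort and
reports per-practice and REML-pooled performance (O:E, C, D/R^2), with
calibration curves and decision curves for the original and recalibrated
model variants.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import MODEL_COVARIATES, build_model_frame
from .decision import decision_curve_analysis
from .finegray import FineGrayResult, StepFunction, fit_finegray, predict_cif
from .imputation import mice_impute, nelson_aalen_covariates, rubin_pool
from .meta import pool_metric
from .performance import (calibration_curve, harrell_c,
                          observed_expected_ratio, per_practice_performance,
                          royston_d)
from .pseudo import grouped_pseudovalues
from .recalibration import (RecalibrationModel, apply_recalibration,
                            fit_recalibration)

logger = logging.getLogger(__name__)

__all__ = ["run_development", "run_external_validation", "predict_risks",
           "DevelopmentResult", "ValidationReport"]

RAW_PREDICTORS = ["age", "sex", "cholesterol", "frailty_index", "smoking",
                  "alcohol"]


@dataclass
class DevelopmentResult:
    model: FineGrayResult
    covariates: list
    recalibrations: dict
    coefficient_table: pd.DataFrame
    per_imputation: list = field(repr=False, default_factory=list)
    apparent: dict = field(repr=False, default_factory=dict)
    seed: int | None = None


def _pool_fits(fits, grid):
    """Rubin-pool coefficients and average baselines on a common grid."""
    m = len(fits)
    names = fits[0].columns
    coefs = np.array([f.coef for f in fits])
    vars_ = np.array([f.se ** 2 for f in fits])
    if m == 1:
        pooled_coef, pooled_se = coefs[0], np.sqrt(vars_[0])
        table = pd.DataFrame({"coef": pooled_coef, "se": pooled_se,
                              "shr": np.exp(pooled_coef)}, index=names)
    else:
        rows = [rubin_pool(coefs[:, j], vars_[:, j])
                for j in range(coefs.shape[1])]
        pooled_coef = np.array([r.estimate for r in rows])
        pooled_se = np.array([r.se for r in rows])
        table = pd.DataFrame({
            "coef": pooled_coef, "se": pooled_se,
            "shr": np.exp(pooled_coef),
            "within_var": [r.within for r in rows],
            "between_var": [r.between for r in rows],
            "df": [r.df for r in rows]}, index=names)
    h0 = np.mean([np.asarray(f.baseline_hazard(grid)) for f in fits], axis=0)
    centering = np.mean([f.centering for f in fits], axis=0)
    pooled = FineGrayResult(
        columns=names, coef=pooled_coef, se=pooled_se,
        cov=np.diag(pooled_se ** 2), centering=centering,
        baseline_hazard=StepFunction(grid, h0, init=0.0),
        transforms=fits[0].transforms, n=fits[0].n,
        n_events=int(np.mean([f.n_events for f in fits])),
    )
    return pooled, table


def run_development(patients, outcomes, covariates=None, m=10,
                    horizons=(1.0, 5.0, 10.0), recalibrate=(5.0, 10.0),
                    n_groups=50, seed=0, transforms=None, exclude=(),
                    fp_search=False, n_cycles=5):
    """Develop a pooled competing-risks prediction model.

    ``covariates`` are derived model columns (default the standard set from
    the synthetic generator); raw predictor columns with missing values are
    imputed first, with Nelson-Aalen outcome covariates in every
    imputation model.  Recalibration is fitted per horizon listed in
    ``recalibrate`` (pseudo-value logit regression on the linear
    predictor), pooled across imputed copies by Rubin's rules.
    """
    covariates = list(covariates or MODEL_COVARIATES)
    has_missing = patients.isna().any().any()
    if has_missing and m >= 1:
        na_cov = nelson_aalen_covariates(outcomes)
        stack = mice_impute(patients, m=m, predictors=RAW_PREDICTORS,
                            extra_covariates=na_cov, seed=seed,
                            n_cycles=n_cycles)
        copies = stack.copies
    else:
        copies = [patients] * m
    merged = [c.merge(outcomes, on="patient_id") for c in copies]
    frames = []
    for c in merged:
        f = build_model_frame(c)
        f["time"] = c["time"].to_numpy()
        f["event"] = c["event"].to_numpy()
        frames.append(f)

    fits = [fit_finegray(f, "time", "event", covariates,
                         transforms=transforms, exclude=exclude)
            for f in frames]
    grid = np.unique(np.concatenate(
        [f.baseline_hazard.times for f in fits]))
    pooled, table = _pool_fits(fits, grid)

    # apparent validation and per-horizon recalibration, pooled across copies
    recalibrations = {}
    apparent = {"curves": {}, "pseudo": {}}
    lp_by_copy = [fit.linear_predictor(
        frame[fit.columns].to_numpy()) for fit, frame in zip(fits, frames)]
    lp_pooled = pooled.linear_predictor(
        frames[0][pooled.columns].to_numpy())
    for h in horizons:
        pv = grouped_pseudovalues(frames[0]["time"], frames[0]["event"],
                                  lp_pooled, h, n_groups=n_groups)
        risks = predict_cif(pooled, t=h, lp=lp_pooled)
        apparent["pseudo"][h] = pv
        apparent["curves"][h] = calibration_curve(pv, risks, horizon=h)
        if h in recalibrate:
            gammas, gvars = [], []
            model_h = None
            for lp_c, frame in zip(lp_by_copy, frames):
                pv_c = grouped_pseudovalues(frame["time"], frame["event"],
                                            lp_c, h, n_groups=n_groups)
                rc = fit_recalibration(pv_c, lp_c, horizon=h,
                                       fp_search=fp_search)
                model_h = rc
                gammas.append(np.concatenate([[rc.intercept], rc.coef]))
                gvars.append(np.diag(rc.cov) if rc.cov is not None
                             else np.full(len(rc.coef) + 1, np.nan))
            if len(gammas) > 1:
                g = np.array(gammas)
                pooled_g = np.array([
                    rubin_pool(g[:, j], np.array(gvars)[:, j]).estimate
                    for j in range(g.shape[1])])
            else:
                pooled_g = gammas[0]
            recalibrations[h] = RecalibrationModel(
                horizon=h, intercept=float(pooled_g[0]),
                coef=pooled_g[1:], powers=model_h.powers,
                shift=model_h.shift)
    return DevelopmentResult(model=pooled, covariates=covariates,
                             recalibrations=recalibrations,
                             coefficient_table=table,
                             per_imputation=fits, apparent=apparent,
                             seed=seed)


def predict_risks(model, covariates, patients, horizons=(1.0, 5.0, 10.0),
                  recalibrations=None):
    """Per-patient predicted risks at each horizon.

    Returns a frame with the linear predictor and, per horizon, the
    original-model risk and (when a recalibration is present) the
    recalibrated risk.  Raw predictor columns must be complete; binary
    flags absent from the input default to 0.
    """
    pats = patients.copy()
    frame = build_model_frame(pats)
    missing = [c for c in covariates if c not in frame.columns]
    if missing:
        raise KeyError(f"missing predictor columns: {missing}")
    bad = frame[covariates].isna().any(axis=1)
    if bad.any():
        raise ValueError(
            f"missing covariate values in rows {list(np.where(bad)[0][:10])}")
    X = frame[model.columns].to_numpy()
    lp = model.linear_predictor(X)
    out = pd.DataFrame({"patient_id": pats["patient_id"], "lp": lp})
    for h in horizons:
        out[f"risk_{h:g}y"] = predict_cif(model, t=h, lp=lp)
        if recalibrations and h in recalibrations:
            out[f"risk_recal_{h:g}y"] = apply_recalibration(
                recalibrations[h], lp)
    return out


@dataclass
class ValidationReport:
    table: pd.DataFrame
    per_practice: dict = field(repr=False, default_factory=dict)
    curves: dict = field(repr=False, default_factory=dict)
    decision_curves: dict = field(repr=False, default_factory=dict)
    pseudo: dict = field(repr=False, default_factory=dict)
    exclusions: dict = field(repr=False, default_factory=dict)


def run_external_validation(model, covariates, patients, outcomes,
                            horizons=(1.0, 5.0, 10.0), recalibrations=None,
                            n_groups=50, thresholds=None, pool=True,
                            min_events=2, min_n=20):
    """Validate a fitted model on an independent cohort.

    Computes, per horizon and model variant (original, recalibrated when
    available): overall O:E, C and D/R^2 against grouped pseudo-values,
    REML-pooled per-practice metrics with 95% CIs and prediction intervals,
    calibration curves, and decision curves.
    """
    preds = predict_risks(model, covariates, patients, horizons,
                          recalibrations)
    merged = patients[["patient_id", "practice_id"]].merge(
        outcomes, on="patient_id")
    lp = preds["lp"].to_numpy()
    rows = []
    report = ValidationReport(table=None)
    for h in horizons:
        pv = grouped_pseudovalues(merged["time"], merged["event"], lp, h,
                                  n_groups=n_groups)
        report.pseudo[h] = pv
        variants = {"original": preds[f"risk_{h:g}y"].to_numpy()}
        if f"risk_recal_{h:g}y" in preds:
            variants["recalibrated"] = preds[f"risk_recal_{h:g}y"].to_numpy()
        report.decision_curves[h] = decision_curve_analysis(
            pv, variants, thresholds, horizon=h)
        for name, risk in variants.items():
            oe, se_oe = observed_expected_ratio(pv, risk)
            c, se_c = harrell_c(pv, risk)
            d, se_d, r2 = royston_d(pv, lp)
            row = {"horizon": h, "variant": name, "oe": oe, "c": c,
                   "d": d, "r2_d": r2}
            report.curves[(h, name)] = calibration_curve(pv, risk, horizon=h)
            pp, excl = per_practice_performance(
                merged["practice_id"].to_numpy(), merged["event"].to_numpy(),
                pv, risk, lp, min_events=min_events, min_n=min_n)
            report.per_practice[(h, name)] = pp
            report.exclusions[(h, name)] = excl
            if pool and len(pp) >= 2:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    for metric in ("oe", "c", "d"):
                        try:
                            mr = pool_metric(pp, metric)
                        except ValueError:
                            continue
                        row[f"pooled_{metric}"] = mr.pooled
                        row[f"pooled_{metric}_ci"] = mr.ci
                        row[f"pooled_{metric}_pi"] = mr.pi
                        row[f"pooled_{metric}_tau2"] = mr.tau2
            rows.append(row)
    report.table = pd.DataFrame(rows)
    return report
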