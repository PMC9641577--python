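"""Delimited-text and structured-text I/O for cohorts, configs and models.

Cohort files are plain CSV with a ``# key=value`` comment header recording
at least the generating seed; empty fields are missing values.  Model files
are versioned YAML documents carrying the coefficient table (name,
transform, beta, SE), centring constants, the baseline cumulative incidence
at the standard horizons plus the full step grid, and any per-horizon
recalibration models, so externally published coefficient sets can be
loaded without code changes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from .finegray import FineGrayResult, FpTransform, StepFunction
from .recalibration import RecalibrationModel

MODEL_FORMAT_VERSION = 1


def write_cohort(path, patients: pd.DataFrame, outcomes=None, seed=None,
                 extra_header=None):
    df = patients if outcomes is None else patients.merge(
        outcomes, on="patient_id")
    header = {"seed": seed, **(extra_header or {})}
    with open(path, "w") as fh:
        for k, v in header.items():
            if v is not None:
                fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def read_cohort(path, split_outcomes=True):
    meta = {}
    skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            skip += 1
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
    df = pd.read_csv(path, skiprows=skip, float_precision="round_trip")
    if split_outcomes and {"time", "event"} <= set(df.columns):
        outcomes = df[["patient_id", "time", "event"]].copy()
        patients = df.drop(columns=["time", "event"])
        return patients, outcomes, meta
    return df, None, meta


def _transform_to_dict(tr: FpTransform):
    return {"variable": tr.variable, "powers": list(tr.powers),
            "shift": tr.shift, "scale": tr.scale}


def _recal_to_dict(rc: RecalibrationModel):
    return {"horizon": rc.horizon, "intercept": float(rc.intercept),
            "coef": [float(c) for c in rc.coef],
            "powers": list(rc.powers), "shift": float(rc.shift)}


def write_model(path, model: FineGrayResult, covariates, horizons=(1, 5, 10),
                recalibrations=None, seed=None):
    """Serialise a fitted model (and optional recalibrations) to YAML."""
    bh = model.baseline_hazard
    doc = {
        "format_version": MODEL_FORMAT_VERSION,
        "seed": seed,
        "covariates": list(covariates),
        "coefficients": [
            {"name": c, "beta": float(b), "se": float(s)}
            for c, b, s in zip(model.columns, model.coef, model.se)
        ],
        "centering": {c: float(v) for c, v in
                      zip(model.columns, model.centering)},
        "transforms": {v: _transform_to_dict(t)
                       for v, t in model.transforms.items()},
        "baseline_cif_at_horizons": {
            str(h): float(model.baseline_cif(h)) for h in horizons},
        "baseline_hazard": {
            "times": [float(t) for t in bh.times],
            "values": [float(v) for v in bh.values]},
        "n": int(model.n), "n_events": int(model.n_events),
        "recalibrations": {
            str(h): _recal_to_dict(rc)
            for h, rc in (recalibrations or {}).items()},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_model(path):
    """Load a model file; returns (FineGrayResult, covariates, recalibrations)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError("unsupported model file version")
    names = [c["name"] for c in doc["coefficients"]]
    coef = np.array([c["beta"] for c in doc["coefficients"]], dtype=float)
    se = np.array([c["se"] for c in doc["coefficients"]], dtype=float)
    transforms = {
        v: FpTransform(t["variable"], tuple(t["powers"]), t["shift"],
                       t["scale"])
        for v, t in (doc.get("transforms") or {}).items()}
    baseline = StepFunction(doc["baseline_hazard"]["times"],
                            doc["baseline_hazard"]["values"], init=0.0)
    model = FineGrayResult(
        columns=names, coef=coef, se=se, cov=np.diag(se ** 2),
        centering=np.array([doc["centering"][c] for c in names]),
        baseline_hazard=baseline, transforms=transforms,
        n=doc.get("n", 0), n_events=doc.get("n_events", 0),
    )
    recals = {
        float(h): RecalibrationModel(
            horizon=float(r["horizon"]), intercept=float(r["intercept"]),
            coef=np.array(r["coef"], dtype=float),
            powers=tuple(r["powers"]), shift=float(r["shift"]))
        for h, r in (doc.get("recalibrations") or {}).items()}
    return model, doc["covariates"], recals


def write_config(path, config_dict):
    with open(path, "w") as fh:
        yaml.safe_dump(config_dict, fh, sort_keys=False)


def read_config(path):
    with open(path) as fh:
        return yaml.safe_load(fh)
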