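"""Shared fixtures: small synthetic datasets and one large fitted model.

The expensive simulation artefacts (the n = 20 000 parameter-recovery
cohort and its Fine-Gray fit, and the calibration-repair study) are
session-scoped so several tests can share them.
"""

import numpy as np
import pytest

from crisk.cohort import (build_model_frame, generate_cohort,
                          parameter_recovery_config, true_cif1,
                          true_linear_predictor)
from crisk.finegray import fit_finegray


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def recovery_study():
    """Recovery cohort (n = 20 000) with its Fine-Gray fit."""
    cfg = parameter_recovery_config(seed=11)
    patients, outcomes = generate_cohort(cfg)
    frame = build_model_frame(patients)
    frame["time"] = outcomes["time"].to_numpy()
    frame["event"] = outcomes["event"].to_numpy()
    fit = fit_finegray(frame, "time", "event", list(cfg.beta))
    return cfg, patients, outcomes, frame, fit


@pytest.fixture(scope="session")
def calibration_study():
    """Cohort scored by the true model and by a miscalibrated distortion."""
    cfg = parameter_recovery_config(seed=21)
    patients, outcomes = generate_cohort(cfg)
    lp = true_linear_predictor(patients, cfg.beta)
    true_risk = {h: true_cif1(h, lp, cfg) for h in (5.0, 10.0)}
    distorted = {h: np.clip(r ** 1.6 * 1.4, 0, 1)
                 for h, r in true_risk.items()}
    return cfg, outcomes, lp, true_risk, distorted


def toy_competing():
    """The canonical 3-patient example: fall at 1, death at 2, censored at 3."""
    return np.array([1.0, 2.0, 3.0]), np.array([1, 2, 0])
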