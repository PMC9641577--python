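"""Subdistribution-hazard estimation against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.duration.hazard_regression import PHReg

from crisk.finegray import (FpTransform, censoring_km, fit_finegray,
                            fp_basis, predict_cif,
                            select_fractional_polynomial, schoenfeld_check,
                            StepFunction)


# --- censoring Kaplan-Meier -----------------------------------------------

class TestCensoringKM:
    def test_no_censoring_gives_unity(self):
        g = censoring_km([1.0, 2.0, 3.0], [1, 2, 1])
        assert np.allclose(g([0.5, 1.5, 5.0]), 1.0)

    def test_all_censored_distinct_times(self):
        g = censoring_km([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0])
        # drops by (n_j - 1)/n_j at each time
        expected = np.cumprod([3 / 4, 2 / 3, 1 / 2, 0.0])
        assert np.allclose(g([1.0, 2.0, 3.0, 4.0]), expected)

    def test_mixed_toy_against_brute_force(self):
        time = np.array([1.0, 1.5, 2.0, 2.5, 3.0])
        event = np.array([1, 0, 2, 0, 1])
        g = censoring_km(time, event)
        # product over risk sets, censoring as the event
        for t in [0.9, 1.6, 2.6, 3.5]:
            prod = 1.0
            for tj, ej in zip(time, event):
                if ej == 0 and tj <= t:
                    n_at_risk = np.sum(time >= tj)
                    prod *= 1 - 1 / n_at_risk
            assert g(t) == pytest.approx(prod, abs=1e-12)


# --- weighted partial likelihood ------------------------------------------

def brute_force_fg_loglik(X, time, event, beta):
    """Literal weighted partial likelihood with IPC weights."""
    G = censoring_km(time, event)
    eta = X @ beta
    ll = 0.0
    for i in np.where(event == 1)[0]:
        t_i = time[i]
        denom = 0.0
        for j in range(len(time)):
            if time[j] >= t_i:
                w = 1.0
            elif event[j] == 2:
                w = G(t_i, side="left") / G(time[j], side="left")
            else:
                continue
            denom += w * np.exp(eta[j])
        ll += eta[i] - np.log(denom)
    return ll


def _random_competing(rng, n):
    x1 = rng.normal(size=n)
    x2 = rng.binomial(1, 0.4, n).astype(float)
    lp = 0.6 * x1 - 0.3 * x2
    t1 = rng.exponential(np.exp(-lp))
    t2 = rng.exponential(1.5, n)
    cause = np.where(rng.random(n) < 0.7, 1, 2)
    t = np.where(cause == 1, t1, t2)
    c = rng.exponential(2.0, n)
    return pd.DataFrame({
        "x1": x1, "x2": x2,
        "time": np.minimum(t, c),
        "event": np.where(t <= c, cause, 0)})


class TestFitFineGray:
    def test_loglik_matches_brute_force(self, rng):
        for _ in range(10):
            df = _random_competing(rng, 40)
            if df["event"].eq(1).sum() < 3:
                continue
            res = fit_finegray(df, "time", "event", ["x1", "x2"])
            X = df[["x1", "x2"]].to_numpy() - res.centering
            for beta in (np.zeros(2), res.coef, np.array([0.3, -0.2])):
                ll = brute_force_fg_loglik(
                    X, df["time"].to_numpy(), df["event"].to_numpy(), beta)
                from crisk.finegray import _fg_loglik_parts
                order = np.argsort(df["time"].to_numpy(), kind="stable")
                ts = df["time"].to_numpy()[order]
                es = df["event"].to_numpy()[order]
                G = censoring_km(df["time"], df["event"])
                gl = np.asarray(G(ts, side="left"))
                uniq = np.unique(ts[es == 1])
                mine = _fg_loglik_parts(
                    X[order], ts, es, beta, 1.0 / gl,
                    np.asarray(G(uniq, side="left")))[0]
                assert mine == pytest.approx(ll, abs=1e-9)

    def test_score_vanishes_at_optimum(self, rng):
        df = _random_competing(rng, 200)
        res = fit_finegray(df, "time", "event", ["x1", "x2"])
        assert res.grad_norm < 1e-6

    def test_score_at_zero_matches_numeric_gradient(self, rng):
        # 6-record toy set with one binary covariate and a competing event
        df = pd.DataFrame({
            "x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
            "time": [0.5, 1.0, 1.5, 2.0, 2.5, 3.0],
            "event": [1, 2, 1, 0, 1, 0]})
        from crisk.finegray import _fg_loglik_parts
        X = df[["x"]].to_numpy() - df["x"].mean()
        time, event = df["time"].to_numpy(), df["event"].to_numpy()
        G = censoring_km(time, event)
        gl = np.asarray(G(time, side="left"))
        uniq = np.unique(time[event == 1])
        gle = np.asarray(G(uniq, side="left"))
        _, score, _, _ = _fg_loglik_parts(X, time, event, np.zeros(1),
                                          1.0 / gl, gle)
        eps = 1e-6
        num = (brute_force_fg_loglik(X, time, event, np.array([eps]))
               - brute_force_fg_loglik(X, time, event, np.array([-eps]))) \
            / (2 * eps)
        assert score[0] == pytest.approx(num, abs=1e-6)

    def test_reduces_to_cox_without_competing_events(self, rng):
        # with no cause-2 events the weighted likelihood is the Cox
        # partial likelihood; compare against statsmodels PHReg
        worst = 0.0
        for _ in range(30):
            n = int(rng.integers(30, 80))
            df = _random_competing(rng, n)
            df.loc[df["event"] == 2, "event"] = 1
            if df["event"].sum() < 5:
                continue
            res = fit_finegray(df, "time", "event", ["x1", "x2"])
            ph = PHReg(df["time"], df[["x1", "x2"]], status=df["event"],
                       ties="breslow").fit()
            worst = max(worst, float(np.max(np.abs(res.coef - ph.params))))
        assert worst < 1e-6

    def test_baseline_matches_cox_breslow_estimator(self, rng):
        # no competing events, no censoring: H0 equals the Breslow
        # cumulative hazard of a standard Cox fit at the same centring
        n = 80
        df = _random_competing(rng, n)
        df["event"] = 1
        res = fit_finegray(df, "time", "event", ["x1", "x2"])
        X = df[["x1", "x2"]].to_numpy() - res.centering
        eta = np.exp(X @ res.coef)
        times = np.sort(df["time"].to_numpy())
        h0 = 0.0
        for t in times:
            h0 += 1.0 / eta[df["time"].to_numpy() >= t].sum()
            assert res.baseline_hazard(t) == pytest.approx(h0, abs=1e-8)

    def test_parameter_recovery(self, recovery_study):
        cfg, _, _, _, fit = recovery_study
        for name, truth in cfg.beta.items():
            i = fit.columns.index(name)
            assert abs(fit.coef[i] - truth) < 0.05
            assert abs(fit.coef[i] - truth) < 3 * fit.se[i]

    def test_null_covariate_shr_near_one(self, rng):
        # a covariate unrelated to the outcome has SHR in [0.95, 1.05]
        n = 20_000
        df = _random_competing(rng, n)
        df["noise"] = rng.normal(size=n)
        res = fit_finegray(df, "time", "event", ["x1", "x2", "noise"])
        shr = float(np.exp(res.coef[res.columns.index("noise")]))
        assert 0.95 < shr < 1.05

    def test_collinear_covariates_named(self, rng):
        df = _random_competing(rng, 50)
        df["x3"] = 2.0 * df["x1"]
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_finegray(df, "time", "event", ["x1", "x2", "x3"])

    def test_requires_cause1_events(self, rng):
        df = _random_competing(rng, 20)
        df["event"] = 0
        with pytest.raises(ValueError):
            fit_finegray(df, "time", "event", ["x1"])


# --- prediction -----------------------------------------------------------

class TestPredictCif:
    def _model(self, cif10=0.05):
        h0 = -np.log(1 - cif10)
        from crisk.finegray import FineGrayResult
        return FineGrayResult(
            columns=["x"], coef=np.array([0.7]), se=np.array([0.1]),
            cov=np.eye(1) * 0.01, centering=np.array([0.0]),
            baseline_hazard=StepFunction([1.0], [h0], init=0.0))

    def test_zero_lp_returns_baseline(self):
        m = self._model(0.05)
        assert predict_cif(m, t=5.0, lp=0.0) == pytest.approx(0.05)

    def test_closed_form_doubling(self):
        m = self._model(0.05)
        # CIF0 = 0.05 and LP = ln 2 gives 1 - 0.95^2 = 0.0975
        assert predict_cif(m, t=5.0, lp=np.log(2.0)) \
            == pytest.approx(0.0975, abs=1e-12)

    def test_time_zero_risk_zero(self):
        assert predict_cif(self._model(), t=0.0, lp=1.3) == 0.0

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            predict_cif(self._model(), t=-1.0, lp=0.0)

    def test_monotone_in_time_and_lp(self, recovery_study):
        _, _, _, _, fit = recovery_study
        lp = np.linspace(-2, 2, 25)
        for t1, t2 in [(1.0, 5.0), (5.0, 10.0)]:
            r1 = predict_cif(fit, t=t1, lp=lp)
            r2 = predict_cif(fit, t=t2, lp=lp)
            assert np.all(r2 >= r1)
        risks = predict_cif(fit, t=10.0, lp=lp)
        assert np.all(np.diff(risks) > 0)


# --- fractional polynomials -----------------------------------------------

class TestFractionalPolynomials:
    def test_log_basis_at_e(self):
        # powers (0, 0) at x = e give (ln e, ln e * ln e) = (1, 1)
        basis = fp_basis(np.array([np.e]), (0.0, 0.0))
        assert np.allclose(basis, [[1.0, 1.0]])

    def test_repeated_power_basis(self):
        basis = fp_basis(np.array([2.0]), (2.0, 2.0))
        assert np.allclose(basis, [[4.0, 4.0 * np.log(2.0)]])

    def test_nonpositive_rejected_without_shift(self):
        with pytest.raises(ValueError, match="positive"):
            fp_basis(np.array([-1.0, 2.0]), (0.5,))
        with pytest.raises(ValueError, match="positive"):
            fp_basis(np.array([0.0, 2.0]), (0.0,))
        # plain positive integer powers are defined everywhere
        assert np.allclose(fp_basis(np.array([-1.0]), (1.0,)), [[-1.0]])

    @staticmethod
    def _cox_frame(rng, n, effect):
        x = rng.uniform(1.0, 3.0, n)
        t = rng.exponential(np.exp(-effect(x)))
        c = rng.exponential(1.0, n)
        return pd.DataFrame({"x": x, "time": np.minimum(t, c),
                             "event": (t <= c).astype(int)})

    def test_linear_truth_selects_first_power(self, rng):
        hits = 0
        for _ in range(10):
            df = self._cox_frame(rng, 500, lambda x: 0.8 * x)
            tr = select_fractional_polynomial(df, "time", "event", ["x"],
                                              "x")
            hits += tr.powers == (1.0,)
        assert hits >= 8

    def test_quadratic_truth_selects_square(self, rng):
        hits = 0
        for _ in range(5):
            df = self._cox_frame(rng, 800, lambda x: 0.6 * x ** 2)
            tr = select_fractional_polynomial(df, "time", "event", ["x"],
                                              "x")
            hits += 2.0 in tr.powers or 3.0 in tr.powers
        assert hits >= 4

    def test_invalid_power_rejected(self):
        with pytest.raises(ValueError):
            FpTransform("x", (1.7,))


# --- proportional hazards diagnostic --------------------------------------

class TestSchoenfeld:
    def test_residuals_sum_to_zero(self, rng):
        df = _random_competing(rng, 300)
        res = fit_finegray(df, "time", "event", ["x1", "x2"])
        # the score at the optimum is the residual sum; already < 1e-6
        assert res.grad_norm < 1e-6
        table = schoenfeld_check(res, df, "time", "event", ["x1", "x2"])
        assert set(table.index) == {"x1", "x2"}

    def test_type_one_error_near_nominal(self):
        # the null must hold proportional subdistribution hazards, so the
        # data come from the generator's own Fine-Gray event process
        from crisk.cohort import (SimulationConfig, build_model_frame,
                                  generate_cohort)
        flags = 0
        reps = 30
        for s in range(reps):
            cfg = SimulationConfig(
                n_patients=700, beta={"age_std": 0.5, "sex_female": 0.3},
                p_cause1=0.3, death_rate=0.02, censor_rate=0.05,
                practice_sd=0.0, missing_rates={}, seed=5000 + s)
            patients, outcomes = generate_cohort(cfg)
            f = build_model_frame(patients)
            f["time"] = outcomes["time"].to_numpy()
            f["event"] = outcomes["event"].to_numpy()
            res = fit_finegray(f, "time", "event",
                               ["age_std", "sex_female"])
            table = schoenfeld_check(res, f, "time", "event",
                                     ["age_std", "sex_female"])
            flags += int(table["flag"].sum())
        rate = flags / (2 * reps)
        assert rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / (2 * reps))

    def test_time_varying_effect_detected(self, rng):
        flagged = 0
        reps = 20
        for _ in range(reps):
            n = 400
            x = rng.binomial(1, 0.5, n).astype(float)
            # hazard ratio flips over time: protective early, harmful late
            t_break = 0.7
            r1 = 0.8 * np.exp(-1.2 * x)
            t = rng.exponential(1 / r1)
            late = t > t_break
            r2 = 0.8 * np.exp(1.2 * x[late])
            t[late] = t_break + rng.exponential(1 / r2)
            c = np.full(n, 4.0)
            df = pd.DataFrame({"x": x, "time": np.minimum(t, c),
                               "event": (t <= c).astype(int)})
            res = fit_finegray(df, "time", "event", ["x"])
            table = schoenfeld_check(res, df, "time", "event", ["x"])
            flagged += int(table["flag"].iloc[0])
        assert flagged >= 0.9 * reps

    def test_too_few_events_rejected(self, rng):
        df = _random_competing(rng, 10)
        df["event"] = [1] + [0] * 9
        res_df = df.copy()
        res_df.loc[1:, "event"] = 0
        res = fit_finegray(df, "time", "event", ["x1"])
        with pytest.raises(ValueError):
            schoenfeld_check(res, res_df, "time", "event", ["x1"])
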