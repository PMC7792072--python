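"""Bespoke survival and binary analyses against hand and library oracles."""

import math

import numpy as np
import pandas as pd
import pytest

from multiarm.endpoint_analysis import (fit_logistic, fit_ph, logrank,
                                        logrank_arrays, two_prop_test)


def _two_arm_cohort(rng, n=120, log_hr=-0.5, cens_scale=2.0):
    """Exponential two-arm cohort whose true Cox coefficients are
    (log_hr, 0.2) for (arm, age)."""
    x = rng.integers(0, 2, n)
    age = rng.normal(0, 1, n)
    t = rng.exponential(np.exp(-(log_hr * x + 0.2 * age)), n)
    c = rng.exponential(cens_scale, n)
    return pd.DataFrame({
        "time": np.minimum(t, c), "event": (t <= c).astype(int),
        "arm": x, "age": age,
    })


class TestLogrank:
    def test_six_patient_hand_computation(self):
        # events at t=1,3 (group 0) and t=2,4,6 (group 1); censored at t=5.
        # By hand: O1=3, E1 = 3/6 + 3/5 + 1/2 + 2/3 + 1 = 49/15,
        # V = 1/4 + 6/25 + 1/4 + 2/9 = 0.962222; chi = (3-49/15)^2 / V.
        tab = pd.DataFrame({
            "time": [1, 2, 3, 4, 5, 6],
            "event": [1, 1, 1, 1, 0, 1],
            "arm": [0, 1, 0, 1, 0, 1],
        })
        chi, p = logrank(tab)
        o_minus_e = 3 - 49 / 15
        var = 1 / 4 + 6 / 25 + 1 / 4 + 2 / 9
        assert chi == pytest.approx(o_minus_e**2 / var, rel=1e-12)

    def test_symmetric_arms_give_zero_statistic(self):
        tab = pd.DataFrame({"time": [1, 1, 2, 2, 3, 3],
                            "event": [1, 1, 1, 1, 1, 1],
                            "arm": [0, 1, 0, 1, 0, 1]})
        chi, p = logrank(tab)
        assert chi == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_null_calibration(self, rng):
        """Rejection at nominal 5% occurs in 5% +/- 3 MC SE of null cohorts."""
        reps, n = 4000, 100
        rej = 0
        for _ in range(reps):
            t = rng.exponential(1.0, n)
            c = rng.exponential(2.0, n)
            g = np.arange(n) % 2
            _, _, p = logrank_arrays(np.minimum(t, c), t <= c, g)
            rej += p < 0.05
        se = math.sqrt(0.05 * 0.95 / reps)
        assert rej / reps == pytest.approx(0.05, abs=3 * se)

    def test_one_group_empty_rejected(self):
        with pytest.raises(ValueError):
            logrank_arrays(np.r_[1.0, 2.0], np.r_[True, True], np.r_[1, 1])


class TestPHFit:
    def test_score_test_equals_logrank_single_binary_covariate(self, rng):
        tab = _two_arm_cohort(rng)
        fit = fit_ph(tab, covariates=["arm"])
        chi, _ = logrank(tab)
        assert fit.score_statistic == pytest.approx(chi, rel=1e-10)

    def test_matches_lifelines_on_random_fixtures(self, rng):
        from lifelines import CoxPHFitter
        worst = 0.0
        for _ in range(20):
            tab = _two_arm_cohort(rng, n=150, log_hr=rng.uniform(-0.8, 0.2))
            fit = fit_ph(tab, covariates=["arm", "age"])
            ref = CoxPHFitter().fit(tab, "time", "event")
            worst = max(worst,
                        np.abs(fit.coefficients
                               - ref.params_[["arm", "age"]].to_numpy()).max(),
                        np.abs(fit.standard_errors
                               - ref.standard_errors_[["arm", "age"]].to_numpy()).max())
        assert worst < 1e-4

    def test_breslow_ties_match_r_survival_fixture(self, rng_unused=None):
        # fixture regenerated deterministically; reference values from
        # coxph(Surv(time,event) ~ arm + z, ties="breslow")
        r = np.random.default_rng(42)
        n = 40
        x = r.integers(0, 2, n)
        z = r.integers(0, 2, n)
        t = np.round(r.exponential(np.exp(-0.7 * x + 0.3 * z), n), 1) + 0.1
        c = np.round(r.exponential(1.5, n), 1) + 0.1
        tab = pd.DataFrame({"time": np.minimum(t, c), "event": (t <= c).astype(int),
                            "arm": x, "z": z})
        assert tab["time"].duplicated().any()
        fit = fit_ph(tab, covariates=["arm", "z"])
        assert fit.coefficients == pytest.approx(
            [0.776606636461, -0.385084207277], abs=1e-8)
        assert fit.standard_errors == pytest.approx(
            [0.418500485321, 0.416901141307], abs=1e-8)

    def test_parameter_recovery_large_cohort(self, rng):
        tab = _two_arm_cohort(rng, n=10_000, log_hr=math.log(0.75), cens_scale=5.0)
        fit = fit_ph(tab, covariates=["arm"])
        assert abs(fit.coefficients[0] - math.log(0.75)) < 3 * fit.standard_errors[0]
        assert fit.converged

    def test_affine_rescaling_leaves_arm_hr_unchanged(self, rng):
        tab = _two_arm_cohort(rng)
        fit1 = fit_ph(tab, covariates=["arm", "age"])
        tab2 = tab.assign(age=tab["age"] * 100 + 7)
        fit2 = fit_ph(tab2, covariates=["arm", "age"])
        assert fit1.coefficients[0] == pytest.approx(fit2.coefficients[0], abs=1e-8)

    def test_zero_events_rejected(self):
        tab = pd.DataFrame({"time": [1.0, 2.0], "event": [0, 0], "arm": [0, 1]})
        with pytest.raises(ValueError, match="event"):
            fit_ph(tab)

    def test_monotone_likelihood_flagged_not_silent(self):
        # all events in one arm, perfectly ordered: likelihood is monotone
        tab = pd.DataFrame({"time": [1, 2, 3, 4, 10, 11, 12, 13],
                            "event": [1, 1, 1, 1, 0, 0, 0, 0],
                            "arm": [1, 1, 1, 1, 0, 0, 0, 0]})
        fit = fit_ph(tab, covariates=["arm"])
        assert fit.separated or not fit.converged


class TestBinary:
    def test_design_n_detects_ten_to_twenty_percent(self):
        z, p = two_prop_test(26, 260, 52, 260)
        assert p < 0.05
        assert z > 0

    def test_equal_counts_give_zero(self):
        z, p = two_prop_test(30, 100, 30, 100)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_logistic_matches_statsmodels(self, rng):
        import statsmodels.api as sm
        x = rng.integers(0, 2, 400)
        y = (rng.random(400) < 1 / (1 + np.exp(-(-1.2 + 0.9 * x)))).astype(int)
        tab = pd.DataFrame({"mrd_negative": y, "arm": x})
        fit = fit_logistic(tab, covariates=["arm"])
        ref = sm.Logit(y, sm.add_constant(x.astype(float))).fit(disp=0)
        assert fit.coefficients == pytest.approx(ref.params, abs=1e-8)
        assert fit.standard_errors == pytest.approx(ref.bse, abs=1e-6)

    def test_intercept_plus_arm_logistic_close_to_unpooled_z(self, rng):
        x = rng.integers(0, 2, 600)
        y = (rng.random(600) < 0.15 + 0.1 * x).astype(int)
        tab = pd.DataFrame({"mrd_negative": y, "arm": x})
        fit = fit_logistic(tab, covariates=["arm"])
        ix = fit.covariate_names.index("arm")
        # Wald z of the arm log-odds vs the proportion z-statistic
        x1, n1 = y[x == 1].sum(), (x == 1).sum()
        x0, n0 = y[x == 0].sum(), (x == 0).sum()
        z_prop, _ = two_prop_test(x0, n0, x1, n1)
        assert abs(abs(fit.wald_z[ix]) - abs(z_prop)) < 0.25

    def test_separation_flagged(self):
        tab = pd.DataFrame({"mrd_negative": [0, 0, 0, 1, 1, 1],
                            "arm": [0, 0, 0, 1, 1, 1]})
        fit = fit_logistic(tab, covariates=["arm"])
        assert fit.separated
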