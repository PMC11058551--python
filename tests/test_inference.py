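import math

import numpy as np
import pytest
from dataclasses import replace

from survpower import (
    Cohort,
    NoEventsError,
    NotConvergedError,
    example_scenario,
    exponential_mle_oracle,
    fit_weibull_ph,
    generate_cohort,
    predict_survival,
    wald_hr_test,
    wald_summary,
    weibull_ph_loglik,
)
from survpower.weibull_inference import _ll_grad_hess, _design


def _single_subject(t, d, x=0, z=0):
    return Cohort(
        subject_id=np.array([1]),
        z=np.array([z]),
        x=np.array([x]),
        time=np.array([t]),
        event=np.array([d]),
    )


class TestLoglik:
    def test_single_event_unit_time(self):
        ll = weibull_ph_loglik([0.0, 0.0, 0.0], 0.0, _single_subject(1.0, 1))
        assert ll == pytest.approx(-1.0)

    def test_single_censored(self):
        ll = weibull_ph_loglik(
            [math.log(0.007), 0.0, 0.0], 0.0, _single_subject(10.0, 0)
        )
        assert ll == pytest.approx(-0.07)

    def test_matches_loop_oracle(self, cohort):
        beta = np.array([-4.5, -0.3, 1.2])
        log_gamma = 0.08
        total = 0.0
        g = math.exp(log_gamma)
        for i in range(len(cohort)):
            lp = beta[0] + beta[1] * cohort.x[i] + beta[2] * cohort.z[i]
            t, d = cohort.time[i], cohort.event[i]
            total += d * (log_gamma + (g - 1) * math.log(t) + lp) - math.exp(lp) * t**g
        assert weibull_ph_loglik(beta, log_gamma, cohort) == pytest.approx(total, rel=1e-12)

    def test_nonpositive_time_rejected(self):
        # invalid times are caught at cohort construction already
        with pytest.raises(ValueError):
            Cohort(
                subject_id=np.array([1]),
                z=np.array([0]),
                x=np.array([0]),
                time=np.array([0.0]),
                event=np.array([1]),
            )

    def test_analytic_gradient_matches_finite_differences(self, cohort):
        t, d, X = _design(cohort)
        logt = np.log(t)
        theta = np.array([-4.8, -0.2, 1.3, 0.1])
        _, grad, H = _ll_grad_hess(theta, t, d, X, logt)
        eps = 1e-6
        for k in range(4):
            bump = np.zeros(4)
            bump[k] = eps
            ll_hi, _, _ = _ll_grad_hess(theta + bump, t, d, X, logt)
            ll_lo, _, _ = _ll_grad_hess(theta - bump, t, d, X, logt)
            fd = (ll_hi - ll_lo) / (2 * eps)
            assert grad[k] == pytest.approx(fd, rel=1e-5)
            _, g_hi, _ = _ll_grad_hess(theta + bump, t, d, X, logt)
            _, g_lo, _ = _ll_grad_hess(theta - bump, t, d, X, logt)
            np.testing.assert_allclose(H[:, k], (g_hi - g_lo) / (2 * eps), rtol=1e-4)


class TestFit:
    def test_parameter_recovery_large_n(self, scenario):
        scn = scenario.with_n(200_000)
        cohort = generate_cohort(scn, np.random.default_rng(77))
        fit = fit_weibull_ph(cohort)
        assert fit.converged
        assert fit.coefficients[1] == pytest.approx(math.log(0.8), abs=0.02)
        assert fit.gamma == pytest.approx(1.1, abs=0.03)

    def test_mle_beats_truth(self, scenario, cohort):
        fit = fit_weibull_ph(cohort)
        out = scenario.outcome
        ll_truth = weibull_ph_loglik(
            [out.beta0, out.beta1, out.beta2], math.log(out.gamma), cohort
        )
        assert fit.loglik >= ll_truth

    def test_no_events_error(self):
        cohort = Cohort(
            subject_id=np.arange(1, 5),
            z=np.array([0, 1, 0, 1]),
            x=np.array([0, 0, 1, 1]),
            time=np.full(4, 10.0),
            event=np.zeros(4, dtype=int),
        )
        with pytest.raises(NoEventsError):
            fit_weibull_ph(cohort)

    def test_row_permutation_invariance(self, cohort):
        fit = fit_weibull_ph(cohort)
        perm = np.random.default_rng(8).permutation(len(cohort))
        shuffled = Cohort(
            subject_id=cohort.subject_id[perm],
            z=cohort.z[perm],
            x=cohort.x[perm],
            time=cohort.time[perm],
            event=cohort.event[perm],
        )
        fit2 = fit_weibull_ph(shuffled)
        np.testing.assert_allclose(fit2.coefficients, fit.coefficients, atol=1e-8)
        assert fit2.log_gamma == pytest.approx(fit.log_gamma, abs=1e-8)

    def test_permutation_null_rejection_rate(self, scenario):
        # breaking the exposure-outcome link should leave |z| < 1.96 ~95% of the time
        scn = scenario.with_n(2000)
        cohort = generate_cohort(scn, np.random.default_rng(21))
        rng = np.random.default_rng(22)
        inside = 0
        for _ in range(200):
            permuted = Cohort(
                subject_id=cohort.subject_id,
                z=cohort.z,
                x=rng.permutation(cohort.x),
                time=cohort.time,
                event=cohort.event,
            )
            fit = fit_weibull_ph(permuted)
            w = wald_hr_test(fit, 1)
            inside += abs(w.z) < 1.959964
        assert inside >= 0.93 * 200

    def test_coverage_of_true_log_hr(self, alt_replications):
        # 95% Wald CI should cover ln(0.8) in 95% +- 3% of replicates
        res = alt_replications
        crit = 1.959963984540054
        est = res.estimates[res.converged]
        ses = res.ses[res.converged]
        covered = np.abs(est - math.log(0.8)) < crit * ses
        assert abs(covered.mean() - 0.95) < 0.03

    def test_consistency_of_beta1(self, alt_replications):
        res = alt_replications
        est = res.estimates[res.converged]
        mc_se = est.std(ddof=1) / math.sqrt(len(est))
        assert abs(est.mean() - math.log(0.8)) < 3 * mc_se


class TestExponentialSubModel:
    """Shape fixed at 1: closed-form and independent-GLM cross-checks."""

    @staticmethod
    def _crafted_cohort():
        # per-pattern rates obeying rate(z,x) = 0.01 * 0.8**x * 4**z exactly:
        # events at t=5, censoring at t=10, so events/person-time is exact
        rows = {"z": [], "x": [], "time": [], "event": []}
        spec = {(0, 0): (10, 95), (0, 1): (8, 96), (1, 0): (40, 80), (1, 1): (32, 84)}
        for (z, x), (n_event, n_cens) in spec.items():
            rows["z"] += [z] * (n_event + n_cens)
            rows["x"] += [x] * (n_event + n_cens)
            rows["time"] += [5.0] * n_event + [10.0] * n_cens
            rows["event"] += [1] * n_event + [0] * n_cens
        n = len(rows["z"])
        return Cohort(
            subject_id=np.arange(1, n + 1),
            z=np.array(rows["z"]),
            x=np.array(rows["x"]),
            time=np.array(rows["time"]),
            event=np.array(rows["event"]),
        )

    def test_saturated_oracle_rates(self):
        table = exponential_mle_oracle(self._crafted_cohort())
        rates = {(r.z, r.x): r.rate for r in table.itertuples()}
        assert rates[(0, 0)] == pytest.approx(0.01, rel=1e-12)
        assert rates[(0, 1)] == pytest.approx(0.008, rel=1e-12)
        assert rates[(1, 0)] == pytest.approx(0.04, rel=1e-12)
        assert rates[(1, 1)] == pytest.approx(0.032, rel=1e-12)

    def test_fixed_shape_fit_matches_saturated_rates(self):
        # the crafted rates satisfy the no-interaction model exactly, so the
        # 3-parameter MLE coincides with the saturated closed form
        fit = fit_weibull_ph(self._crafted_cohort(), fixed_gamma=1.0)
        assert fit.converged
        assert math.exp(fit.coefficients[0]) == pytest.approx(0.01, abs=1e-6)
        assert math.exp(fit.coefficients[1]) == pytest.approx(0.8, abs=1e-6)
        assert math.exp(fit.coefficients[2]) == pytest.approx(4.0, abs=1e-6)

    def test_fixed_shape_fit_matches_statsmodels_glm(self, exponential_scenario):
        sm = pytest.importorskip("statsmodels.api")
        scn = exponential_scenario.with_n(20_000)
        cohort = generate_cohort(scn, np.random.default_rng(9))
        fit = fit_weibull_ph(cohort, fixed_gamma=1.0)
        table = exponential_mle_oracle(cohort)
        X = np.column_stack([np.ones(4), table.x, table.z])
        glm = sm.GLM(
            table.events,
            X,
            family=sm.families.Poisson(),
            offset=np.log(table.person_time),
        ).fit()
        np.testing.assert_allclose(fit.coefficients, glm.params, atol=1e-3)

    def test_free_shape_near_one_on_exponential_data(self, exponential_scenario):
        cohort = generate_cohort(
            exponential_scenario.with_n(50_000), np.random.default_rng(10)
        )
        fit = fit_weibull_ph(cohort)
        assert fit.gamma == pytest.approx(1.0, abs=0.05)


class TestWald:
    def test_printed_example_consistency(self):
        # z and p implied by estimate ln(0.89) with SE back-derived from z=-1.52
        w = wald_summary(math.log(0.89), 0.0766)
        assert w.z == pytest.approx(-1.52, abs=0.005)
        assert w.p_two_sided == pytest.approx(0.13, abs=0.005)
        assert w.hr == pytest.approx(0.89)

    def test_null_estimate(self):
        w = wald_summary(0.0, 0.5)
        assert w.z == 0.0
        assert w.p_two_sided == pytest.approx(1.0)
        assert w.ci_low * w.ci_high == pytest.approx(1.0)  # symmetric on log scale

    def test_ci_collapses_with_tiny_se(self):
        w = wald_summary(0.3, 1e-10)
        assert w.ci_low == pytest.approx(math.exp(0.3), rel=1e-6)
        assert w.ci_high == pytest.approx(math.exp(0.3), rel=1e-6)

    def test_invariants(self, cohort):
        fit = fit_weibull_ph(cohort)
        w = wald_hr_test(fit, 1, 0.95)
        assert w.hr == pytest.approx(math.exp(w.estimate))
        assert w.ci_low < w.hr < w.ci_high
        assert w.z == pytest.approx(w.estimate / w.se)

    def test_refuses_non_converged(self, cohort):
        fit = fit_weibull_ph(cohort)
        bad = replace(fit, converged=False)
        with pytest.raises(NotConvergedError):
            wald_hr_test(bad, 1)

    def test_bad_se_rejected(self):
        with pytest.raises(ValueError):
            wald_summary(0.1, 0.0)


class TestPredictSurvival:
    def test_paper_pattern_values(self, scenario):
        out = scenario.outcome
        # frozen closed forms exp(-(7/1000)*0.8**x * 10**1.1)
        assert predict_survival(out, [10.0], x=0, z=0)[0] == pytest.approx(
            0.9156466162853951, rel=1e-12
        )
        assert predict_survival(out, [10.0], x=1, z=0)[0] == pytest.approx(
            0.931927904420668, rel=1e-12
        )

    def test_limits_and_monotonicity(self, scenario):
        times = np.linspace(0.0, 50.0, 200)
        s = predict_survival(scenario.outcome, times, x=1, z=1)
        assert s[0] == pytest.approx(1.0)
        assert (np.diff(s) <= 0).all()

    def test_accepts_fit_result(self, cohort):
        fit = fit_weibull_ph(cohort)
        s = predict_survival(fit, [1.0, 5.0, 10.0], x=0, z=0)
        assert ((0 < s) & (s < 1)).all()

    def test_negative_times_rejected(self, scenario):
        with pytest.raises(ValueError):
            predict_survival(scenario.outcome, [-1.0], x=0, z=0)
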