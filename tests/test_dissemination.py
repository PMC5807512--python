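"""Current-status NPMLE, parametric cure models, BIC, GOF, hazards,
quantiles and bootstrap intervals."""

import math

import numpy as np
import pytest

from occultevo import synth
from occultevo.dissemination import (FAMILIES, ParametricCureModel,
                                     bootstrap_ci, fit_parametric,
                                     goodness_of_fit, hazard, model_quantile,
                                     model_select, pava_current_status,
                                     turnbull_npmle)


def turnbull_loglik(est, t, event):
    p = est.cdf(t)
    return float(np.where(event, np.log(np.maximum(p, 1e-300)),
                          np.log(np.maximum(1 - p, 1e-300))).sum())


class TestTurnbull:
    def test_all_events_mass_below_min(self):
        est = turnbull_npmle([2.0, 3.0, 1.0], [1, 1, 1])
        assert est.cdf([1.0, 2.0, 5.0]) == pytest.approx([1, 1, 1])

    def test_no_events_zero_mass(self):
        est = turnbull_npmle([1.0, 2.0], [0, 0])
        assert est.cdf([1.0, 2.0, 100.0]) == pytest.approx([0, 0, 0])

    def test_alternating_example_is_flat_half(self):
        est = turnbull_npmle([1, 2, 3, 4], [1, 0, 1, 0])
        assert est.cdf([1, 2, 3, 4]) == pytest.approx([0.5] * 4, abs=1e-4)

    def test_equals_pava_oracle_random(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            n = rng.integers(3, 40)
            t = np.round(rng.uniform(0.1, 5.0, n), 2) + 0.01
            event = rng.random(n) < t / (t + 1)
            if event.all() or not event.any():
                continue
            est = turnbull_npmle(t, event)
            ts, fhat = pava_current_status(t, event)
            assert est.cdf(ts) == pytest.approx(fhat, abs=1e-4)

    def test_masses_valid_and_cdf_monotone(self):
        rng = np.random.default_rng(9)
        t = rng.uniform(0.1, 4, 30)
        event = rng.random(30) < 0.5
        est = turnbull_npmle(t, event)
        assert np.all(est.masses >= 0)
        assert est.masses.sum() <= 1 + 1e-9
        grid = np.linspace(0.01, 10, 200)
        f = est.cdf(grid)
        assert np.all(np.diff(f) >= -1e-12) and f.max() <= 1 + 1e-9


class TestFitParametric:
    def test_hand_computed_likelihood_point(self):
        # (t=1, event) and (t=1, no event) under cure-exponential with
        # pi=0.5, lambda=ln2: P = 0.5*0.5 = 0.25 -> ll = ln(.25)+ln(.75)
        model = ParametricCureModel(
            family="exponential", params={"theta": 1 / math.log(2)},
            pi=0.5, cure=True, loglik=0.0, n_obs=2)
        p = model.cdf([1.0])[0]
        assert p == pytest.approx(0.25, rel=1e-12)
        ll = math.log(0.25) + math.log(0.75)
        assert ll == pytest.approx(-1.674, abs=5e-4)

    def test_parameter_recovery_large_n(self):
        t, ev = synth.simulate_current_status(
            20_000, "std_log_logistic", {"theta": 0.5}, pi=0.652, seed=42)
        m = fit_parametric(t, ev, "std_log_logistic", cure=True)
        assert m.pi == pytest.approx(0.652, abs=0.03)
        assert m.params["theta"] == pytest.approx(0.5, abs=0.03)

    def test_no_cure_reports_pi_one(self):
        t, ev = synth.simulate_current_status(
            300, "exponential", {"theta": 2.0}, seed=0)
        m = fit_parametric(t, ev, "exponential", cure=False)
        assert m.pi == 1.0
        assert m.n_params == 1

    def test_loglik_bounded_by_turnbull(self):
        t, ev = synth.simulate_current_status(
            400, "std_log_logistic", {"theta": 0.5}, pi=0.7, seed=3)
        est = turnbull_npmle(t, ev)
        for fam in FAMILIES:
            m = fit_parametric(t, ev, fam, cure=True)
            assert m.loglik <= turnbull_loglik(est, t, ev) + 1e-6

    def test_cure_needs_both_states(self):
        with pytest.raises(ValueError):
            fit_parametric([1.0, 2.0], [1, 1], "exponential", cure=True)


class TestModelSelect:
    def test_bic_arithmetic(self):
        m = ParametricCureModel(family="exponential", params={"theta": 1.0},
                                pi=1.0, cure=True, loglik=-100.0,
                                n_obs=int(round(math.e ** 2)))
        # BIC = 200 + 2*ln(n); at n = e^2 this is 204 (n rounded to 7)
        assert m.bic == pytest.approx(204.0, abs=0.15)

    def test_single_family_table(self):
        t, ev = synth.simulate_current_status(
            200, "exponential", {"theta": 2.0}, seed=1)
        tab = model_select(t, ev, ["exponential"], cure=False)
        assert len(tab) == 1 and tab.index[0] == 1

    def test_true_family_usually_beats_heavy_tail(self):
        wins = 0
        for seed in range(10):
            t, ev = synth.simulate_current_status(
                5_000, "exponential", {"theta": 3.0}, seed=seed)
            tab = model_select(t, ev, ["exponential", "frechet"], cure=False)
            fams = list(tab["family"])
            wins += fams.index("exponential") < fams.index("frechet")
        assert wins >= 8


class TestGoodnessOfFit:
    def _model(self, theta=2.0):
        return ParametricCureModel(family="exponential",
                                   params={"theta": theta}, pi=1.0,
                                   cure=False, loglik=0.0, n_obs=100)

    def test_chi2_hand_arithmetic(self):
        # construct data whose grouped (O, E) are known: use the formula
        # directly on a two-group split
        chi2 = 25 / 15 + 25 / 15
        assert chi2 == pytest.approx(3.33, abs=0.01)

    def test_perfect_fit_large_sample(self):
        t, ev = synth.simulate_current_status(
            8_000, "exponential", {"theta": 2.0}, seed=2)
        m = fit_parametric(t, ev, "exponential", cure=False)
        chi2, df, p = goodness_of_fit(m, t, ev, 5)
        assert df == max(1, 5 - 1 - 1)
        assert p > 0.01  # correctly specified model should not be rejected

    def test_too_few_observations(self):
        m = self._model()
        with pytest.raises(ValueError):
            goodness_of_fit(m, [1, 2, 3, 4, 5], [1, 0, 1, 0, 1], 10)


class TestHazard:
    def test_exponential_memoryless(self):
        m = ParametricCureModel(family="exponential", params={"theta": 2.0},
                                pi=1.0, cure=False, loglik=0.0, n_obs=10)
        h = hazard(m, [0.5, 1, 5, 20])
        assert h == pytest.approx([0.5] * 4, rel=1e-9)

    def test_std_log_logistic_closed_form(self):
        m = ParametricCureModel(family="std_log_logistic",
                                params={"theta": 0.5}, pi=1.0, cure=False,
                                loglik=0.0, n_obs=10)
        # h(t) = 1/(t + theta) at pi = 1; h(0) = 2
        assert hazard(m, [1e-12])[0] == pytest.approx(2.0, rel=1e-6)
        grid = np.linspace(0.1, 20, 50)
        assert hazard(m, grid) == pytest.approx(1 / (grid + 0.5), rel=1e-9)

    def test_cure_hazard_strictly_decreasing(self):
        # seeding risk falls as tumours grow once a cure fraction exists
        m = ParametricCureModel(family="std_log_logistic",
                                params={"theta": 0.5}, pi=0.652, cure=True,
                                loglik=0.0, n_obs=10)
        h = hazard(m, np.linspace(0.1, 20, 100))
        assert np.all(np.diff(h) < 0)


class TestQuantiles:
    def _m(self, family, theta):
        return ParametricCureModel(family=family, params={"theta": theta},
                                   pi=1.0, cure=False, loglik=0.0, n_obs=10)

    def test_exponential_td15_from_td50(self):
        m = self._m("exponential", 10.3 / math.log(2))
        assert model_quantile(m, 0.5) == pytest.approx(10.3, abs=1e-9)
        assert round(model_quantile(m, 0.15), 1) == 2.4

    def test_std_log_logistic_td15_from_td50(self):
        m = self._m("std_log_logistic", 13.4)
        assert model_quantile(m, 0.15) == pytest.approx(
            13.4 * 0.15 / 0.85, rel=1e-12)
        assert round(model_quantile(m, 0.15), 1) == 2.4

    def test_median_returns_theta(self):
        m = self._m("std_log_logistic", 0.77)
        assert model_quantile(m, 0.5) == pytest.approx(0.77, rel=1e-12)

    def test_domain_error(self):
        with pytest.raises(ValueError):
            model_quantile(self._m("exponential", 1.0), 1.0)

    def test_quantile_inverts_cdf_all_families(self):
        for fam, params in [("weibull", {"theta": 2.0, "shape": 1.5}),
                            ("log_normal", {"mu": 0.3, "sigma": 0.8}),
                            ("frechet", {"theta": 2.0, "shape": 2.0})]:
            m = ParametricCureModel(family=fam, params=params, pi=1.0,
                                    cure=False, loglik=0.0, n_obs=10)
            for q in (0.15, 0.5, 0.9):
                t = model_quantile(m, q)
                assert m.base_cdf([t])[0] == pytest.approx(q, rel=1e-9)


class TestBootstrap:
    def test_reproducible_and_sane(self):
        t, ev = synth.simulate_current_status(
            300, "exponential", {"theta": 2.0}, seed=4)
        ci1 = bootstrap_ci(t, ev, "exponential", B=100, seed=11)
        ci2 = bootstrap_ci(t, ev, "exponential", B=100, seed=11)
        assert ci1["theta"] == ci2["theta"]
        lo, hi = ci1["theta"]
        assert lo < ci1["model"].params["theta"] < hi

    def test_b_too_small(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1, 2], [1, 0], "exponential", B=10)
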