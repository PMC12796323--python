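import numpy as np
import pandas as pd
import pytest
from scipy import optimize as sopt
from scipy import stats as sstats

import vtbind as v
from vtbind.bci import BCIModel, BCIParams, bic, compare_models, pseudo_r2
from conftest import make_trials


def posterior_log_odds(x, p_same, sigma, sigma_s):
    """Independent oracle: log p(C=1|x) / p(C=2|x) from the generative model.

    Under a common cause the true asynchrony is 0, so x ~ N(0, sigma^2);
    under separate causes x ~ N(0, sigma^2 + sigma_s^2).
    """
    l1 = np.log(p_same) + sstats.norm.logpdf(x, 0.0, sigma)
    l2 = np.log(1 - p_same) + sstats.norm.logpdf(
        x, 0.0, np.sqrt(sigma**2 + sigma_s**2)
    )
    return l1 - l2


class TestDecisionThreshold:
    def test_closed_form_value(self):
        thr = v.decision_threshold(0.5, 290.0, 290.0)
        assert thr.defined
        assert thr.k == pytest.approx(290.0 * np.sqrt(2.0 * np.log(2.0)), abs=1e-9)

    def test_vanishing_prior_undefined(self):
        thr = v.decision_threshold(1e-9, 150.0, 290.0)
        assert not thr.defined
        assert np.isnan(thr.k)

    def test_matches_posterior_equality_point(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            p_same = rng.uniform(0.2, 0.95)
            sigma = rng.uniform(40.0, 400.0)
            sigma_s = rng.choice([290.0, 293.0])
            thr = v.decision_threshold(p_same, sigma, sigma_s)
            if not thr.defined:
                # oracle agrees: C=2 wins even at the most favourable x = 0
                assert posterior_log_odds(0.0, p_same, sigma, sigma_s) <= 0
                continue
            root = sopt.brentq(
                posterior_log_odds, 1e-9, 1e5, args=(p_same, sigma, sigma_s),
                xtol=1e-10,
            )
            assert thr.k == pytest.approx(root, abs=1e-6)
            # MAP category flips exactly at the threshold
            assert posterior_log_odds(0.99 * thr.k, p_same, sigma, sigma_s) > 0
            assert posterior_log_odds(1.01 * thr.k, p_same, sigma, sigma_s) < 0


class TestPredictPYes:
    def test_pure_lapse_is_half(self):
        params = BCIParams(0.7, 0.6, 150.0, 1.0)
        s = np.array([-400.0, 0.0, 250.0])
        assert v.predict_p_yes(s, params, "ownership", 293.0) == pytest.approx(0.5)

    def test_window_swallows_everything(self):
        params = BCIParams(1 - 1e-15, 0.6, 290.0, 0.0)
        assert v.predict_p_yes(0.0, params, "ownership", 290.0) >= 0.99999

    def test_undefined_threshold_gives_half_lapse(self):
        params = BCIParams(1e-9 + 1e-12, 0.6, 150.0, 0.1)
        assert v.predict_p_yes(0.0, params, "ownership", 290.0) == pytest.approx(0.05)

    def test_even_monotone_bounded(self):
        rng = np.random.default_rng(3)
        s = np.linspace(0.0, 800.0, 41)
        for _ in range(25):
            params = BCIParams(
                rng.uniform(0.05, 0.95), 0.6,
                rng.uniform(30.0, 400.0), rng.uniform(0.0, 0.9),
            )
            up = v.predict_p_yes(s, params, "ownership", 293.0)
            down = v.predict_p_yes(-s, params, "ownership", 293.0)
            assert np.allclose(up, down, atol=1e-12)  # even in s
            assert (np.diff(up) <= 1e-12).all()  # nonincreasing in |s|
            lo, hi = 0.5 * params.lapse, 1.0 - 0.5 * params.lapse
            assert (up >= lo - 1e-12).all() and (up <= hi + 1e-12).all()

    def test_matches_monte_carlo(self, e2_levels):
        params = BCIParams(0.7, 0.6, 150.0, 0.02)
        obs = v.BCIObserver(0.7, 0.6, 150.0, 0.02, 290.0)
        reps = 8000
        trials = make_trials(e2_levels, reps)
        sim = v.simulate_bci_responses(obs, trials, seed=11)
        emp = sim.groupby("asynchrony_ms")["response"].apply(lambda r: (r == "yes").mean())
        for s, rate in emp.items():
            p = v.predict_p_yes(s, params, "ownership", 290.0)
            se = np.sqrt(p * (1 - p) / reps)
            assert abs(rate - p) < 3 * se


class TestLogLikelihood:
    def test_pure_lapse_coinflip(self, e2_levels):
        trials = make_trials(e2_levels, 5)
        obs = v.BCIObserver(lapse=1.0)
        sim = v.simulate_bci_responses(obs, trials, seed=0)
        params = BCIParams(0.8, 0.6, 150.0, 1.0)
        assert v.log_likelihood(params, sim, 293.0) == pytest.approx(
            len(sim) * np.log(0.5)
        )

    def test_analytic_gradient_matches_numerical(self, e2_participant_trials):
        from scipy.optimize import approx_fprime
        model = BCIModel(e2_participant_trials, 293.0)
        bounds = np.array(model.bounds())
        rng = np.random.default_rng(12)
        for _ in range(10):
            theta = rng.uniform(bounds[:, 0] + 0.01, bounds[:, 1] - 0.01)
            ll, grad = model.loglike_and_grad(theta)
            assert ll == pytest.approx(model.loglike(theta), abs=1e-9)
            num = approx_fprime(theta, model.loglike, 1e-7)
            assert np.allclose(grad, num, rtol=1e-3, atol=1e-3 * (1 + np.abs(num)).max())

    def test_matches_naive_per_trial_sum(self, e2_participant_trials):
        params = BCIParams(0.75, 0.55, 130.0, 0.03)
        got = v.log_likelihood(params, e2_participant_trials, 293.0)
        total = 0.0
        for _, row in e2_participant_trials.iterrows():
            thr = v.decision_threshold(params.p_same(row["task"]), params.sigma, 293.0)
            p_in = (
                sstats.norm.cdf((thr.k - row["asynchrony_ms"]) / params.sigma)
                - sstats.norm.cdf((-thr.k - row["asynchrony_ms"]) / params.sigma)
                if thr.defined
                else 0.0
            )
            p = 0.5 * params.lapse + (1 - params.lapse) * p_in
            total += np.log(p if row["response"] == "yes" else 1 - p)
        assert got == pytest.approx(total, rel=1e-9)


class TestGoodnessOfFit:
    def test_pseudo_r2_endpoints(self):
        n = 120
        assert pseudo_r2(n * np.log(0.5), n) == pytest.approx(0.0)
        assert pseudo_r2(0.0, n) == pytest.approx(1.0)

    def test_pseudo_r2_direct_evaluation(self):
        n = 100
        logL0 = n * np.log(0.5)
        logL = 0.5 * logL0
        r2 = 1.0 - np.exp(-2.0 / n * (logL - logL0))
        r2_max = 1.0 - np.exp(2.0 / n * logL0)
        assert pseudo_r2(logL, n) == pytest.approx(r2 / r2_max)

    def test_aic_bic_arithmetic(self):
        assert v.aic(-100.0, 4) == 208.0
        assert bic(-100.0, 6, 210) == pytest.approx(6 * np.log(210) + 200.0)
        assert bic(-100.0, 6, 210, exact_printed_form=True) == pytest.approx(
            210 * np.log(6) + 200.0
        )
        assert v.aic(-50.0, 6) - v.aic(-50.0, 8) == pytest.approx(-4.0)


class TestFitting:
    def test_noiseless_inverse(self, e2_levels):
        """Fitting expected-count data recovers the generating parameters."""
        truth = BCIParams(0.8, 0.6, 150.0, 0.02)
        n_per = 20000
        rows = []
        for task in ("ownership", "simultaneity"):
            for s in e2_levels:
                p = v.predict_p_yes(s, truth, task, 293.0)
                n_yes = int(round(n_per * p))
                rows += [("P1", task, 0, 0, s, "none", "yes")] * n_yes
                rows += [("P1", task, 0, 0, s, "none", "no")] * (n_per - n_yes)
        trials = pd.DataFrame(
            rows, columns=["participant", "task", "block", "trial_index",
                           "asynchrony_ms", "condition", "response"],
        )
        res = v.fit_bci(trials, sigma_s=293.0, n_starts=30, seed=0)
        assert res.params["p_same_own"] == pytest.approx(0.8, abs=0.01)
        assert res.params["p_same_sim"] == pytest.approx(0.6, abs=0.01)
        assert res.params["sigma"] == pytest.approx(150.0, rel=0.01)
        assert res.params["lapse"] == pytest.approx(0.02, abs=0.01)
        # pseudo-R2 of a stochastic observer is well below 1 even at truth;
        # it must simply agree with its definition at the optimum
        assert res.r2 == pytest.approx(v.pseudo_r2(res.llf, res.n_trial))
        # the optimum beats local perturbations of each parameter
        model = BCIModel(trials, 293.0)
        theta = res.theta
        for i in range(4):
            for d in (-0.02, 0.02):
                pert = theta.copy()
                pert[i] = np.clip(pert[i] * (1 + d) + (d if pert[i] < 1 else 0),
                                  *model.bounds()[i])
                assert model.loglike(pert) <= res.llf + 1e-6

    def test_fit_result_bookkeeping(self, e2_participant_trials):
        res = v.fit_bci(e2_participant_trials, sigma_s=293.0, n_starts=20, seed=1)
        assert res.n_par == 4
        assert res.n_trial == 270
        assert res.aic == pytest.approx(2 * 4 - 2 * res.llf)
        assert 0.0 <= res.r2 <= 1.0
        assert "sigma" in res.summary()

    def test_sigma_variant_on_homogeneous_conditions(self):
        """Equal true sigmas across conditions come back mutually close."""
        obs = v.BCIObserver(sigma_s=290.0)
        tabs = []
        for ci, cond in enumerate(("low", "sham", "high")):
            for ti, task in enumerate(("ownership", "simultaneity")):
                t = v.enumerate_trials(
                    v.build_design("E3", task), n_blocks=8,
                    seed=100 * ci + ti, condition=cond,
                )
                tabs.append(v.simulate_bci_responses(obs, t, seed=len(tabs)))
        trials = pd.concat(tabs, ignore_index=True)
        res = v.fit_bci(trials, sigma_s=290.0, variant="sigma_varies",
                        n_starts=40, seed=0)
        sigmas = [res.params[f"sigma_{c}"] for c in ("low", "sham", "high")]
        assert max(sigmas) / min(sigmas) < 1.10
        assert res.n_par == 6

    def test_psame_variant_param_count(self):
        obs = v.BCIObserver(sigma_s=290.0)
        tabs = []
        for cond in ("low", "sham", "high"):
            for task in ("ownership", "simultaneity"):
                t = v.enumerate_trials(v.build_design("E3", task),
                                       seed=7, condition=cond)
                tabs.append(v.simulate_bci_responses(obs, t, seed=len(tabs)))
        res = v.fit_bci(pd.concat(tabs, ignore_index=True), sigma_s=290.0,
                        variant="psame_varies", n_starts=15, seed=0)
        assert res.n_par == 8
        assert {n for n in res.params} >= {
            "p_same_own_low", "p_same_sim_high", "sigma", "lapse"
        }


class _FakeFit:
    def __init__(self, aic, bic):
        self.aic, self.bic = aic, bic


class TestCompareModels:
    def test_degenerate_bootstrap(self):
        fits_a = [_FakeFit(10.0, 20.0)] * 12
        fits_b = [_FakeFit(14.0, 24.0)] * 12
        comp = compare_models(fits_a, fits_b, n_boot=200, seed=0)
        assert comp.sum_delta_aic == pytest.approx(-48.0)
        assert comp.ci_aic == (pytest.approx(-48.0), pytest.approx(-48.0))
        assert comp.resample_size == 12

    def test_single_bootstrap_draw(self):
        rng = np.random.default_rng(0)
        fits_a = [_FakeFit(float(a), float(a)) for a in rng.normal(0, 5, 10)]
        fits_b = [_FakeFit(float(a), float(a)) for a in rng.normal(0, 5, 10)]
        comp = compare_models(fits_a, fits_b, n_boot=1, resample_size=4, seed=3)
        assert comp.ci_aic[0] == pytest.approx(comp.ci_aic[1])

    def test_symmetric_deltas_cover_zero(self):
        rng = np.random.default_rng(1)
        cover = 0
        for rep in range(40):
            d = rng.normal(0.0, 3.0, 15)
            fits_a = [_FakeFit(x, x) for x in d]
            fits_b = [_FakeFit(0.0, 0.0)] * 15
            comp = compare_models(fits_a, fits_b, n_boot=400, seed=rep)
            cover += comp.ci_aic[0] <= 0.0 <= comp.ci_aic[1]
        assert cover >= 33  # ~95% nominal coverage, loose binomial band

    def test_unpaired_raises(self):
        with pytest.raises(ValueError):
            compare_models([_FakeFit(1, 1)], [])
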