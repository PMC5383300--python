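import math

import numpy as np
import pytest
from scipy import stats

import plaquefit as pf
from plaquefit.likelihood import _ParamTable, MechanisticResults


def make_grid(ages, S, h):
    return pf.SurvivalGrid(ages=np.asarray(ages, float),
                           S=np.asarray(S, float),
                           h=np.asarray(h, float))


def worker(**kwargs):
    defaults = dict(id="w0", birth_year=1930, age_in=20.0, age_out=60.0,
                    event=0)
    defaults.update(kwargs)
    return pf.WorkerRecord(**defaults)


class TestIndividualLoglik:
    def test_case_contribution_arithmetic(self):
        grid = make_grid([40.0, 60.0], [0.99, 0.90], [0.01, 0.01])
        rec = worker(age_in=40.0, age_out=60.0, event=1)
        expected = math.log(0.90 / 0.99 * 0.01)
        assert pf.individual_loglik(rec, grid) == pytest.approx(expected,
                                                                abs=1e-10)
        assert expected == pytest.approx(-4.70048, abs=1e-5)

    def test_censored_with_flat_survival_contributes_zero(self):
        grid = make_grid([0.0, 80.0], [1.0, 1.0], [0.0, 0.0])
        rec = worker(event=0)
        assert pf.individual_loglik(rec, grid) == 0.0

    def test_case_at_zero_hazard_is_minus_inf(self):
        grid = make_grid([0.0, 80.0], [1.0, 1.0], [0.0, 0.0])
        rec = worker(event=1)
        assert pf.individual_loglik(rec, grid) == -math.inf


class TestCohortDeviance:
    def test_empty_cohort(self):
        assert pf.cohort_deviance(pf.Cohort([]), lambda r: None) == 0.0

    def test_riskless_model_single_censored_worker(self):
        grid = make_grid([0.0, 80.0], [1.0, 1.0], [0.0, 0.0])
        cohort = pf.Cohort([worker()])
        assert pf.cohort_deviance(cohort, lambda r: grid) == 0.0

    def test_doubling_cohort_doubles_deviance(self, small_cohort):
        model = pf.MechanisticStrokeModel(small_cohort)
        params = {**model.params_table.fixed, "nu0N": 4.5, "gamma": 0.12,
                  "nu1": 1.3}
        d1 = model.deviance(params)
        doubled = pf.Cohort(list(small_cohort) + list(small_cohort))
        d2 = pf.MechanisticStrokeModel(doubled).deviance(params)
        assert d2 == pytest.approx(2 * d1, rel=1e-12)

    def test_reordering_invariance(self, small_cohort):
        params = {"nu0N": 4.5, "gamma": 0.12, "nu1": 1.3,
                  "alpha": 12.0, "nu2": 1e-7, "t_lag": 10.0}
        d1 = pf.MechanisticStrokeModel(small_cohort).deviance(params)
        shuffled = pf.Cohort(list(small_cohort)[::-1])
        d2 = pf.MechanisticStrokeModel(shuffled).deviance(params)
        assert d1 == pytest.approx(d2, abs=1e-8)

    def test_stratified_fast_path_matches_per_record_evaluation(
            self, small_cohort):
        """The cached/stratified deviance equals the naive per-record one."""
        model = pf.MechanisticStrokeModel(small_cohort)
        params = {"nu0N": 4.5, "gamma": 0.12, "nu1": 1.3,
                  "alpha": 12.0, "nu2": 1e-7, "t_lag": 10.0}
        fast = model.deviance(params)
        timeline = model._timeline(params, {}, None)
        grid = pf.stroke_hazard_survival(timeline, model.nodes)
        slow = pf.cohort_deviance(small_cohort, lambda r: grid)
        assert fast == pytest.approx(slow, abs=1e-8)


class TestLikelihoodRatioTest:
    @pytest.mark.parametrize("delta,df,p", [
        (0.0, 1, 1.0),
        (3.841458820694124, 1, 0.05),
        (5.991464547107979, 2, 0.05),
    ])
    def test_chi2_reference_points(self, delta, df, p):
        assert pf.lrt(100.0, 100.0 - delta, df) == pytest.approx(p, abs=1e-9)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            pf.lrt(100.0, 101.0, 1)


class _QuadraticModel:
    """Duck-typed stand-in with an analytically known deviance surface."""

    def __init__(self, free, fixed, fun):
        self.params_table = _ParamTable(free, fixed)
        self._fun = fun
        self.spec = pf.FitSpec(free=free, fixed=fixed)

    def deviance(self, params):
        return self._fun(params)


class TestProfileIntervals:
    def test_gaussian_case_recovers_wald_interval(self):
        """For deviance (theta - 2)^2 / sigma^2 the 95% profile interval is
        theta_hat +/- 1.96 sigma."""
        sigma = 0.5
        model = _QuadraticModel(
            {"theta": (-10.0, 10.0)}, {},
            lambda p: (p["theta"] - 2.0) ** 2 / sigma ** 2)
        res = MechanisticResults(model, {"theta": 2.0}, 0.0, True, 1, 0)
        lo, hi = res.profile_ci("theta")
        z = math.sqrt(stats.chi2.ppf(0.95, 1))
        assert lo == pytest.approx(2.0 - z * sigma, abs=1e-3)
        assert hi == pytest.approx(2.0 + z * sigma, abs=1e-3)

    def test_flat_deviance_is_boundary_censored(self):
        model = _QuadraticModel({"theta": (-1.0, 1.0)}, {}, lambda p: 0.0)
        res = MechanisticResults(model, {"theta": 0.0}, 0.0, True, 1, 0)
        assert res.profile_ci("theta") == (-1.0, 1.0)

    def test_exponential_rate_matches_deviance_scan(self):
        """Asymmetric one-parameter likelihood (exponential rate, 10 events):
        profile bounds agree with a brute-force scan of the deviance curve."""
        n, total = 10, 25.0

        def dev(p):
            lam = p["lam"]
            return -2.0 * (n * math.log(lam) - lam * total)

        model = _QuadraticModel({"lam": (1e-3, 5.0)}, {}, dev)
        lam_hat = n / total
        res = MechanisticResults(model, {"lam": lam_hat}, dev({"lam":
                                                               lam_hat}),
                                 True, 1, 0)
        lo, hi = res.profile_ci("lam")
        # oracle: dense scan for the crossing points
        grid = np.linspace(1e-3, 5.0, 400001)
        devs = -2.0 * (n * np.log(grid) - grid * total)
        target = res.minus2logl + stats.chi2.ppf(0.95, 1)
        inside = grid[devs <= target]
        assert lo == pytest.approx(inside[0], abs=1e-3)
        assert hi == pytest.approx(inside[-1], abs=1e-3)
        assert hi - lam_hat > lam_hat - lo  # right-skewed likelihood


class TestFitting:
    def test_all_fixed_is_pure_evaluation(self, small_cohort):
        spec = pf.FitSpec(free={}, fixed={"nu0N": 4.5, "gamma": 0.12,
                                          "nu1": 1.3, "alpha": 12.0,
                                          "nu2": 1e-7, "t_lag": 10.0},
                          reference_deviance=0.0)
        model = pf.MechanisticStrokeModel(small_cohort, spec)
        res = model.fit(seed=0)
        assert res.converged
        assert res.minus2logl == pytest.approx(
            model.deviance(spec.fixed), abs=1e-10)
        assert res.delta_dev == res.minus2logl

    def test_single_free_parameter_recovery(self, bestfit_truth):
        """Fitting only the uptake product on data generated at 4.5/year
        recovers it within the 95% profile interval."""
        design = pf.CohortDesign(n_workers=1500, truth=bestfit_truth, seed=9)
        cohort = pf.generate_cohort(design).cohort
        spec = pf.FitSpec(free={"nu0N": (1.0, 10.0)},
                          fixed={"gamma": 0.12, "nu1": 1.3, "alpha": 12.0,
                                 "nu2": 1e-7, "t_lag": 10.0})
        res = pf.MechanisticStrokeModel(cohort, spec).fit(n_starts=3, seed=1)
        lo, hi = res.profile_ci("nu0N")
        assert lo <= 4.5 <= hi
        assert res.params["nu0N"] == pytest.approx(4.5, rel=0.25)

    def test_infeasible_region_repels_fit(self, small_cohort):
        """Points with gamma + nu1 > alpha carry infinite deviance."""
        model = pf.MechanisticStrokeModel(small_cohort)
        bad = {"nu0N": 4.5, "gamma": 0.3, "nu1": 11.9, "alpha": 12.0,
               "nu2": 1e-7, "t_lag": 10.0}
        assert model.deviance(bad) == math.inf


class TestRiskFactorScan:
    def test_identical_categories_give_no_improvement(self, bestfit_truth):
        """If every worker shares one smoking category the scan finds no
        deviance gain anywhere."""
        prev = {"smoking": {"nonsmoker": 1.0, "smoker_or_ex": 0.0,
                            "unknown": 0.0},
                "blood_pressure": {"normal": 0.7, "hypertensive": 0.25,
                                   "unknown": 0.05},
                "graduation": {"none": 0.75, "higher": 0.2,
                               "unknown": 0.05}}
        design = pf.CohortDesign(n_workers=500, truth=bestfit_truth, seed=3,
                                 covariate_prevalences=prev)
        cohort = pf.generate_cohort(design).cohort
        table = pf.scan_risk_factor_targets(
            cohort, pf.FitSpec(), "smoking", candidates=("nu2", "gamma"),
            n_starts=1, seed=0)
        assert (table["error"] == "").all()
        assert np.all(table["delta_dev"].abs() < 0.6)

    def test_true_nu2_effect_ranks_well(self):
        """A genuine hypertension doubling of nu2 should rank nu2 among the
        best candidates."""
        mod = pf.CovariateModifier("nu2", "blood_pressure",
                                   {"normal": 1.0, "hypertensive": 2.0,
                                    "unknown": 1.0})
        truth = pf.MechanisticTruth(
            rates=pf.RateSet(nu0N=4.5, alpha=12.0, gamma=0.12, nu1=1.3,
                             nu2=1e-7, t_lag=10.0),
            modifiers=(mod,))
        design = pf.CohortDesign(n_workers=12000, truth=truth, seed=17)
        cohort = pf.generate_cohort(design).cohort
        table = pf.scan_risk_factor_targets(
            cohort, pf.FitSpec(), "blood_pressure",
            candidates=("nu0N", "nu2"), n_starts=3, seed=0)
        assert (table["error"] == "").all()
        by_target = table.set_index("target")["deviance"]
        # the late-acting true target must beat the early-acting one
        assert by_target["nu2"] < by_target["nu0N"]
        assert table["delta_dev"].min() < -4.0
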