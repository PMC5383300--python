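import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import plaquefit as pf
from plaquefit.cohortgen import design_from_manifest


class TestDeterminism:
    def test_same_seed_reproduces_cohort_exactly(self, bestfit_truth):
        design = pf.CohortDesign(n_workers=300, truth=bestfit_truth, seed=42)
        a = pf.generate_cohort(design).cohort
        b = pf.generate_cohort(design).cohort
        ca, da = a.to_dataframes()
        cb, db = b.to_dataframes()
        pd.testing.assert_frame_equal(ca, cb)
        pd.testing.assert_frame_equal(da, db)

    def test_different_seeds_differ(self, bestfit_truth):
        a = pf.generate_cohort(
            pf.CohortDesign(n_workers=300, truth=bestfit_truth,
                            seed=1)).cohort
        b = pf.generate_cohort(
            pf.CohortDesign(n_workers=300, truth=bestfit_truth,
                            seed=2)).cohort
        assert a.to_dataframes()[0].equals(b.to_dataframes()[0]) is False


class TestStructure:
    def test_zero_risk_truth_yields_no_cases(self):
        truth = pf.MechanisticTruth(rates=pf.RateSet(
            nu0N=3.0, alpha=12.0, gamma=0.2, nu1=1.0, nu2=0.0, t_lag=10.0))
        cohort = pf.generate_cohort(
            pf.CohortDesign(n_workers=400, truth=truth, seed=8)).cohort
        assert cohort.n_cases == 0
        assert cohort.person_years > 0

    def test_follow_up_starts_at_employment(self, bestfit_truth):
        cohort = pf.generate_cohort(
            pf.CohortDesign(n_workers=200, truth=bestfit_truth,
                            seed=3)).cohort
        for rec in cohort:
            hire_year = rec.birth_year + math.floor(rec.age_in)
            assert 1948 <= hire_year <= 1972
            if rec.dose_history:
                assert rec.dose_history[0][0] >= hire_year

    def test_dose_calibration_at_full_scale(self):
        """At the emulated cohort size the cumulative-dose distribution hits
        a 0.28 Gy median with a 5-10% tail above 2 Gy."""
        truth = pf.MechanisticTruth(rates=pf.RateSet(
            nu0N=3.0, alpha=12.0, gamma=0.2, nu1=1.0, nu2=0.0, t_lag=10.0))
        cohort = pf.generate_cohort(
            pf.CohortDesign(n_workers=14056, truth=truth, seed=77)).cohort
        totals = np.array([sum(d for _, d in r.dose_history)
                           for r in cohort])
        assert 0.2 <= np.median(totals) <= 0.4
        assert 0.05 <= (totals > 2.0).mean() <= 0.10

    def test_event_fraction_monotone_in_nu2(self):
        fractions = []
        for mult in (0.5, 1.0, 2.0):
            truth = pf.MechanisticTruth(rates=pf.RateSet(
                nu0N=4.5, alpha=12.0, gamma=0.12, nu1=1.3,
                nu2=mult * 1e-7, t_lag=10.0))
            cohort = pf.generate_cohort(
                pf.CohortDesign(n_workers=2500, truth=truth, seed=55)).cohort
            fractions.append(cohort.n_cases / len(cohort))
        assert fractions[0] < fractions[1] < fractions[2]

    def test_bookkeeping_matches_likelihood_side(self, small_cohort):
        py = sum(r.age_out - r.age_in for r in small_cohort)
        cases = sum(r.event for r in small_cohort)
        assert small_cohort.person_years == pytest.approx(py)
        assert small_cohort.n_cases == cases


class TestStrokeAgeSampling:
    def test_unit_survival_never_strokes(self, rng):
        grid = pf.SurvivalGrid(ages=np.arange(0.0, 101.0),
                               S=np.ones(101), h=np.zeros(101))
        for _ in range(50):
            assert pf.stroke_age_from_survival(grid, rng) is None

    def test_exponential_mean(self, rng):
        """S(a) = exp(-0.01 a) on a long grid: draws average 100 years."""
        ages = np.arange(0.0, 2001.0)
        grid = pf.SurvivalGrid(ages=ages, S=np.exp(-0.01 * ages),
                               h=np.full_like(ages, 0.01))
        draws = np.array([pf.stroke_age_from_survival(grid, rng)
                          for _ in range(20000)], dtype=float)
        assert np.isnan(draws).mean() < 1e-3
        se = 100.0 / math.sqrt(20000)
        assert abs(np.nanmean(draws) - 100.0) < 3.5 * se

    def test_left_truncation_conditions_on_entry(self, rng):
        ages = np.arange(0.0, 301.0)
        grid = pf.SurvivalGrid(ages=ages, S=np.exp(-0.02 * ages),
                               h=np.full_like(ages, 0.02))
        draws = [pf.stroke_age_from_survival(grid, rng, age_in=50.0)
                 for _ in range(4000)]
        draws = np.array([d for d in draws if d is not None])
        assert np.all(draws >= 50.0)
        # memorylessness: residual mean is 1/0.02 = 50
        assert abs((draws - 50.0).mean() - 50.0) < 3.5 * 50 / math.sqrt(
            len(draws))

    def test_matches_monte_carlo_stroke_ages(self, fig2_rates):
        """Inverse-CDF sampling from the analytic survival and direct
        simulation of the cell process draw from the same distribution."""
        rates = fig2_rates.with_(nu2=1e-5)
        cfg = pf.SimulationConfig(steps_per_year=365, n_replicates=1500,
                                  max_age=90, seed=13)
        mc = pf.simulate_stroke_ages(rates, cfg)
        mc = mc[~np.isnan(mc)]
        tl = pf.ParameterTimeline.constant(rates, 90.0)
        grid = pf.stroke_hazard_survival(tl, np.arange(0.0, 91.0))
        rng = np.random.default_rng(99)
        inv = [pf.stroke_age_from_survival(grid, rng) for _ in range(1500)]
        inv = np.array([a for a in inv if a is not None and a <= 90.0])
        _, p = stats.ks_2samp(mc, inv)
        assert p > 0.05


class TestManifest:
    def test_round_trip(self, tmp_path, bestfit_truth):
        design = pf.CohortDesign(n_workers=120, truth=bestfit_truth, seed=6)
        gen = pf.generate_cohort(design)
        path = tmp_path / "truth.yaml"
        pf.save_manifest(gen.truth_manifest, path)
        loaded = pf.load_manifest(path)
        assert loaded == gen.truth_manifest

    def test_manifest_without_seed_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("schema: plaquefit-cohort-design/1\nn_workers: 5\n")
        with pytest.raises(ValueError):
            pf.load_manifest(path)

    def test_manifest_drives_recovery_run(self, tmp_path, bestfit_truth):
        """Save a design manifest, rebuild the design, regenerate the cohort
        and evaluate the likelihood at the recorded truth."""
        design = pf.CohortDesign(n_workers=400, truth=bestfit_truth, seed=31)
        gen = pf.generate_cohort(design)
        path = tmp_path / "truth.yaml"
        pf.save_manifest(gen.truth_manifest, path)
        rebuilt = design_from_manifest(pf.load_manifest(path))
        regen = pf.generate_cohort(rebuilt)
        a, _ = gen.cohort.to_dataframes()
        b, _ = regen.cohort.to_dataframes()
        pd.testing.assert_frame_equal(a, b)
        truth = rebuilt.truth.rates
        model = pf.MechanisticStrokeModel(regen.cohort)
        dev = model.deviance({"nu0N": truth.nu0N, "gamma": truth.gamma,
                              "nu1": truth.nu1, "alpha": truth.alpha,
                              "nu2": truth.nu2, "t_lag": truth.t_lag})
        assert math.isfinite(dev)
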