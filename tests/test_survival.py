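import math

import numpy as np
import pytest

import plaquefit as pf
from plaquefit.survival import SolverOptions, solve_cached


def closed_form_u(tau, nu1, nu2):
    """Two-stage exponential race: macrophage -> foam cell -> plaque,
    valid when alpha = beta = 0."""
    return (math.exp(-nu1 * tau)
            + nu1 * (math.exp(-nu2 * tau) - math.exp(-nu1 * tau))
            / (nu1 - nu2))


def constant_timeline(**kwargs):
    defaults = dict(nu0N=3.0, alpha=12.0, gamma=0.2, nu1=1.0, nu2=1e-5,
                    t_lag=10.0)
    defaults.update(kwargs)
    return pf.ParameterTimeline.constant(pf.RateSet(**defaults), 100.0)


class TestFoamCellSafeProb:
    def test_zero_window_and_zero_rate(self, fig2_rates):
        tl = pf.ParameterTimeline.constant(fig2_rates, 80.0)
        assert pf.foam_cell_safe_prob(tl, 30.0, 30.0) == 1.0
        tl0 = constant_timeline(nu2=0.0)
        assert pf.foam_cell_safe_prob(tl0, 10.0, 70.0) == 1.0

    def test_constant_rate_closed_form(self, fig2_rates):
        tl = pf.ParameterTimeline.constant(fig2_rates, 80.0)
        assert pf.foam_cell_safe_prob(tl, 40.0, 50.0) == pytest.approx(
            math.exp(-1e-6), rel=1e-12)

    def test_multiplicative_over_adjacent_windows(self, fig2_rates):
        tl = pf.ParameterTimeline.constant(fig2_rates.with_(nu2=1e-3), 80.0)
        ab = pf.foam_cell_safe_prob(tl, 10.0, 30.0)
        bc = pf.foam_cell_safe_prob(tl, 30.0, 72.5)
        ac = pf.foam_cell_safe_prob(tl, 10.0, 72.5)
        assert ac == pytest.approx(ab * bc, rel=1e-12)


class TestMacrophageSafeProb:
    def test_zero_plaque_rate_fixed_point(self):
        tl = constant_timeline(nu2=0.0)
        for tau in (1.0, 10.0, 40.0):
            assert pf.macrophage_safe_prob(tl, 50.0 - tau, 50.0) == \
                pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("nu1,nu2", [(1.0, 1e-3), (0.5, 1e-2),
                                         (2.0, 1e-4)])
    def test_two_exponential_closed_form(self, nu1, nu2):
        """alpha=beta=0 reduces the backward Riccati equation to a linear
        two-stage race with an analytic solution."""
        rs = pf.RateSet(nu0N=3.0, alpha=0.0, gamma=-nu1, nu1=nu1, nu2=nu2,
                        t_lag=10.0)
        tl = pf.ParameterTimeline.constant(rs, 60.0)
        for tau in np.linspace(0.5, 50.0, 12):
            u = pf.macrophage_safe_prob(tl, 50.0 - tau + 10.0 - 10.0, 50.0)
            # evaluate at s = 50 - tau
            u = pf.macrophage_safe_prob(tl, 50.0 - tau, 50.0)
            assert u == pytest.approx(closed_form_u(tau, nu1, nu2),
                                      abs=1e-6)

    def test_probability_bounds_across_parameter_box(self):
        for gamma, nu1, nu2 in [(0.1, 0.1, 1e-7), (0.3, 8.0, 1e-3),
                                (0.2, 1.0, 1e-5), (0.1, 11.0, 1e-3)]:
            tl = constant_timeline(gamma=gamma, nu1=nu1, nu2=nu2)
            for s, t in [(0.0, 30.0), (20.0, 90.0), (59.5, 60.0)]:
                u = pf.macrophage_safe_prob(tl, s, t)
                assert 0.0 < u <= 1.0

    def test_monte_carlo_agreement_single_macrophage(self):
        """Seed one macrophage, count descendants' plaques by tau=20."""
        rs = pf.RateSet(nu0N=0.0, alpha=2.0, gamma=0.1, nu1=0.5, nu2=1e-3,
                        t_lag=0.0)
        tl = pf.ParameterTimeline.constant(rs, 30.0)
        u = pf.macrophage_safe_prob(tl, 0.0, 20.0)
        rng = np.random.default_rng(8)
        n = 1500
        safe = 0
        for _ in range(n):
            state = pf.CellState(age=0.0, M=1, F=0, R=0)
            for _ in range(20 * 100):
                state = pf.step(state, rs, 1 / 100, rng)
                if state.R > 0:
                    break
                if state.M == 0 and state.F == 0:
                    break
            # finish the clock for survivors with foam cells pending
            while state.age < 20.0 and state.R == 0 and \
                    (state.M > 0 or state.F > 0):
                state = pf.step(state, rs, 1 / 100, rng)
            safe += state.R == 0
        se = math.sqrt(u * (1 - u) / n)
        assert abs(safe / n - u) < 3 * se


class TestStrokeSurvival:
    def test_no_hazard_before_lag(self, fig2_rates):
        tl = pf.ParameterTimeline.constant(fig2_rates.with_(nu2=1e-4), 80.0)
        grid = pf.stroke_hazard_survival(tl, np.arange(0.0, 90.0))
        assert np.all(grid.S[:11] == 1.0)
        assert np.all(grid.h[:10] == 0.0)
        assert grid.h[60] > 0.0

    def test_zero_influx_or_zero_nu2_is_riskless(self):
        for kwargs in (dict(nu0N=0.0), dict(nu2=0.0)):
            tl = constant_timeline(**kwargs)
            grid = pf.stroke_hazard_survival(tl, np.arange(0.0, 100.0))
            assert np.allclose(grid.S, 1.0)

    def test_survival_hazard_identity(self):
        """exp(-int h) reproduces S to < 1e-4 relative on a 0.25 y grid."""
        tl = constant_timeline(nu2=1e-5)
        ages = np.arange(0.0, 100.25, 0.25)
        grid = pf.stroke_hazard_survival(tl, ages)
        H = np.concatenate(
            [[0.0], np.cumsum(0.25 * 0.5 * (grid.h[1:] + grid.h[:-1]))])
        assert np.max(np.abs(np.exp(-H) - grid.S) / grid.S) < 1e-4

    def test_hazard_rises_steeply_with_age(self, bestfit_rates):
        tl = pf.ParameterTimeline.constant(bestfit_rates, 90.0)
        grid = pf.stroke_hazard_survival(tl, np.arange(40.0, 81.0))
        assert np.all(np.diff(grid.h) > 0)
        assert grid.h[-1] / grid.h[0] > 10

    def test_general_path_matches_homogeneous_fast_path(self):
        tl = constant_timeline()
        rates = list(tl.rates)
        rates[0] = rates[0].with_(nu0N=rates[0].nu0N + 1e-13)
        tl_general = pf.ParameterTimeline(rates=tuple(rates))
        ages = np.arange(0.0, 100.0)
        fast = pf.stroke_hazard_survival(tl, ages)
        slow = pf.stroke_hazard_survival(tl_general, ages)
        assert np.max(np.abs(fast.S - slow.S)) < 1e-7
        pos = fast.h > 1e-12
        assert np.max(np.abs(fast.h[pos] - slow.h[pos]) / fast.h[pos]) < 0.01

    def test_finite_difference_matches_exact_derivative(self):
        tl = constant_timeline()
        rates = list(tl.rates)
        rates[0] = rates[0].with_(nu0N=rates[0].nu0N + 1e-13)
        tl_general = pf.ParameterTimeline(rates=tuple(rates))
        ages = np.arange(12.0, 100.0)
        fd = pf.stroke_hazard_survival(tl_general, ages,
                                       SolverOptions(hazard_method="fd"))
        exact = pf.stroke_hazard_survival(
            tl_general, ages, SolverOptions(hazard_method="exact"))
        assert np.max(np.abs(fd.h - exact.h) / exact.h) < 0.01

    def test_inhomogeneous_timeline_tracks_age_law(self):
        """An age law on nu0N must change S relative to the constant case."""
        law = pf.AgePowerLaw("nu0N", psi=1.0, a0=10.0)
        base = pf.RateSet(nu0N=2.4, alpha=12.0, gamma=0.12, nu1=1.3,
                          nu2=1e-5, t_lag=10.0)

        def evaluator(age):
            return pf.evaluate_rates(base, laws=[law],
                                     context=pf.ParameterContext(age=age))

        tl = pf.ParameterTimeline.from_evaluator(evaluator, 90.0)
        const = pf.ParameterTimeline.constant(base, 90.0)
        ages = np.arange(0.0, 100.0)
        g_law = pf.stroke_hazard_survival(tl, ages)
        g_const = pf.stroke_hazard_survival(const, ages)
        # uptake grows with age under psi=1, so risk accumulates faster
        assert g_law.S[80] < g_const.S[80]


class TestRelativeRisk:
    def test_identical_timelines_give_unity(self, fig2_rates):
        tl = pf.ParameterTimeline.constant(fig2_rates.with_(nu2=1e-5), 90.0)
        ages = np.arange(15.0, 90.0)
        rr = pf.relative_risk(tl, tl, ages)
        assert np.allclose(rr, 1.0)

    def test_nu2_multiplier_declines_from_k(self, bestfit_rates):
        """Doubling nu2 doubles the hazard just above the lag, then the
        ratio falls with age as high-burden individuals are selected out."""
        base = bestfit_rates
        tl_b = pf.ParameterTimeline.constant(base, 90.0)
        tl_a = pf.ParameterTimeline.constant(
            base.with_(nu2=2 * base.nu2), 90.0)
        ages = np.arange(11.0, 90.0)
        rr = pf.relative_risk(tl_a, tl_b, ages)
        assert rr[0] == pytest.approx(2.0, rel=0.02)
        assert np.all(np.diff(rr) < 0.0)

    def test_zero_reference_hazard_is_an_error(self, fig2_rates):
        tl = pf.ParameterTimeline.constant(fig2_rates.with_(nu2=1e-5), 90.0)
        with pytest.raises(ZeroDivisionError):
            pf.relative_risk(tl, tl, np.arange(0.0, 30.0))


class TestGridCache:
    def test_cached_solution_identical(self, fig2_rates):
        tl = pf.ParameterTimeline.constant(fig2_rates.with_(nu2=1e-5), 90.0)
        ages = np.arange(0.0, 100.0)
        a = solve_cached(tl, ages)
        b = solve_cached(tl, ages)
        assert a is b
        direct = pf.stroke_hazard_survival(tl, ages)
        assert np.array_equal(a.S, direct.S)
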