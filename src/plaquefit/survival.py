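"""Stroke-free survival and hazard implied by the stochastic lesion model.

Because monocytes, macrophages and foam cells evolve independently of each
other, the infinite master equation of the (M, F, R) process collapses to
low-dimensional backward equations:

* ``v(s, t) = exp(-int_s^t nu2(x) dx)`` is the probability that a single foam
  cell present at age s has produced no vulnerable plaque by age t;
* ``u(s, t)``, the probability that a single macrophage present at age s has
  no plaque among its descendants by age t, solves the backward Riccati ODE

      du/ds = (alpha+beta+nu1) u - alpha u^2 - beta - nu1 v(s,t),
      u(t, t) = 1;

* Poisson immigration of monocytes at rate ``nu0N(s)`` then gives the
  probability of no plaque at all by age t:

      S_R(t) = exp(-int_0^t nu0N(s) (1 - u(s,t)) ds).

A stroke occurs exactly ``t_lag`` years after the first plaque, so the
stroke-free survival is S(a) = S_R(a - t_lag) and the stroke hazard is the
first-plaque hazard evaluated at a - t_lag.

Rates are piecewise constant on annual age intervals (the resolution of the
cohort's dose records); within intervals a fixed-step RK4 integrator is used,
with the per-foam-cell probability v carried analytically.  For an
age-constant timeline u depends on s and t only through t - s, which allows
a single forward sweep and the exact hazard identity
h_R(t) = nu0N * (1 - u(t)); this fast path is detected automatically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
from numba import njit

from .params import RateSet

__all__ = [
    "ParameterTimeline", "SurvivalGrid", "SolverOptions",
    "foam_cell_safe_prob", "macrophage_safe_prob", "survival_no_plaque",
    "stroke_hazard_survival", "relative_risk",
]


class SolverError(RuntimeError):
    """The backward integration produced an invalid probability."""


@dataclass(frozen=True)
class ParameterTimeline:
    """Piecewise-constant-in-age realized rates for one covariate/dose profile.

    ``rates[k]`` applies on the annual age interval [k, k+1); the timeline
    covers [0, len(rates)] years.  All intervals must share ``t_lag``.
    """

    rates: Tuple[RateSet, ...]

    def __post_init__(self) -> None:
        if not self.rates:
            raise ValueError("timeline needs at least one interval")
        lags = {r.t_lag for r in self.rates}
        if len(lags) != 1:
            raise ValueError("t_lag must be constant along a timeline")

    @classmethod
    def constant(cls, rates: RateSet, max_age: float) -> "ParameterTimeline":
        return cls(rates=(rates,) * int(math.ceil(max_age)))

    @classmethod
    def from_evaluator(cls, evaluator: Callable[[float], RateSet],
                       max_age: float) -> "ParameterTimeline":
        """Sample an age -> RateSet callable at annual interval midpoints."""
        n = int(math.ceil(max_age))
        return cls(rates=tuple(evaluator(k + 0.5) for k in range(n)))

    @property
    def t_lag(self) -> float:
        return self.rates[0].t_lag

    @property
    def max_age(self) -> float:
        return float(len(self.rates))

    @property
    def is_homogeneous(self) -> bool:
        return all(r == self.rates[0] for r in self.rates)

    def rate_arrays(self) -> Tuple[np.ndarray, ...]:
        return tuple(
            np.array([getattr(r, name) for r in self.rates], dtype=np.float64)
            for name in ("nu0N", "alpha", "gamma", "nu1", "nu2"))


@dataclass(frozen=True)
class SolverOptions:
    """Numerical controls of the backward integration.

    ``ds`` is the RK4 step in years; ``fd_step`` the half-width (years) of the
    central difference used for the hazard on inhomogeneous timelines.  The
    exact augmented-ODE derivative is available via ``hazard_method="exact"``
    and is the only method used on the homogeneous fast path, where it is free.
    """

    ds: float = 0.02
    fd_step: float = 0.05
    hazard_method: str = "fd"  # "fd" | "exact" (general path only)


DEFAULT_OPTIONS = SolverOptions()


# ----------------------------------------------------------------------
# numba kernels
# ----------------------------------------------------------------------

@njit(cache=True)
def _rk4_u(u, v0, dvfac, h, a, b, n1):
    """One backward RK4 step for u over a distance h (away from the horizon).

    v at offset theta below the current point is v0 * exp(-dvfac*theta) with
    dvfac = -nu2 ... stored so that v(theta) = v0 * math.exp(dvfac * theta).
    """
    s = a + b + n1
    v1 = v0
    k1 = -(s * u - a * u * u - b - n1 * v1)
    vh = v0 * math.exp(dvfac * 0.5 * h)
    u2 = u + 0.5 * h * k1
    k2 = -(s * u2 - a * u2 * u2 - b - n1 * vh)
    u3 = u + 0.5 * h * k2
    k3 = -(s * u3 - a * u3 * u3 - b - n1 * vh)
    vf = v0 * math.exp(dvfac * h)
    u4 = u + h * k3
    k4 = -(s * u4 - a * u4 * u4 - b - n1 * vf)
    return u + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4), vf


@njit(cache=True)
def _backward_sweep(t, s_stop, nu0N_y, alpha_y, beta_y, nu1_y, nu2_y,
                    ds, nu2_at_t, want_h):
    """Integrate u (and optionally its horizon-derivative) from s=t to s_stop.

    Returns (u(s_stop, t), I, Ih) with
    I  = int_{s_stop}^t nu0N(s) (1 - u(s,t)) ds  and
    Ih = int_{s_stop}^t nu0N(s) (-du/dt)(s,t) ds  (zero unless want_h).
    """
    u = 1.0
    ut = 0.0
    v = 1.0
    I = 0.0
    Ih = 0.0
    n = nu0N_y.shape[0]
    k_top = min(int(math.ceil(t)) - 1, n - 1)
    if t <= 0.0:
        return 1.0, 0.0, 0.0
    for k in range(k_top, -1, -1):
        seg_hi = min(t, float(k + 1))
        seg_lo = max(s_stop, float(k))
        if seg_hi <= seg_lo:
            if float(k + 1) <= s_stop:
                break
            continue
        width = seg_hi - seg_lo
        m = int(math.ceil(width / ds))
        h = width / m
        a = alpha_y[k]
        b = beta_y[k]
        n1 = nu1_y[k]
        n2 = nu2_y[k]
        n0 = nu0N_y[k]
        dvfac = -n2
        for _ in range(m):
            f_old = 1.0 - u
            g_old = -ut
            if want_h:
                # coupled RK4 for (u, ut); v analytic within the interval
                s_ = a + b + n1
                v1 = v
                k1u = -(s_ * u - a * u * u - b - n1 * v1)
                k1t = -((s_ - 2.0 * a * u) * ut + n1 * nu2_at_t * v1)
                vh = v * math.exp(dvfac * 0.5 * h)
                u2 = u + 0.5 * h * k1u
                t2 = ut + 0.5 * h * k1t
                k2u = -(s_ * u2 - a * u2 * u2 - b - n1 * vh)
                k2t = -((s_ - 2.0 * a * u2) * t2 + n1 * nu2_at_t * vh)
                u3 = u + 0.5 * h * k2u
                t3 = ut + 0.5 * h * k2t
                k3u = -(s_ * u3 - a * u3 * u3 - b - n1 * vh)
                k3t = -((s_ - 2.0 * a * u3) * t3 + n1 * nu2_at_t * vh)
                vf = v * math.exp(dvfac * h)
                u4 = u + h * k3u
                t4 = ut + h * k3t
                k4u = -(s_ * u4 - a * u4 * u4 - b - n1 * vf)
                k4t = -((s_ - 2.0 * a * u4) * t4 + n1 * nu2_at_t * vf)
                u = u + (h / 6.0) * (k1u + 2.0 * k2u + 2.0 * k3u + k4u)
                ut = ut + (h / 6.0) * (k1t + 2.0 * k2t + 2.0 * k3t + k4t)
                v = vf
            else:
                u, v = _rk4_u(u, v, dvfac, h, a, b, n1)
            I += n0 * h * 0.5 * (f_old + (1.0 - u))
            if want_h:
                Ih += n0 * h * 0.5 * (g_old + (-ut))
        if float(k) <= s_stop:
            break
    return u, I, Ih


@njit(cache=True)
def _homogeneous_sweep(tau_out, nu0N, alpha, beta, nu1, nu2, ds):
    """Forward sweep in tau = t - s for an age-constant rate set.

    Returns (u(tau), J(tau)) at the sorted output points, where
    J(tau) = int_0^tau (1 - u) dx, so that S_R(t) = exp(-nu0N * J(t)) and
    h_R(t) = nu0N * (1 - u(t)) exactly.
    """
    nout = tau_out.shape[0]
    u_arr = np.empty(nout)
    j_arr = np.empty(nout)
    u = 1.0
    J = 0.0
    tau = 0.0
    for i in range(nout):
        width = tau_out[i] - tau
        if width < 0:
            raise ValueError("tau_out must be ascending")
        if width > 0.0:
            m = int(math.ceil(width / ds))
            h = width / m
            for _ in range(m):
                f_old = 1.0 - u
                v0 = math.exp(-nu2 * tau)
                u, _ = _rk4_u(u, v0, -nu2, h, alpha, beta, nu1)
                tau += h
                J += h * 0.5 * (f_old + (1.0 - u))
        u_arr[i] = u
        j_arr[i] = J
    return u_arr, j_arr


# ----------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------

def foam_cell_safe_prob(timeline: ParameterTimeline, s: float, t: float) -> float:
    """P(a foam cell present at age s seeds no plaque by age t) = exp(-int nu2)."""
    if s > t:
        raise ValueError("need s <= t")
    nu2 = timeline.rate_arrays()[4]
    integral = _piecewise_integral(nu2, s, t)
    return math.exp(-integral)


def _piecewise_integral(values_per_year: np.ndarray, lo: float, hi: float) -> float:
    total = 0.0
    n = len(values_per_year)
    for k in range(int(math.floor(lo)), int(math.ceil(hi))):
        seg = min(hi, k + 1.0) - max(lo, float(k))
        if seg > 0:
            total += values_per_year[min(k, n - 1)] * seg
    return total


def macrophage_safe_prob(timeline: ParameterTimeline, s: float, t: float,
                         options: SolverOptions = DEFAULT_OPTIONS) -> float:
    """P(one macrophage at age s yields no plaque among descendants by t)."""
    if s > t or s < 0:
        raise ValueError("need 0 <= s <= t")
    if t > timeline.max_age:
        raise ValueError("t exceeds timeline coverage")
    nu0N, alpha, gamma, nu1, nu2 = timeline.rate_arrays()
    beta = alpha - gamma - nu1
    u, _, _ = _backward_sweep(t, s, nu0N, alpha, beta, nu1, nu2,
                              options.ds, _nu2_at(nu2, t), False)
    if not (0.0 < u <= 1.0 + 1e-9):
        raise SolverError(f"u(s={s}, t={t}) = {u} outside (0, 1]")
    return min(u, 1.0)


def _nu2_at(nu2: np.ndarray, t: float) -> float:
    k = min(max(int(math.ceil(t)) - 1, 0), len(nu2) - 1)
    return float(nu2[k])


def survival_no_plaque(timeline: ParameterTimeline, t: float,
                       options: SolverOptions = DEFAULT_OPTIONS) -> float:
    """S_R(t): probability that no vulnerable plaque exists at age t."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if t > timeline.max_age:
        raise ValueError("t exceeds timeline coverage")
    if t == 0.0:
        return 1.0
    nu0N, alpha, gamma, nu1, nu2 = timeline.rate_arrays()
    beta = alpha - gamma - nu1
    _, I, _ = _backward_sweep(t, 0.0, nu0N, alpha, beta, nu1, nu2,
                              options.ds, _nu2_at(nu2, t), False)
    return math.exp(-I)


@dataclass(frozen=True)
class SurvivalGrid:
    """Ages with stroke-free survival S(a) and stroke hazard h(a) (per year).

    S is interpolated log-linearly between grid points (piecewise-exponential
    survival); h linearly.
    """

    ages: np.ndarray
    S: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        if np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        if np.any(self.S <= 0) or np.any(self.S > 1.0 + 1e-12):
            raise SolverError("S outside (0, 1]")
        if np.any(np.diff(self.S) > 1e-12):
            raise SolverError("S must be non-increasing")
        if np.any(self.h < -1e-12):
            raise SolverError("negative hazard")

    def log_S(self, age) -> np.ndarray:
        """log S at arbitrary ages, linear interpolation of ln S."""
        return np.interp(np.asarray(age, dtype=float), self.ages,
                         np.log(self.S))

    def hazard(self, age) -> np.ndarray:
        return np.interp(np.asarray(age, dtype=float), self.ages, self.h)


def stroke_hazard_survival(timeline: ParameterTimeline,
                           ages: Optional[Sequence[float]] = None,
                           options: SolverOptions = DEFAULT_OPTIONS) -> SurvivalGrid:
    """Stroke-free survival and stroke hazard on an age grid.

    S(a) = S_R(max(a - t_lag, 0)); h(a) is the first-plaque hazard at
    a - t_lag (zero for a <= t_lag).  On the homogeneous fast path the hazard
    uses the exact identity h_R = nu0N (1 - u); otherwise central finite
    differences of -ln S_R (or the augmented-ODE exact derivative when
    ``options.hazard_method == "exact"``).
    """
    t_lag = timeline.t_lag
    if ages is None:
        ages = np.arange(0.0, math.floor(timeline.max_age + t_lag) + 1.0)
    ages = np.asarray(ages, dtype=float)
    if np.any(ages < 0):
        raise ValueError("ages must be >= 0")
    if ages.max() - t_lag > timeline.max_age + 1e-9:
        raise ValueError("age grid exceeds timeline coverage (+ t_lag)")

    taus = np.maximum(ages - t_lag, 0.0)
    nu0N, alpha, gamma, nu1, nu2 = timeline.rate_arrays()
    beta = alpha - gamma - nu1

    S = np.empty_like(taus)
    h = np.empty_like(taus)
    if timeline.is_homogeneous:
        order = np.argsort(taus)
        tau_sorted = taus[order]
        u_arr, j_arr = _homogeneous_sweep(
            tau_sorted, nu0N[0], alpha[0], beta[0], nu1[0], nu2[0], options.ds)
        S[order] = np.exp(-nu0N[0] * j_arr)
        h[order] = nu0N[0] * (1.0 - u_arr)
    else:
        for i, t in enumerate(taus):
            if t == 0.0:
                S[i] = 1.0
                h[i] = 0.0
                continue
            want_exact = options.hazard_method == "exact"
            _, I, Ih = _backward_sweep(
                t, 0.0, nu0N, alpha, beta, nu1, nu2, options.ds,
                _nu2_at(nu2, t), want_exact)
            S[i] = math.exp(-I)
            if want_exact:
                h[i] = Ih
            else:
                d = options.fd_step
                lo = max(t - d, 0.0)
                hi = min(t + d, timeline.max_age)
                _, Ilo, _ = _backward_sweep(
                    lo, 0.0, nu0N, alpha, beta, nu1, nu2, options.ds,
                    _nu2_at(nu2, lo), False)
                _, Ihi, _ = _backward_sweep(
                    hi, 0.0, nu0N, alpha, beta, nu1, nu2, options.ds,
                    _nu2_at(nu2, hi), False)
                h[i] = (Ihi - Ilo) / (hi - lo)
    h = np.maximum(h, 0.0)
    return SurvivalGrid(ages=ages, S=np.minimum(S, 1.0), h=h)


def relative_risk(timeline_a: ParameterTimeline, timeline_b: ParameterTimeline,
                  ages: Sequence[float],
                  options: SolverOptions = DEFAULT_OPTIONS) -> np.ndarray:
    """Hazard ratio h_a / h_b on the given age grid.

    Both timelines must share the lag; ages at which the reference hazard
    vanishes (a <= t_lag) are rejected.
    """
    if timeline_a.t_lag != timeline_b.t_lag:
        raise ValueError("timelines must share t_lag")
    ages = np.asarray(ages, dtype=float)
    ga = stroke_hazard_survival(timeline_a, ages, options)
    gb = stroke_hazard_survival(timeline_b, ages, options)
    if np.any(gb.h <= 0):
        raise ZeroDivisionError(
            "reference hazard is zero on part of the grid "
            "(restrict ages to > t_lag)")
    return ga.h / gb.h


# Strata sharing a timeline are common in cohort fitting; cache solved grids.
@lru_cache(maxsize=512)
def _cached_grid(timeline: ParameterTimeline, ages_key: Tuple[float, ...],
                 options: SolverOptions) -> SurvivalGrid:
    return stroke_hazard_survival(timeline, np.array(ages_key), options)


def solve_cached(timeline: ParameterTimeline, ages: Sequence[float],
                 options: SolverOptions = DEFAULT_OPTIONS) -> SurvivalGrid:
    return _cached_grid(timeline, tuple(float(a) for a in ages), options)
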