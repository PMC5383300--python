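"""Exact Monte-Carlo simulation of the (M, F, R) lesion process.

Each simulated year is split into ``steps_per_year`` sub-steps (365 by
default).  Within a step the five transitions — monocyte influx, macrophage
proliferation and death, foam-cell formation and plaque seeding — are drawn
as independent Poisson counts with means rate*state*dt computed from the
state at the start of the step, then applied simultaneously.  This aggregate
draw is distributionally equivalent to per-cell events in the dt -> 0 limit
and costs O(1) per step.

M and F are floored at zero after applying decrements; flooring is rare at
the default resolution and is counted for diagnostics.  A plaque conversion
decrements F by one (the transition of a single foam cell) — numerically
negligible for realistic nu2 but kept so that conversions are conserved.

Rates are re-evaluated once per simulated year (piecewise constant in age),
matching the analytic solver's annual timeline.  Replicate i draws from a
dedicated stream seeded from (base_seed, i) so that runs are reproducible
independently of batching.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple, Union

import numpy as np
from numba import njit

from .params import RateSet
from .survival import ParameterTimeline

__all__ = ["CellState", "SimulationConfig", "PrevalenceCurve", "step",
           "simulate_individual", "lesion_prevalence", "simulate_stroke_ages",
           "LesionEnsemble"]

RateSource = Union[RateSet, ParameterTimeline, Callable[[float], RateSet]]


@dataclass(frozen=True)
class CellState:
    """Counts of macrophages (M), foam cells + debris (F) and plaques (R)."""

    age: float
    M: int
    F: int
    R: int

    def __post_init__(self) -> None:
        if min(self.M, self.F, self.R) < 0:
            raise ValueError("cell counts must be >= 0")


@dataclass(frozen=True)
class SimulationConfig:
    steps_per_year: int = 365
    n_replicates: int = 500
    max_age: float = 90.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps_per_year < 1 or self.n_replicates < 1:
            raise ValueError("steps_per_year and n_replicates must be >= 1")


@dataclass(frozen=True)
class PrevalenceCurve:
    """Fraction of replicates with at least X macrophages + foam cells."""

    ages: np.ndarray
    thresholds: np.ndarray
    fractions: np.ndarray  # shape (n_ages, n_thresholds)


def step(state: CellState, rates: RateSet, dt: float,
         rng: np.random.Generator) -> CellState:
    """One Poisson update of a single state (reference scalar implementation)."""
    if dt <= 0:
        raise ValueError("dt must be > 0")
    influx = rng.poisson(rates.nu0N * dt)
    births = rng.poisson(rates.alpha * state.M * dt)
    deaths = rng.poisson(rates.beta * state.M * dt)
    conversions = rng.poisson(rates.nu1 * state.M * dt)
    plaques = rng.poisson(rates.nu2 * state.F * dt)
    M = max(state.M + influx + births - deaths - conversions, 0)
    F = max(state.F + conversions - plaques, 0)
    return CellState(age=state.age + dt, M=M, F=F, R=state.R + plaques)


@njit(cache=True)
def _run_replicates(seeds, steps_per_year, n_years,
                    nu0N_y, alpha_y, beta_y, nu1_y, nu2_y):
    n_rep = seeds.shape[0]
    m_snap = np.zeros((n_rep, n_years + 1), np.int64)
    f_snap = np.zeros((n_rep, n_years + 1), np.int64)
    r_snap = np.zeros((n_rep, n_years + 1), np.int64)
    first_plaque = np.full(n_rep, np.nan)
    conv_total = np.zeros(n_rep, np.int64)
    plaque_total = np.zeros(n_rep, np.int64)
    floor_events = np.zeros(n_rep, np.int64)
    dt = 1.0 / steps_per_year
    for i in range(n_rep):
        np.random.seed(seeds[i])
        M = np.int64(0)
        F = np.int64(0)
        R = np.int64(0)
        for y in range(n_years):
            lam_in = nu0N_y[y] * dt
            a = alpha_y[y] * dt
            b = beta_y[y] * dt
            n1 = nu1_y[y] * dt
            n2 = nu2_y[y] * dt
            for s in range(steps_per_year):
                influx = np.random.poisson(lam_in)
                births = np.int64(0)
                deaths = np.int64(0)
                conversions = np.int64(0)
                plaques = np.int64(0)
                if M > 0:
                    births = np.random.poisson(a * M)
                    deaths = np.random.poisson(b * M)
                    conversions = np.random.poisson(n1 * M)
                if F > 0 and n2 > 0.0:
                    plaques = np.random.poisson(n2 * F)
                M_new = M + influx + births - deaths - conversions
                if M_new < 0:
                    M_new = np.int64(0)
                    floor_events[i] += 1
                F_new = F + conversions - plaques
                if F_new < 0:
                    F_new = np.int64(0)
                    floor_events[i] += 1
                if plaques > 0 and R == 0:
                    first_plaque[i] = y + (s + 1) * dt
                M = M_new
                F = F_new
                R = R + plaques
                conv_total[i] += conversions
                plaque_total[i] += plaques
            m_snap[i, y + 1] = M
            f_snap[i, y + 1] = F
            r_snap[i, y + 1] = R
    return (m_snap, f_snap, r_snap, first_plaque, conv_total, plaque_total,
            floor_events)


@dataclass(frozen=True)
class LesionEnsemble:
    """Annual snapshots of all replicates plus first-plaque ages."""

    ages: np.ndarray
    M: np.ndarray          # (n_rep, n_ages)
    F: np.ndarray
    R: np.ndarray
    first_plaque_age: np.ndarray  # nan where no plaque occurred
    conversions: np.ndarray
    plaques: np.ndarray
    floor_events: np.ndarray
    t_lag: float

    def stroke_ages(self, max_age: Optional[float] = None) -> np.ndarray:
        """First-plaque age + t_lag; nan if no plaque by max_age - t_lag."""
        horizon = (self.ages[-1] if max_age is None else max_age) - self.t_lag
        out = np.where(self.first_plaque_age <= horizon,
                       self.first_plaque_age + self.t_lag, np.nan)
        return out


def _as_timeline(rate_source: RateSource, max_age: float) -> ParameterTimeline:
    if isinstance(rate_source, ParameterTimeline):
        return rate_source
    if isinstance(rate_source, RateSet):
        return ParameterTimeline.constant(rate_source, max_age)
    return ParameterTimeline.from_evaluator(rate_source, max_age)


def _replicate_seeds(base_seed: int, n: int) -> np.ndarray:
    return np.array(
        [np.random.SeedSequence((base_seed, i)).generate_state(1)[0]
         for i in range(n)], dtype=np.int64)


def run_ensemble(rate_source: RateSource,
                 config: SimulationConfig) -> LesionEnsemble:
    """Simulate ``config.n_replicates`` lives from birth (M=F=R=0)."""
    timeline = _as_timeline(rate_source, config.max_age)
    n_years = int(math.ceil(config.max_age))
    if timeline.max_age < n_years:
        raise ValueError("timeline does not cover max_age")
    nu0N, alpha, gamma, nu1, nu2 = timeline.rate_arrays()
    beta = alpha - gamma - nu1
    seeds = _replicate_seeds(config.seed, config.n_replicates)
    m, f, r, fp, conv, plq, floors = _run_replicates(
        seeds, config.steps_per_year, n_years,
        nu0N[:n_years], alpha[:n_years], beta[:n_years], nu1[:n_years],
        nu2[:n_years])
    return LesionEnsemble(
        ages=np.arange(n_years + 1, dtype=float), M=m, F=f, R=r,
        first_plaque_age=fp, conversions=conv, plaques=plq,
        floor_events=floors, t_lag=timeline.t_lag)


def simulate_individual(rate_source: RateSource, config: SimulationConfig,
                        replicate: int = 0
                        ) -> Tuple[np.ndarray, np.ndarray, np.ndarray,
                                   np.ndarray, Optional[float]]:
    """One life: annual (ages, M, F, R) snapshots and the first-plaque age."""
    timeline = _as_timeline(rate_source, config.max_age)
    n_years = int(math.ceil(config.max_age))
    nu0N, alpha, gamma, nu1, nu2 = timeline.rate_arrays()
    beta = alpha - gamma - nu1
    seed = np.array([np.random.SeedSequence(
        (config.seed, replicate)).generate_state(1)[0]], dtype=np.int64)
    m, f, r, fp, *_ = _run_replicates(
        seed, config.steps_per_year, n_years, nu0N[:n_years],
        alpha[:n_years], beta[:n_years], nu1[:n_years], nu2[:n_years])
    ages = np.arange(n_years + 1, dtype=float)
    first = None if np.isnan(fp[0]) else float(fp[0])
    return ages, m[0], f[0], r[0], first


def lesion_prevalence(rate_source: RateSource, config: SimulationConfig,
                      thresholds: Sequence[float] = (1e2, 1e3, 1e4)
                      ) -> PrevalenceCurve:
    """Fraction of replicates whose current M + F reaches each threshold."""
    thresholds = np.asarray(thresholds, dtype=float)
    if np.any(np.diff(thresholds) <= 0):
        raise ValueError("thresholds must be sorted ascending")
    ens = run_ensemble(rate_source, config)
    mf = ens.M + ens.F
    fractions = np.stack(
        [(mf >= x).mean(axis=0) for x in thresholds], axis=1)
    return PrevalenceCurve(ages=ens.ages, thresholds=thresholds,
                           fractions=fractions)


def simulate_stroke_ages(rate_source: RateSource,
                         config: SimulationConfig) -> np.ndarray:
    """Stroke ages (first plaque + t_lag) per replicate; nan where absent."""
    ens = run_ensemble(rate_source, config)
    return ens.stroke_ages(config.max_age)
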