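"""Descriptive (empirical) reference model for stroke incidence.

The baseline hazard is log-linear-spline in age and calendar year,

    h = exp(b0 + f_age(a) + f_year(y)) * prod(covariate factors)
        * (1 + lam * d) for a < mu (no dose effect at or above mu),

with piecewise-linear f_age (knots at 40 and 60 years by default; slope plus
two slope increments = 3 parameters) and f_year (knots 1970 and 1990, linear
already before the first knot).  Covariates multiply the hazard, so the
hazard ratio between categories is the same at every age — the qualitative
contrast to the mechanistic model, where selection makes relative risks fall
with age.  The age cutoff mu of the radiation term is profiled on a 1-year
grid because the likelihood is piecewise constant in mu.

Exact piecewise-exponential integration: within each annual age segment the
log hazard is linear in age, so cumulative hazards are computed in closed
form (no quadrature error).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize, stats

from .likelihood import (CATEGORIES, Cohort, WorkerRecord, _ParamTable, lrt)
from .survival import SurvivalGrid

__all__ = ["EmpiricalModel", "empirical_hazard", "empirical_survival",
           "err_age_profile", "EmpiricalStrokeModel", "EmpiricalResults"]


@dataclass(frozen=True)
class EmpiricalModel:
    """Fully specified empirical hazard."""

    log_h0: float
    age_knots: Tuple[float, float] = (40.0, 60.0)
    age_slopes: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    year_knots: Tuple[float, float] = (1970.0, 1990.0)
    year_slopes: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    covariate_factors: Mapping[str, Mapping[str, float]] = field(
        default_factory=dict)
    err_lambda: float = 0.0
    err_age_cutoff: float = math.inf

    def __post_init__(self) -> None:
        if self.err_age_cutoff <= 0:
            raise ValueError("mu must be > 0")
        for cov, fac in self.covariate_factors.items():
            if any(v <= 0 for v in fac.values()):
                raise ValueError(f"non-positive factor for {cov}")

    def log_baseline(self, age, calendar_year):
        """b0 + f_age + f_year (vectorized)."""
        a = np.asarray(age, dtype=float)
        y = np.asarray(calendar_year, dtype=float)
        k0, k1 = self.age_knots
        s0, s1, s2 = self.age_slopes
        out = self.log_h0 + s0 * (a - k0) + s1 * np.maximum(a - k0, 0.0) \
            + s2 * np.maximum(a - k1, 0.0)
        y0, y1 = self.year_knots
        c0, c1, c2 = self.year_slopes
        out = out + c0 * (y - y0) + c1 * np.maximum(y - y0, 0.0) \
            + c2 * np.maximum(y - y1, 0.0)
        return out


def _cov_factor(model: EmpiricalModel, covariates: Mapping[str, str]) -> float:
    factor = 1.0
    for cov, table in model.covariate_factors.items():
        factor *= table[covariates[cov]]
    return factor


def empirical_hazard(model: EmpiricalModel, age: float, calendar_year: float,
                     covariates: Mapping[str, str],
                     cumulative_dose: float = 0.0) -> float:
    """Hazard (1/year) at one evaluation point."""
    base = math.exp(float(model.log_baseline(age, calendar_year)))
    base *= _cov_factor(model, covariates)
    if age < model.err_age_cutoff:
        err = 1.0 + model.err_lambda * cumulative_dose
        if err <= 0:
            raise ValueError("1 + lambda*d <= 0")
        base *= err
    return base


def err_age_profile(model: EmpiricalModel, ages: Sequence[float],
                    dose: float) -> np.ndarray:
    """Relative risk (1 + lambda*d) below the cutoff, 1 at and above it."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    ages = np.asarray(ages, dtype=float)
    rr = np.where(ages < model.err_age_cutoff,
                  1.0 + model.err_lambda * dose, 1.0)
    if np.any(rr <= 0):
        raise ValueError("1 + lambda*d <= 0")
    return rr


def _segment_integral(model: EmpiricalModel, record: WorkerRecord,
                      lo: float, hi: float, dose_cum: float) -> float:
    """Exact integral of the hazard over [lo, hi] within one annual segment."""
    covs = record.covariates()
    K = _cov_factor(model, covs)
    mid = 0.5 * (lo + hi)
    if mid < model.err_age_cutoff:
        err = 1.0 + model.err_lambda * dose_cum
        if err <= 0:
            raise ValueError("1 + lambda*d <= 0")
        K *= err
    year = record.birth_year + mid
    s0, s1, s2 = model.age_slopes
    c0, c1, c2 = model.year_slopes
    b = s0 + (s1 if mid >= model.age_knots[0] else 0.0) \
        + (s2 if mid >= model.age_knots[1] else 0.0) \
        + c0 + (c1 if year >= model.year_knots[0] else 0.0) \
        + (c2 if year >= model.year_knots[1] else 0.0)
    e_mid = float(model.log_baseline(mid, year))
    half = 0.5 * (hi - lo)
    if abs(b * half) < 1e-8:
        width = (hi - lo) * (1.0 + (b * half) ** 2 / 6.0)
    else:
        width = 2.0 * math.sinh(b * half) / b
    return K * math.exp(e_mid) * width


def _segments(record: WorkerRecord, lo: float, hi: float,
              extra: Iterable[float] = ()) -> Iterable[Tuple[float, float]]:
    cuts = {lo, hi}
    cuts.update(float(k) for k in range(int(math.floor(lo)) + 1,
                                        int(math.ceil(hi))))
    cuts.update(c for c in extra if lo < c < hi)
    cuts = sorted(cuts)
    return zip(cuts[:-1], cuts[1:])


def cumulative_hazard(model: EmpiricalModel, record: WorkerRecord,
                      lo: float, hi: float) -> float:
    """Exact integral of the worker's hazard over [lo, hi]."""
    if hi < lo:
        raise ValueError("need hi >= lo")
    n_years = int(math.ceil(hi)) + 1
    dose_age = record.dose_by_age(n_years)
    cum = np.concatenate([[0.0], np.cumsum(dose_age)])
    extra = [model.err_age_cutoff, *model.age_knots,
             *(k - record.birth_year for k in model.year_knots)]
    total = 0.0
    for a, b in _segments(record, lo, hi, extra):
        k = min(int(math.floor(0.5 * (a + b))), n_years - 1)
        total += _segment_integral(model, record, a, b, float(cum[k]))
    return total


def empirical_survival(model: EmpiricalModel, record: WorkerRecord,
                       grid: Sequence[float]) -> SurvivalGrid:
    """S on a grid, normalized to 1 at the first grid point.

    Plugs into the same individual-likelihood machinery as the mechanistic
    survival grid; S(grid[0]) = 1 so ratios across follow-up are exact.
    """
    grid = np.asarray(grid, dtype=float)
    H = np.zeros_like(grid)
    for i in range(1, len(grid)):
        H[i] = H[i - 1] + cumulative_hazard(model, record,
                                            grid[i - 1], grid[i])
    h = np.array([empirical_hazard(
        model, a, record.birth_year + a, record.covariates(),
        _cum_dose_at(record, a)) for a in grid])
    return SurvivalGrid(ages=grid, S=np.exp(-H), h=h)


def _cum_dose_at(record: WorkerRecord, age: float) -> float:
    n = int(math.ceil(age)) + 1
    return float(record.dose_by_age(n)[:int(math.floor(age))].sum())


class EmpiricalStrokeModel:
    """Empirical reference model fitted by individual likelihood.

    Free parameters: intercept, three age-spline slopes, optionally three
    calendar-year slopes, one factor per non-reference covariate category,
    and the ERR slope lambda when ``err`` is enabled (its age cutoff mu is
    profiled on a grid via ``fit(mu_grid=...)``).
    """

    def __init__(self, cohort: Cohort,
                 covariates: Sequence[str] = (),
                 calendar: bool = False,
                 err: bool = False,
                 age_knots: Tuple[float, float] = (40.0, 60.0),
                 year_knots: Tuple[float, float] = (1970.0, 1990.0),
                 err_age_cutoff: float = math.inf):
        if len(cohort) == 0:
            raise ValueError("empty cohort")
        self.cohort = cohort
        self.covariates = tuple(covariates)
        self.calendar = calendar
        self.err = err
        self.age_knots = age_knots
        self.year_knots = year_knots
        self.err_age_cutoff = err_age_cutoff
        free: Dict[str, Tuple[float, float]] = {
            "log_h0": (-30.0, 3.0),
            "age_0": (-0.5, 0.5), "age_1": (-0.5, 0.5), "age_2": (-0.5, 0.5)}
        if calendar:
            for i in range(3):
                free[f"cal_{i}"] = (-0.2, 0.2)
        for cov in self.covariates:
            for cat in CATEGORIES[cov][1:]:
                free[f"haz_{cov}_{cat}"] = (0.05, 20.0)
        if err:
            free["lam"] = (-0.45, 10.0)
        self.params_table = _ParamTable(free, {})
        self._precompute()

    def _precompute(self) -> None:
        rows = []
        for i, rec in enumerate(self.cohort):
            n_years = int(math.ceil(rec.age_out)) + 1
            cum = np.concatenate([[0.0],
                                  np.cumsum(rec.dose_by_age(n_years))])
            extra = [*self.age_knots,
                     *(k - rec.birth_year for k in self.year_knots)]
            if self.err and math.isfinite(self.err_age_cutoff):
                extra.append(self.err_age_cutoff)
            for a, b in _segments(rec, rec.age_in, rec.age_out, extra):
                k = int(math.floor(0.5 * (a + b)))
                rows.append((i, a, b, rec.birth_year + 0.5 * (a + b),
                             float(cum[min(k, n_years - 1)])))
        arr = np.array(rows)
        self._seg_rec = arr[:, 0].astype(np.int64)
        self._seg_lo = arr[:, 1]
        self._seg_hi = arr[:, 2]
        self._seg_year = arr[:, 3]
        self._seg_dose = arr[:, 4]
        self._seg_mid = 0.5 * (self._seg_lo + self._seg_hi)

        ev = np.array([bool(r.event) for r in self.cohort])
        self._ev_rows = np.flatnonzero(ev)
        self._ev_age = np.array([r.age_out for r in self.cohort])[ev]
        self._ev_year = np.array(
            [r.birth_year + r.age_out for r in self.cohort])[ev]
        self._ev_dose = np.array([_cum_dose_at(r, r.age_out)
                                  for r in self.cohort])[ev]
        self._cats = {cov: np.array([getattr(r, cov) for r in self.cohort])
                      for cov in self.covariates}

    def _factors(self, params, rows):
        f = np.ones(len(rows))
        for cov in self.covariates:
            table = {CATEGORIES[cov][0]: 1.0}
            for cat in CATEGORIES[cov][1:]:
                table[cat] = params[f"haz_{cov}_{cat}"]
            f *= np.array([table[c] for c in self._cats[cov][rows]])
        return f

    def _model_from(self, params: Mapping[str, float],
                    mu: Optional[float] = None) -> EmpiricalModel:
        factors = {}
        for cov in self.covariates:
            factors[cov] = {CATEGORIES[cov][0]: 1.0}
            for cat in CATEGORIES[cov][1:]:
                factors[cov][cat] = params[f"haz_{cov}_{cat}"]
        return EmpiricalModel(
            log_h0=params["log_h0"], age_knots=self.age_knots,
            age_slopes=(params["age_0"], params["age_1"], params["age_2"]),
            year_knots=self.year_knots,
            year_slopes=((params["cal_0"], params["cal_1"], params["cal_2"])
                         if self.calendar else (0.0, 0.0, 0.0)),
            covariate_factors=factors,
            err_lambda=params.get("lam", 0.0),
            err_age_cutoff=(mu if mu is not None else self.err_age_cutoff))

    def deviance(self, params: Mapping[str, float],
                 mu: Optional[float] = None) -> float:
        mu_eff = mu if mu is not None else self.err_age_cutoff
        k0, k1 = self.age_knots
        s0 = params["age_0"]
        s1 = params["age_1"]
        s2 = params["age_2"]
        mid = self._seg_mid
        b = s0 + np.where(mid >= k0, s1, 0.0) + np.where(mid >= k1, s2, 0.0)
        e_mid = params["log_h0"] + s0 * (mid - k0) \
            + s1 * np.maximum(mid - k0, 0.0) + s2 * np.maximum(mid - k1, 0.0)
        e_ev = params["log_h0"] + s0 * (self._ev_age - k0) \
            + s1 * np.maximum(self._ev_age - k0, 0.0) \
            + s2 * np.maximum(self._ev_age - k1, 0.0)
        if self.calendar:
            y0, y1 = self.year_knots
            c0, c1, c2 = (params["cal_0"], params["cal_1"], params["cal_2"])
            b = b + c0 + np.where(self._seg_year >= y0, c1, 0.0) \
                + np.where(self._seg_year >= y1, c2, 0.0)
            e_mid = e_mid + c0 * (self._seg_year - y0) \
                + c1 * np.maximum(self._seg_year - y0, 0.0) \
                + c2 * np.maximum(self._seg_year - y1, 0.0)
            e_ev = e_ev + c0 * (self._ev_year - y0) \
                + c1 * np.maximum(self._ev_year - y0, 0.0) \
                + c2 * np.maximum(self._ev_year - y1, 0.0)
        K_seg = self._factors(params, self._seg_rec)
        K_ev = self._factors(params, self._ev_rows)
        if self.err:
            lam = params["lam"]
            err_seg = np.where(mid < mu_eff,
                               1.0 + lam * self._seg_dose, 1.0)
            err_ev = np.where(self._ev_age < mu_eff,
                              1.0 + lam * self._ev_dose, 1.0)
            if np.any(err_seg <= 0) or np.any(err_ev <= 0):
                return math.inf
            K_seg = K_seg * err_seg
            K_ev = K_ev * err_ev
        half = 0.5 * (self._seg_hi - self._seg_lo)
        bh = b * half
        width = np.where(np.abs(bh) < 1e-8,
                         2.0 * half * (1.0 + bh * bh / 6.0),
                         2.0 * np.sinh(bh) / np.where(b == 0.0, 1.0, b))
        H = float(np.sum(K_seg * np.exp(e_mid) * width))
        log_h = e_ev + np.log(K_ev)
        return 2.0 * H - 2.0 * float(np.sum(log_h))

    def fit(self, n_starts: int = 3, seed: int = 0,
            mu_grid: Optional[Sequence[float]] = None,
            start: Optional[Mapping[str, float]] = None
            ) -> "EmpiricalResults":
        table = self.params_table
        rng = np.random.default_rng(seed)
        n_eval = 0
        mus = list(mu_grid) if mu_grid is not None else [self.err_age_cutoff]
        best = (None, None)

        for mu in mus:
            def objective(x, mu=mu):
                nonlocal n_eval
                n_eval += 1
                d = self.deviance(table.to_dict(x), mu)
                return d if math.isfinite(d) else 1e12

            starts = [table.start_point(start or {"log_h0": -6.0})]
            lo = np.array([b[0] for b in table.bounds])
            hi = np.array([b[1] for b in table.bounds])
            for _ in range(max(n_starts - 1, 0)):
                x = starts[0] + 0.3 * (hi - lo) * rng.uniform(
                    -1, 1, size=len(lo))
                starts.append(np.clip(x, lo, hi))
            for x0 in starts:
                res = optimize.minimize(objective, x0, method="L-BFGS-B",
                                        bounds=table.bounds,
                                        options={"maxiter": 500,
                                                 "ftol": 1e-10})
                if best[0] is None or res.fun < best[0].fun:
                    best = (res, mu)
        res, mu = best
        if not math.isfinite(res.fun) or res.fun >= 1e12:
            raise RuntimeError("no finite-deviance point found")
        params = table.to_dict(res.x)
        return EmpiricalResults(self, params, float(res.fun),
                                mu=float(mu), converged=bool(res.success),
                                n_evaluations=n_eval, seed=seed)


@dataclass
class EmpiricalResults:
    model: EmpiricalStrokeModel
    params: Dict[str, float]
    minus2logl: float
    mu: float
    converged: bool
    n_evaluations: int
    seed: int
    profile_intervals: Dict[str, Tuple[float, float]] = field(
        default_factory=dict)

    def as_empirical_model(self) -> EmpiricalModel:
        return self.model._model_from(self.params, self.mu)

    def profile_ci(self, name: str, level: float = 0.95
                   ) -> Tuple[float, float]:
        table = self.model.params_table
        if name not in table.names:
            raise KeyError(f"{name} is not a free parameter")
        crit = float(stats.chi2.ppf(level, 1))
        target = self.minus2logl + crit
        idx = table.names.index(name)
        lo_b, hi_b = table.bounds[idx]
        theta = self.params[name]

        def profiled(v):
            free = {n: b for n, b in zip(table.names, table.bounds)
                    if n != name}
            sub = _ParamTable(free, {name: v})

            def obj(x):
                d = self.model.deviance(sub.to_dict(x), self.mu)
                return d if math.isfinite(d) else 1e12

            res = optimize.minimize(obj, sub.start_point(self.params),
                                    method="L-BFGS-B", bounds=sub.bounds,
                                    options={"maxiter": 300, "ftol": 1e-10})
            return float(res.fun)

        def g(v):
            return profiled(v) - target

        def search(direction: int) -> float:
            bound = hi_b if direction > 0 else lo_b
            step = max(0.02 * (hi_b - lo_b), 0.02 * abs(theta) + 1e-4)
            prev = theta
            for _ in range(60):
                cand = theta + direction * step
                if (direction > 0 and cand >= bound) or \
                        (direction < 0 and cand <= bound):
                    if g(bound) < 0:
                        return bound
                    cand = bound
                if g(cand) >= 0:
                    a, b = sorted((prev, cand))
                    return float(optimize.brentq(g, a, b, xtol=1e-5))
                prev = cand
                step *= 1.8
            return bound

        interval = (search(-1), search(+1))
        self.profile_intervals[name] = interval
        return interval

    def lrt_against(self, null: "EmpiricalResults") -> float:
        df = (len(self.model.params_table.names)
              - len(null.model.params_table.names))
        return lrt(null.minus2logl, self.minus2logl, df)

    def summary(self) -> str:
        lines = ["Empirical stroke model fit",
                 "=" * 34,
                 f"workers: {len(self.model.cohort)}   "
                 f"cases: {self.model.cohort.n_cases}",
                 f"deviance (-2 ln l): {self.minus2logl:.3f}",
                 f"ERR age cutoff mu: {self.mu}",
                 "-" * 34]
        for name in self.model.params_table.names:
            ci = self.profile_intervals.get(name)
            ci_s = f"({ci[0]:.4g}, {ci[1]:.4g})" if ci else ""
            lines.append(f"{name:<20}{self.params[name]:>12.4g}  {ci_s}")
        return "\n".join(lines)
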