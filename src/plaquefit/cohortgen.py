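"""Synthetic occupational cohorts with known generating truth.

Emulates the structure the likelihood machinery assumes: male workers hired
over a fixed calendar window (1948-1972 by default), follow-up from first
employment to stroke, death, emigration or an administrative cutoff (2008),
categorical covariates fixed at entry, and annual external gamma-dose
histories during employment whose overall scale is solved to reproduce a
target median cumulative dose (0.28 Gy) with an early-era excess.

Stroke ages are drawn by inverse-CDF sampling from the analytic stroke-free
survival of the generating truth (exact under the model and fast); the
stochastic simulator provides an independent cross-check of that sampling
path.  Censoring is drawn independently of the latent cell state
(non-informative): Gompertz other-cause mortality, exponential emigration
and the administrative cutoff.

Entry-age and employment-duration distributions are modelling assumptions
of this generator, not cohort facts; see the package methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .empirical import EmpiricalModel, cumulative_hazard
from .likelihood import CATEGORIES, Cohort, WorkerRecord
from .params import (AgePowerLaw, CovariateModifier, DoseResponse,
                     ParameterContext, RateSet, evaluate_rates)
from .survival import (DEFAULT_OPTIONS, ParameterTimeline, SolverOptions,
                       SurvivalGrid, solve_cached)

__all__ = ["CohortDesign", "MechanisticTruth", "EmpiricalTruth",
           "GeneratedCohort", "generate_cohort", "stroke_age_from_survival",
           "save_manifest", "load_manifest", "default_design"]


@dataclass(frozen=True)
class MechanisticTruth:
    rates: RateSet
    age_laws: Tuple[AgePowerLaw, ...] = ()
    modifiers: Tuple[CovariateModifier, ...] = ()
    dose_response: Optional[DoseResponse] = None


@dataclass(frozen=True)
class EmpiricalTruth:
    model: EmpiricalModel


@dataclass(frozen=True)
class DoseModelDesign:
    """Annual lognormal doses during employment, scaled to a target median."""

    target_median_gy: float = 0.28
    annual_sigma: float = 0.8
    worker_sigma: float = 1.1
    era_decay_per_year: float = 0.08  # early-plant years carry higher doses
    employment_log_mean: float = math.log(12.0)
    employment_log_sd: float = 0.9


@dataclass(frozen=True)
class CensoringDesign:
    """Non-informative exits: Gompertz mortality, emigration, admin cutoff."""

    gompertz_level: float = 0.005   # other-cause mortality at age 40 (1/y)
    gompertz_slope: float = 0.085   # log-hazard slope (1/y)
    emigration_rate: float = 0.025  # 1/y
    admin_end_year: int = 2008


def _default_prevalences() -> Dict[str, Dict[str, float]]:
    return {"smoking": {"nonsmoker": 0.4, "smoker_or_ex": 0.5,
                        "unknown": 0.1},
            "blood_pressure": {"normal": 0.70, "hypertensive": 0.25,
                               "unknown": 0.05},
            "graduation": {"none": 0.75, "higher": 0.20, "unknown": 0.05}}


@dataclass(frozen=True)
class CohortDesign:
    n_workers: int
    truth: object  # MechanisticTruth | EmpiricalTruth
    seed: int
    hire_year_range: Tuple[int, int] = (1948, 1972)
    entry_age_mean: float = 22.0
    entry_age_sd: float = 5.0
    entry_age_range: Tuple[float, float] = (18.0, 45.0)
    covariate_prevalences: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_prevalences)
    dose_model: DoseModelDesign = DoseModelDesign()
    censoring: CensoringDesign = CensoringDesign()
    max_age: float = 105.0

    def __post_init__(self) -> None:
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")
        for cov, probs in self.covariate_prevalences.items():
            if set(probs) != set(CATEGORIES[cov]):
                raise ValueError(f"prevalences for {cov} must cover "
                                 f"{CATEGORIES[cov]}")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"prevalences for {cov} must sum to 1")


def default_design(n_workers: int, truth: object, seed: int,
                   **overrides) -> CohortDesign:
    return CohortDesign(n_workers=n_workers, truth=truth, seed=seed,
                        **overrides)


@dataclass(frozen=True)
class GeneratedCohort:
    cohort: Cohort
    truth_manifest: Dict


def stroke_age_from_survival(grid: SurvivalGrid, rng: np.random.Generator,
                             age_in: float = 0.0) -> Optional[float]:
    """Inverse-transform sample of the stroke age, left-truncated at age_in.

    Draws U uniform on (0, S(age_in)) and returns the age where S crosses U
    (log-linear interpolation); None if the draw falls beyond the grid.
    """
    logS = np.log(grid.S)
    if np.any(np.diff(logS) > 1e-12):
        raise ValueError("survival grid must be non-increasing")
    log_u = math.log(rng.uniform()) + float(grid.log_S(age_in))
    if log_u < logS[-1]:
        return None
    j = int(np.searchsorted(-logS, -log_u, side="left"))
    if j == 0:
        return float(grid.ages[0])
    denom = logS[j] - logS[j - 1]
    frac = 0.0 if denom == 0.0 else (log_u - logS[j - 1]) / denom
    return float(grid.ages[j - 1]
                 + frac * (grid.ages[j] - grid.ages[j - 1]))


def _gompertz_death_age(rng, age_in, level, slope):
    # inversion of H(a) - H(age_in) = Exp(1) for h(a) = level*exp(slope*(a-40))
    e = rng.exponential()
    base = math.exp(slope * (age_in - 40.0))
    return 40.0 + math.log(base + slope * e / level) / slope


class _MechanisticSampler:
    def __init__(self, truth: MechanisticTruth, max_age: float,
                 options: SolverOptions):
        self.truth = truth
        self.max_age = max_age
        self.options = options
        self._cache: Dict[tuple, SurvivalGrid] = {}
        self._rate_covs = sorted({m.covariate_name for m in truth.modifiers})
        self._n_years = int(math.ceil(max_age))

    def grid_for(self, covs: Dict[str, str],
                 dose_age: Optional[np.ndarray]) -> SurvivalGrid:
        key = (tuple(covs[c] for c in self._rate_covs),
               dose_age.tobytes() if dose_age is not None else b"")
        if key not in self._cache:
            cum = (np.concatenate([[0.0], np.cumsum(dose_age)])
                   if dose_age is not None else None)
            rates = []
            for k in range(self._n_years):
                ctx = ParameterContext(
                    age=k + 0.5,
                    covariates={c: covs[c] for c in self._rate_covs},
                    cumulative_dose=float(cum[k]) if cum is not None else 0.0,
                    annual_dose_rate=(float(dose_age[k])
                                      if dose_age is not None else 0.0))
                rates.append(evaluate_rates(
                    self.truth.rates, self.truth.age_laws,
                    self.truth.modifiers, self.truth.dose_response, ctx))
            timeline = ParameterTimeline(rates=tuple(rates))
            ages = np.arange(0.0, self.max_age + 1.0)
            self._cache[key] = solve_cached(timeline, ages, self.options)
        return self._cache[key]


def generate_cohort(design: CohortDesign,
                    solver_options: SolverOptions = DEFAULT_OPTIONS
                    ) -> GeneratedCohort:
    """Draw a cohort from the design; same design + seed is bit-reproducible."""
    rng = np.random.default_rng(design.seed)
    n = design.n_workers
    y0, y1 = design.hire_year_range
    hire_years = rng.integers(y0, y1 + 1, size=n)

    lo, hi = design.entry_age_range
    entry_ages = np.empty(n)
    for i in range(n):
        while True:
            a = rng.normal(design.entry_age_mean, design.entry_age_sd)
            if lo <= a <= hi:
                entry_ages[i] = a
                break
    entry_ages = np.round(entry_ages, 3)

    covs: Dict[str, np.ndarray] = {}
    for cov in ("smoking", "blood_pressure", "graduation"):
        cats = list(CATEGORIES[cov])  # canonical order: draws must not
        probs = [design.covariate_prevalences[cov][c] for c in cats]
        # depend on the mapping's key order (manifest round-trip safety)
        covs[cov] = rng.choice(cats, size=n, p=probs)

    # employment durations and unscaled annual doses
    dm = design.dose_model
    admin = design.censoring.admin_end_year
    durations = np.clip(
        rng.lognormal(dm.employment_log_mean, dm.employment_log_sd, size=n),
        1.0, admin - hire_years).astype(int).clip(min=1)
    worker_level = rng.lognormal(0.0, dm.worker_sigma, size=n)
    raw_histories = []
    for i in range(n):
        years = np.arange(hire_years[i], hire_years[i] + durations[i])
        era = np.exp(-dm.era_decay_per_year * (years - y0))
        annual = worker_level[i] * era * rng.lognormal(
            0.0, dm.annual_sigma, size=len(years))
        raw_histories.append((years, annual))
    totals = np.array([a.sum() for _, a in raw_histories])
    scale = dm.target_median_gy / np.median(totals)
    histories = [tuple((int(y), round(float(d * scale), 6))
                       for y, d in zip(years, annual))
                 for years, annual in raw_histories]

    # stroke ages from the truth's analytic survival
    if isinstance(design.truth, MechanisticTruth):
        sampler = _MechanisticSampler(design.truth, design.max_age,
                                      solver_options)
        dose_active = design.truth.dose_response is not None
    elif isinstance(design.truth, EmpiricalTruth):
        sampler = None
        dose_active = False
    else:
        raise TypeError("truth must be MechanisticTruth or EmpiricalTruth")

    records = []
    cens = design.censoring
    for i in range(n):
        age_in = float(entry_ages[i])
        cov_i = {c: str(covs[c][i]) for c in covs}
        birth_year = int(hire_years[i] - math.floor(age_in))
        if sampler is not None:
            dose_age = None
            if dose_active:
                dose_age = np.zeros(int(math.ceil(design.max_age)))
                for y, d in histories[i]:
                    k = y - birth_year
                    if 0 <= k < len(dose_age):
                        dose_age[k] += d
            grid = sampler.grid_for(cov_i, dose_age)
            stroke = stroke_age_from_survival(grid, rng, age_in)
        else:
            stroke = _empirical_stroke_age(
                design.truth.model, rng, birth_year, age_in, cov_i,
                histories[i], design.max_age)
        death = _gompertz_death_age(rng, age_in, cens.gompertz_level,
                                    cens.gompertz_slope)
        emig = age_in + rng.exponential(1.0 / cens.emigration_rate)
        admin_age = age_in + (admin - hire_years[i]) + 1.0
        cens_age = min(death, emig, admin_age, design.max_age)
        if stroke is not None and stroke < cens_age:
            age_out, event = stroke, 1
        else:
            age_out, event = cens_age, 0
        records.append(WorkerRecord(
            id=f"w{i:06d}", birth_year=birth_year, age_in=age_in,
            age_out=round(float(age_out), 4), event=event,
            smoking=cov_i["smoking"],
            blood_pressure=cov_i["blood_pressure"],
            graduation=cov_i["graduation"],
            dose_history=histories[i]))

    manifest = _manifest(design)
    return GeneratedCohort(cohort=Cohort(records), truth_manifest=manifest)


def _empirical_stroke_age(model: EmpiricalModel, rng, birth_year, age_in,
                          cov_i, history, max_age) -> Optional[float]:
    record = WorkerRecord(id="tmp", birth_year=birth_year, age_in=age_in,
                          age_out=max_age, event=0, dose_history=history,
                          **cov_i)
    target = rng.exponential()
    lo_a, hi_a = age_in, max_age
    if cumulative_hazard(model, record, age_in, max_age) < target:
        return None
    for _ in range(60):
        mid = 0.5 * (lo_a + hi_a)
        if cumulative_hazard(model, record, age_in, mid) < target:
            lo_a = mid
        else:
            hi_a = mid
    return 0.5 * (lo_a + hi_a)


# ----------------------------------------------------------------------
# truth manifest serialization
# ----------------------------------------------------------------------

def _truth_dict(truth) -> Dict:
    if isinstance(truth, MechanisticTruth):
        return {"kind": "mechanistic",
                "rates": asdict(truth.rates),
                "age_laws": [asdict(l) for l in truth.age_laws],
                "modifiers": [{"parameter_name": m.parameter_name,
                               "covariate_name": m.covariate_name,
                               "multipliers": dict(m.multipliers)}
                              for m in truth.modifiers],
                "dose_response": (asdict(truth.dose_response)
                                  if truth.dose_response else None)}
    return {"kind": "empirical",
            "model": {**asdict(truth.model),
                      "covariate_factors": {
                          k: dict(v) for k, v in
                          truth.model.covariate_factors.items()}}}


def _manifest(design: CohortDesign) -> Dict:
    return {"schema": "plaquefit-cohort-design/1",
            "seed": design.seed,
            "n_workers": design.n_workers,
            "hire_year_range": list(design.hire_year_range),
            "entry_age": {"mean": design.entry_age_mean,
                          "sd": design.entry_age_sd,
                          "range": list(design.entry_age_range)},
            "covariate_prevalences": {
                k: dict(v) for k, v in design.covariate_prevalences.items()},
            "dose_model": asdict(design.dose_model),
            "censoring": asdict(design.censoring),
            "max_age": design.max_age,
            "truth": _truth_dict(design.truth)}


def save_manifest(manifest: Dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def load_manifest(path) -> Dict:
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "seed" not in manifest:
        raise ValueError("manifest must be a mapping containing a seed")
    if manifest.get("schema") != "plaquefit-cohort-design/1":
        raise ValueError("unknown manifest schema")
    return manifest


def design_from_manifest(manifest: Dict) -> CohortDesign:
    """Rebuild a CohortDesign (with truth) from a saved manifest."""
    t = manifest["truth"]
    if t["kind"] == "mechanistic":
        truth = MechanisticTruth(
            rates=RateSet(**t["rates"]),
            age_laws=tuple(AgePowerLaw(**l) for l in t["age_laws"]),
            modifiers=tuple(CovariateModifier(**m) for m in t["modifiers"]),
            dose_response=(DoseResponse(**t["dose_response"])
                           if t["dose_response"] else None))
    else:
        m = dict(t["model"])
        for key in ("age_knots", "age_slopes", "year_knots", "year_slopes"):
            m[key] = tuple(m[key])
        truth = EmpiricalTruth(model=EmpiricalModel(**m))
    return CohortDesign(
        n_workers=manifest["n_workers"], truth=truth,
        seed=manifest["seed"],
        hire_year_range=tuple(manifest["hire_year_range"]),
        entry_age_mean=manifest["entry_age"]["mean"],
        entry_age_sd=manifest["entry_age"]["sd"],
        entry_age_range=tuple(manifest["entry_age"]["range"]),
        covariate_prevalences=manifest["covariate_prevalences"],
        dose_model=DoseModelDesign(**manifest["dose_model"]),
        censoring=CensoringDesign(**manifest["censoring"]),
        max_age=manifest["max_age"])
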