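"""Biological parameterization of the atherosclerosis model.

The disease model tracks three cell populations in the arterial wall:
macrophages (M), foam cells plus their debris (F) and vulnerable plaques (R).
Five rates govern the dynamics, all in units of 1/year:

* ``nu0N`` — product of the monocyte pool size N and the per-monocyte uptake
  rate nu0 (only the product is identifiable);
* ``alpha`` — macrophage proliferation rate;
* ``gamma`` — effective (net) proliferation rate, gamma = alpha - beta - nu1,
  where beta is the rate of macrophage death/emigration;
* ``nu1`` — rate at which a macrophage turns into a foam cell;
* ``nu2`` — rate at which one foam cell (or its debris) seeds a vulnerable
  plaque.

A vulnerable plaque causes a first stroke exactly ``t_lag`` years after its
formation.  gamma rather than beta is the stored parameter; beta is always
derived (beta = alpha - gamma - nu1) and must be non-negative.

Rates may be modified by a power law in age, by categorical covariates
(multiplicative factors per category) and by radiation dose (linear excess
in cumulative dose or annual dose rate).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

RATE_NAMES = ("nu0N", "alpha", "gamma", "nu1", "nu2")

#: Reference ages (years) at which the fit constraints on each rate apply.
DEFAULT_REFERENCE_AGES = {"nu0N": 10.0, "alpha": 40.0, "gamma": 40.0,
                          "nu1": 40.0, "nu2": 60.0}

#: Box constraints used when a rate is free in a fit (per year).
DEFAULT_FIT_BOUNDS = {"nu0N": (1.0, 10.0), "gamma": (0.1, 0.3),
                      "nu1": (0.1, 12.0)}

#: Values at which the non-identifiable parameters are conventionally fixed.
DEFAULT_FIXED = {"alpha": 12.0, "nu2": 1e-7, "t_lag": 10.0}


class InvalidParameterizationError(ValueError):
    """A rate combination is biologically infeasible (e.g. beta < 0)."""


@dataclass(frozen=True)
class RateSet:
    """The five biological rates plus the plaque-to-stroke lag.

    All rates are per year, ``t_lag`` in years.  ``beta`` is derived.
    """

    nu0N: float
    alpha: float
    gamma: float
    nu1: float
    nu2: float
    t_lag: float = DEFAULT_FIXED["t_lag"]

    def __post_init__(self) -> None:
        # gamma is a *net* rate (alpha - beta - nu1) and may be negative,
        # e.g. when proliferation is absent; the physical constraints are
        # non-negative event rates and beta >= 0.
        for name in ("nu0N", "alpha", "nu1", "nu2"):
            if getattr(self, name) < 0:
                raise InvalidParameterizationError(
                    f"rate {name} must be >= 0, got {getattr(self, name)}")
        if self.t_lag < 0:
            raise InvalidParameterizationError("t_lag must be >= 0")
        # triggers the beta >= 0 check
        self.beta  # noqa: B018

    @property
    def beta(self) -> float:
        """Macrophage death/emigration rate, alpha - gamma - nu1 (per year)."""
        return beta_from_rates(self)

    def with_(self, **kwargs: float) -> "RateSet":
        return replace(self, **kwargs)


def beta_from_rates(rates: RateSet) -> float:
    """Derive beta = alpha - gamma - nu1 and reject infeasible combinations.

    gamma = alpha - beta - nu1 defines the effective proliferation rate; a
    negative beta (death rate) is meaningless, so gamma + nu1 must not exceed
    alpha.
    """
    beta = rates.alpha - rates.gamma - rates.nu1
    if beta < 0:
        raise InvalidParameterizationError(
            f"beta = alpha - gamma - nu1 = {beta:.6g} < 0 "
            f"(alpha={rates.alpha}, gamma={rates.gamma}, nu1={rates.nu1})")
    return beta


@dataclass(frozen=True)
class AgePowerLaw:
    """Power-law age dependence of one rate.

    eta(a) = eta(a0) * ((a + offset) / (a0 + offset))**psi

    with offset = 10 years regularizing the law near birth.  ``a0`` is the
    reference age at which the fit constraints apply.
    """

    parameter_name: str
    psi: float
    a0: Optional[float] = None
    offset: float = 10.0

    def __post_init__(self) -> None:
        if self.parameter_name not in RATE_NAMES:
            raise ValueError(f"unknown rate {self.parameter_name!r}")
        if not -1.0 <= self.psi <= 1.0:
            raise ValueError(f"psi must lie in [-1, 1], got {self.psi}")
        if self.a0 is None:
            object.__setattr__(
                self, "a0", DEFAULT_REFERENCE_AGES[self.parameter_name])


def age_scaled(value_at_a0: float, law: AgePowerLaw, age: float) -> float:
    """Evaluate a rate under its power-law age dependence."""
    if age < 0:
        raise ValueError("age must be >= 0")
    return value_at_a0 * ((age + law.offset) / (law.a0 + law.offset)) ** law.psi


@dataclass(frozen=True)
class CovariateModifier:
    """Multiplicative category factors acting on one rate.

    Exactly one category is the reference with factor 1; the others carry
    positive multipliers (e.g. hypertension doubling nu2).
    """

    parameter_name: str
    covariate_name: str
    multipliers: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.parameter_name not in RATE_NAMES:
            raise ValueError(f"unknown rate {self.parameter_name!r}")
        if not any(m == 1.0 for m in self.multipliers.values()):
            raise ValueError(
                "a reference category with factor 1 is required, "
                f"got {dict(self.multipliers)}")
        if any(m <= 0 for m in self.multipliers.values()):
            raise ValueError("multipliers must be > 0")

    def factor(self, category: str) -> float:
        try:
            return self.multipliers[category]
        except KeyError:
            raise KeyError(
                f"category {category!r} not covered by modifier on "
                f"{self.covariate_name}") from None


@dataclass(frozen=True)
class DoseResponse:
    """Linear excess of one rate in radiation dose.

    ``cumulative_dose`` mode scales by (1 + lam * d) with d the dose in Gy
    accumulated up to the age considered; ``annual_dose_rate`` mode scales by
    (1 + lam * r) with r the dose rate in Gy/year of the calendar year
    considered.
    """

    parameter_name: str
    mode: str  # "cumulative_dose" | "annual_dose_rate"
    lam: float

    def __post_init__(self) -> None:
        if self.parameter_name not in RATE_NAMES:
            raise ValueError(f"unknown rate {self.parameter_name!r}")
        if self.mode not in ("cumulative_dose", "annual_dose_rate"):
            raise ValueError(f"unknown dose-response mode {self.mode!r}")


@dataclass(frozen=True)
class ParameterContext:
    """Where a rate is evaluated: age, covariates, dose and calendar year."""

    age: float = 0.0
    covariates: Mapping[str, str] = field(default_factory=dict)
    cumulative_dose: float = 0.0
    annual_dose_rate: float = 0.0
    calendar_year: Optional[int] = None

    def __post_init__(self) -> None:
        if self.age < 0 or self.cumulative_dose < 0 or self.annual_dose_rate < 0:
            raise ValueError("age and doses must be >= 0")


def dose_modified(base: float, dr: DoseResponse, context: ParameterContext) -> float:
    """Apply the linear dose response; a non-positive factor is an error.

    The factor (1 + lam*x) is not clamped — the fitting machinery relies on
    the error to repel the optimizer from invalid slopes.
    """
    x = (context.cumulative_dose if dr.mode == "cumulative_dose"
         else context.annual_dose_rate)
    factor = 1.0 + dr.lam * x
    if factor <= 0:
        raise InvalidParameterizationError(
            f"dose factor 1 + {dr.lam}*{x} = {factor:.6g} <= 0")
    return base * factor


def evaluate_rates(base: RateSet,
                   laws: Sequence[AgePowerLaw] = (),
                   mods: Sequence[CovariateModifier] = (),
                   dr: Optional[DoseResponse] = None,
                   context: ParameterContext = ParameterContext()) -> RateSet:
    """Realized rates at one context: age law, then covariates, then dose.

    At most one age law per rate.  beta is recomputed from the transformed
    alpha, gamma and nu1 and validated after the composition (an age law on
    alpha may push beta below zero only in combination).
    """
    seen = set()
    for law in laws:
        if law.parameter_name in seen:
            raise ValueError(f"multiple age laws for {law.parameter_name}")
        seen.add(law.parameter_name)

    values = {name: getattr(base, name) for name in RATE_NAMES}
    for law in laws:
        values[law.parameter_name] = age_scaled(
            values[law.parameter_name], law, context.age)
    for mod in mods:
        category = context.covariates.get(mod.covariate_name)
        if category is None:
            raise KeyError(
                f"context lacks covariate {mod.covariate_name!r}")
        values[mod.parameter_name] *= mod.factor(category)
    if dr is not None:
        values[dr.parameter_name] = dose_modified(
            values[dr.parameter_name], dr, context)
    return RateSet(t_lag=base.t_lag, **values)


def proliferation_bound(n_max: float, n_seed: float,
                        ratio_nu1_gamma: float, duration: float) -> float:
    """Upper bound on gamma from lesion growth over a lifetime.

    Exponential net growth from ``n_seed`` macrophages to at most ``n_max``
    foam cells within ``duration`` years, with a foam-cell-to-macrophage
    ratio nu1/gamma, gives

        gamma <= [ln(n_max/n_seed) - ln(nu1/gamma)] / duration.
    """
    if n_seed <= 0 or n_max <= n_seed:
        raise ValueError("need n_max > n_seed > 0")
    if ratio_nu1_gamma <= 0 or duration <= 0:
        raise ValueError("ratio and duration must be > 0")
    return (math.log(n_max / n_seed) - math.log(ratio_nu1_gamma)) / duration


def attributable_fraction(err_per_gy: float, dose: float) -> float:
    """Fraction of cases attributable to radiation, ERR*d / (1 + ERR*d)."""
    excess = err_per_gy * dose
    if 1.0 + excess <= 0:
        raise ValueError("1 + ERR*d must be > 0")
    return excess / (1.0 + excess)
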