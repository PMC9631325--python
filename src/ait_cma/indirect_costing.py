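"""Human-capital valuation of productivity losses and symptom-relief costing.

The base case values only treatment-related productivity loss: two hours of
foregone gross wages per healthcare-professional interaction. Disease-related
absenteeism and presenteeism over the 50-day tree pollen season, and the cost
of symptom-relieving medication, enter only through sensitivity scenarios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .errors import ConfigurationError, InvalidParameterError
from .schedules import VisitSchedule


@dataclass(frozen=True)
class HumanCapitalParams:
    """Wage and workforce parameters for the human capital approach.

    ``annual_working_hours`` converts annual gross salary to an hourly wage;
    ``working_days_per_year`` converts it to a daily wage for the
    disease-burden scenario.

    The default working year is 220 workdays of 8 hours (1,760 contracted
    hours) scaled by the 96.7% employment rate to 1,701.92 effective hours,
    so the employment-adjusted hourly wage equals the contracted wage over a
    full 1,760-hour year (336,138/1,760 = 190.99 DKK/h at the default sex
    mix). This convention reproduces the published per-visit productivity
    losses exactly.
    """

    mean_age: float = 36.1
    proportion_male: float = 0.47
    annual_salary_male: float = 381_400.0
    annual_salary_female: float = 296_000.0
    workforce_entry_age: float = 18.0
    retirement_age: float = 67.0
    unemployment_rate: float = 0.033
    working_days_per_year: float = 220.0
    annual_working_hours: float = 1_760.0 * 0.967  # = 1,701.92 effective h
    hours_lost_per_visit: float = 2.0

    def __post_init__(self) -> None:
        for attr in ("proportion_male", "unemployment_rate"):
            if not (0.0 <= getattr(self, attr) <= 1.0):
                raise InvalidParameterError(f"{attr} must lie in [0, 1]")
        for attr in ("annual_salary_male", "annual_salary_female",
                     "hours_lost_per_visit"):
            if getattr(self, attr) < 0:
                raise InvalidParameterError(f"{attr} must be >= 0")
        if self.workforce_entry_age >= self.retirement_age:
            raise InvalidParameterError("entry age must precede retirement age")
        if self.working_days_per_year <= 0 or self.annual_working_hours <= 0:
            raise InvalidParameterError(
                "working_days_per_year and annual_working_hours must be > 0")

    @property
    def weighted_annual_salary(self) -> float:
        return (self.proportion_male * self.annual_salary_male
                + (1.0 - self.proportion_male) * self.annual_salary_female)


def hourly_wage(hc: HumanCapitalParams) -> float:
    """Employment-adjusted average hourly wage (DKK/h)."""
    return (hc.weighted_annual_salary * (1.0 - hc.unemployment_rate)
            / hc.annual_working_hours)


def daily_wage(hc: HumanCapitalParams) -> float:
    """Employment-adjusted average daily wage (DKK/workday)."""
    return (hc.weighted_annual_salary * (1.0 - hc.unemployment_rate)
            / hc.working_days_per_year)


def per_visit_loss(hc: HumanCapitalParams) -> float:
    """Productivity loss per healthcare-professional interaction (DKK)."""
    return hc.hours_lost_per_visit * hourly_wage(hc)


def visit_indirect_cost(schedule: VisitSchedule,
                        hc: HumanCapitalParams) -> list[float]:
    """Per-year indirect cost of attending the scheduled visits."""
    loss = per_visit_loss(hc)
    return [year.total * loss for year in schedule.years]


def relative_risk_from_reduction(reduction: float) -> float:
    """Relative risk corresponding to a stated proportional reduction
    (a 42% reduction in sick days corresponds to a relative risk of 0.58)."""
    if not (0.0 <= reduction <= 1.0):
        raise InvalidParameterError("reduction must lie in [0, 1]")
    return 1.0 - reduction


@dataclass(frozen=True)
class DiseaseBurdenParams:
    """Disease-related absenteeism/presenteeism over the tree pollen season.

    Placebo-arm trial observations: a fraction of season days lost as sick
    days, and a mean on-the-job productivity level. Active treatment scales
    sick days by ``sick_day_relative_risk`` and raises productivity by
    ``productivity_gain_points``. ``tps_workday_fraction`` scales season days
    to workdays (default 1: no weekend adjustment).
    """

    tps_days: float = 50.0
    placebo_sick_day_rate: float = 0.0129
    sick_day_relative_risk: float = 0.58
    placebo_productivity: float = 0.893
    productivity_gain_points: float = 0.034
    apply_equally_to_both_arms: bool = True
    tps_workday_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.tps_days < 0:
            raise InvalidParameterError("tps_days must be >= 0")
        for attr in ("placebo_sick_day_rate", "sick_day_relative_risk",
                     "placebo_productivity", "tps_workday_fraction"):
            if not (0.0 <= getattr(self, attr) <= 1.0):
                raise InvalidParameterError(f"{attr} must lie in [0, 1]")

    @property
    def tps_workdays(self) -> float:
        return self.tps_days * self.tps_workday_fraction

    def sick_day_rate(self, treated: bool) -> float:
        rr = self.sick_day_relative_risk if treated else 1.0
        return self.placebo_sick_day_rate * rr

    def productivity(self, treated: bool) -> float:
        gain = self.productivity_gain_points if treated else 0.0
        return self.placebo_productivity + gain


def disease_burden_cost(db: DiseaseBurdenParams, hc: HumanCapitalParams,
                        treated: bool) -> float:
    """Annual cost (DKK) of pollen-season absenteeism and presenteeism.

    Absenteeism: sick days valued at the full daily wage. Presenteeism: the
    productivity shortfall on the remaining season workdays, valued at the
    daily wage.
    """
    wage = daily_wage(hc)
    sick_days = db.sick_day_rate(treated) * db.tps_workdays
    absenteeism = sick_days * wage
    present_days = db.tps_workdays - sick_days
    presenteeism = (1.0 - db.productivity(treated)) * present_days * wage
    return absenteeism + presenteeism


@dataclass(frozen=True)
class SymptomMedication:
    """One symptom-relieving medication used over the tree pollen season."""

    name: str
    proportion_using: float
    seasonal_dose: float
    pack_price: float
    pack_size: float
    unit: Literal["tablets", "drops", "sprays"]
    pack_ml: float | None = None
    drops_per_ml: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.proportion_using <= 1.0):
            raise InvalidParameterError("proportion_using must lie in [0, 1]")
        if self.seasonal_dose < 0:
            raise InvalidParameterError("seasonal_dose must be >= 0")
        if self.pack_price <= 0 or self.pack_size <= 0:
            raise InvalidParameterError("pack_price and pack_size must be > 0")

    @property
    def per_unit_price(self) -> float:
        if self.unit == "drops":
            if not self.pack_ml or not self.drops_per_ml:
                raise ConfigurationError(
                    f"{self.name}: eyedrop pricing requires pack_ml and drops_per_ml")
            return self.pack_price / (self.pack_ml * self.drops_per_ml)
        return self.pack_price / self.pack_size


def symptom_med_cost(medications: Iterable[SymptomMedication]) -> float:
    """Expected annual symptom-relief medication cost per patient (DKK)."""
    return sum(m.proportion_using * m.seasonal_dose * m.per_unit_price
               for m in medications)
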