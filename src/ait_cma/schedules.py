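"""Visit schedules and drug consumption for the two immunotherapy arms.

Subcutaneous immunotherapy (SCIT) requires one clinic visit per injection:
a weekly up-dosing (titration) phase, two bridging "transition" injections of
the full maintenance dose, and an ongoing maintenance injection every six
weeks. Sublingual immunotherapy (SLIT) is a daily at-home tablet; only the
supervised first dose and one annual evaluation per treatment year generate
clinic visits.

Counts are carried as real numbers throughout (the steady-state maintenance
rate of 52/6 weeks is conventionally reported as 8.7 visits/year and that
one-decimal figure is used for all downstream costing).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

from .errors import InvalidParameterError, ModalityError
from .rounding import round_half_up

Modality = Literal["SCIT", "SLIT"]

WEEKS_PER_YEAR = 52
#: A treatment year of exactly 52 weeks (364 days) is used for daily-tablet
#: counting; see docs/methods.md for the rationale.
DAYS_PER_TREATMENT_YEAR = 364


@dataclass(frozen=True)
class DosingScheme:
    """Dosing rules for one treatment arm.

    For SCIT, ``titration_injections`` doses are given over
    ``titration_span_weeks``, followed by ``transition_injections`` full-dose
    injections at the offsets in ``transition_intervals_weeks`` (cumulative
    weeks after the end of titration), then ongoing maintenance every
    ``maintenance_interval_weeks``. ``first_year_maintenance`` optionally fixes
    the number of year-1 maintenance injections where the regimen definition
    states it explicitly; otherwise it is derived by packing maintenance
    visits into the remainder of the 52-week year.

    For SLIT, all injection counts are zero; ``tablets_per_day`` and
    ``annual_evaluations_per_year`` drive consumption and visits.
    """

    name: str
    modality: Modality
    titration_injections: int = 0
    titration_span_weeks: float = 0.0
    transition_injections: int = 0
    transition_intervals_weeks: tuple[float, ...] = ()
    maintenance_interval_weeks: float = 0.0
    tablets_per_day: float = 0.0
    annual_evaluations_per_year: int = 0
    first_year_maintenance: int | None = None

    def __post_init__(self) -> None:
        if self.modality not in ("SCIT", "SLIT"):
            raise ModalityError(f"unknown modality {self.modality!r}")
        for attr in ("titration_injections", "transition_injections",
                     "tablets_per_day", "annual_evaluations_per_year"):
            if getattr(self, attr) < 0:
                raise InvalidParameterError(f"{attr} must be >= 0")
        if self.modality == "SCIT":
            if self.maintenance_interval_weeks <= 0:
                raise InvalidParameterError(
                    "SCIT scheme requires maintenance_interval_weeks > 0")
            if len(self.transition_intervals_weeks) != self.transition_injections:
                raise InvalidParameterError(
                    "transition_intervals_weeks must list one offset per "
                    "transition injection")
        else:
            if (self.titration_injections or self.transition_injections):
                raise InvalidParameterError("SLIT scheme must have zero injections")


#: Conventional initial therapy: 15 weekly up-dosing injections, transition
#: doses 2 and a further 4 weeks later, then 6-weekly maintenance.
CONVENTIONAL = DosingScheme(
    name="conventional", modality="SCIT",
    titration_injections=15, titration_span_weeks=15,
    transition_injections=2, transition_intervals_weeks=(2.0, 4.0),
    maintenance_interval_weeks=6.0,
)

#: Accelerated (hospital) up-dosing: 8 injections over 16 weeks; the published
#: regimen definition fixes the first-year course at 12 injections in total,
#: i.e. two maintenance injections after the two transition doses.
ACCELERATED = DosingScheme(
    name="accelerated", modality="SCIT",
    titration_injections=8, titration_span_weeks=16,
    transition_injections=2, transition_intervals_weeks=(2.0, 4.0),
    maintenance_interval_weeks=6.0,
    first_year_maintenance=2,
)

#: Daily SLIT tablet with a supervised first dose and one annual evaluation.
SLIT_DAILY = DosingScheme(
    name="slit-daily", modality="SLIT",
    tablets_per_day=1.0, annual_evaluations_per_year=1,
)

BUILTIN_SCHEMES = {s.name: s for s in (CONVENTIONAL, ACCELERATED, SLIT_DAILY)}


@dataclass(frozen=True)
class VisitYear:
    """Healthcare-professional interactions in one treatment year.

    ``annual_control`` counts stand-alone annual evaluation visits (SLIT);
    ``control_relabel`` counts maintenance visits re-billed at the annual
    control tariff in the specialist setting (SCIT) — these are already
    included in ``maintenance`` and do not add to the total.
    """

    year_index: int
    first_dose: float = 0.0
    titration: float = 0.0
    transition: float = 0.0
    maintenance: float = 0.0
    annual_control: float = 0.0
    control_relabel: float = 0.0

    def __post_init__(self) -> None:
        for attr in ("first_dose", "titration", "transition", "maintenance",
                     "annual_control", "control_relabel"):
            if getattr(self, attr) < 0:
                raise InvalidParameterError(f"{attr} must be >= 0")
        if self.control_relabel > self.maintenance:
            raise InvalidParameterError(
                "control_relabel cannot exceed the maintenance visit count")

    @property
    def total(self) -> float:
        return (self.first_dose + self.titration + self.transition
                + self.maintenance + self.annual_control)

    @property
    def initiation_visits(self) -> float:
        """Visits in the treatment-initiation phase (up-dosing + transition,
        or the supervised SLIT first dose)."""
        return self.first_dose + self.titration + self.transition

    @property
    def maintenance_phase_visits(self) -> float:
        return self.maintenance + self.annual_control


@dataclass(frozen=True)
class VisitSchedule:
    modality: Modality
    years: tuple[VisitYear, ...]

    def __post_init__(self) -> None:
        for i, year in enumerate(self.years, start=1):
            if year.year_index != i:
                raise InvalidParameterError("year_index must be contiguous from 1")

    @property
    def horizon_years(self) -> int:
        return len(self.years)

    @property
    def total_visits(self) -> float:
        return sum(y.total for y in self.years)


def maintenance_visits_per_year(interval_weeks: float,
                                weeks_per_year: float = WEEKS_PER_YEAR) -> float:
    """Average maintenance visits per year, half-up rounded to one decimal.

    With the standard 6-weekly interval this is the conventional 8.7
    visits/year figure carried through all costing.
    """
    if interval_weeks <= 0:
        raise InvalidParameterError("interval_weeks must be positive")
    return round_half_up(weeks_per_year / interval_weeks, 1)


def _packed_first_year_maintenance(scheme: DosingScheme,
                                   weeks_per_year: float) -> int:
    """Maintenance injections fitting in the remainder of the first 52-week
    year, after titration and the transition offsets, at the maintenance
    interval."""
    consumed = scheme.titration_span_weeks + sum(scheme.transition_intervals_weeks)
    remaining = weeks_per_year - consumed
    if remaining <= 0:
        return 0
    return int(math.floor(remaining / scheme.maintenance_interval_weeks))


def build_scit_visit_schedule(scheme: DosingScheme, horizon_years: int,
                              annual_control_start_year: int = 1,
                              weeks_per_year: float = WEEKS_PER_YEAR,
                              ) -> VisitSchedule:
    """Per-year SCIT visit schedule over the horizon.

    Year 1 holds the full titration and transition course plus the maintenance
    injections packed into the rest of the 52-week year; subsequent years hold
    the steady-state maintenance rate. From ``annual_control_start_year``
    onward, one maintenance visit per year is flagged for re-billing at the
    specialist annual-control tariff.
    """
    if scheme.modality != "SCIT":
        raise ModalityError("build_scit_visit_schedule requires a SCIT scheme")
    if horizon_years < 1:
        raise InvalidParameterError("horizon_years must be >= 1")

    if scheme.first_year_maintenance is not None:
        year1_maintenance = scheme.first_year_maintenance
    else:
        year1_maintenance = _packed_first_year_maintenance(scheme, weeks_per_year)
    steady_state = maintenance_visits_per_year(
        scheme.maintenance_interval_weeks, weeks_per_year)

    years = []
    for y in range(1, horizon_years + 1):
        maintenance = year1_maintenance if y == 1 else steady_state
        relabel = 1.0 if (y >= annual_control_start_year and maintenance >= 1) else 0.0
        years.append(VisitYear(
            year_index=y,
            titration=scheme.titration_injections if y == 1 else 0.0,
            transition=scheme.transition_injections if y == 1 else 0.0,
            maintenance=maintenance,
            control_relabel=relabel,
        ))
    return VisitSchedule(modality="SCIT", years=tuple(years))


def build_slit_visit_schedule(scheme: DosingScheme,
                              horizon_years: int) -> VisitSchedule:
    """Per-year SLIT visit schedule: one supervised first dose in year 1 plus
    one annual evaluation in every treatment year (total = 1 + horizon with
    the default single evaluation per year)."""
    if scheme.modality != "SLIT":
        raise ModalityError("build_slit_visit_schedule requires a SLIT scheme")
    if horizon_years < 1:
        raise InvalidParameterError("horizon_years must be >= 1")
    years = tuple(
        VisitYear(
            year_index=y,
            first_dose=1.0 if y == 1 else 0.0,
            annual_control=float(scheme.annual_evaluations_per_year),
        )
        for y in range(1, horizon_years + 1)
    )
    return VisitSchedule(modality="SLIT", years=years)


@dataclass(frozen=True)
class ConsumptionModel:
    """How SCIT maintenance-phase drug volume is derived.

    ``implied`` (default): a configured total maintenance volume over the
    horizon, spread across years in proportion to post-titration injections.
    ``mechanistic``: one vial-volume per post-titration injection, with the
    unused remainder of the last titration vial credited against year 1.
    """

    kind: Literal["implied", "mechanistic"] = "implied"
    total_maintenance_volume_ml: float = 19.0
    ml_per_injection: float = 1.0
    titration_vial_leftover_ml: float = 2.5

    def __post_init__(self) -> None:
        if self.kind not in ("implied", "mechanistic"):
            raise InvalidParameterError(f"unknown consumption model {self.kind!r}")
        for attr in ("total_maintenance_volume_ml", "ml_per_injection",
                     "titration_vial_leftover_ml"):
            if getattr(self, attr) < 0:
                raise InvalidParameterError(f"{attr} must be >= 0")


@dataclass(frozen=True)
class DrugConsumption:
    """Per-year drug quantities for one arm (the other arm's fields are zero)."""

    modality: Modality
    tablets: tuple[float, ...]
    titration_packs: tuple[float, ...]
    maintenance_volume_ml: tuple[float, ...]

    @property
    def total_tablets(self) -> float:
        return sum(self.tablets)

    @property
    def total_maintenance_volume_ml(self) -> float:
        return sum(self.maintenance_volume_ml)


def _post_titration_injections(schedule: VisitSchedule) -> list[float]:
    return [y.transition + y.maintenance for y in schedule.years]


def drug_consumption(schedule: VisitSchedule, scheme: DosingScheme,
                     consumption_model: ConsumptionModel | None = None,
                     days_per_treatment_year: float = DAYS_PER_TREATMENT_YEAR,
                     ) -> DrugConsumption:
    """Per-year drug quantities implied by a visit schedule.

    SLIT consumes ``tablets_per_day`` over a 52-week (364-day) treatment year.
    SCIT consumes one titration pack during year-1 up-dosing, then maintenance
    vial volume per the chosen consumption model.
    """
    if schedule.modality != scheme.modality:
        raise ModalityError(
            f"schedule modality {schedule.modality} != scheme {scheme.modality}")
    model = consumption_model or ConsumptionModel()
    n = schedule.horizon_years
    zeros = (0.0,) * n

    if scheme.modality == "SLIT":
        tablets = tuple(scheme.tablets_per_day * days_per_treatment_year
                        for _ in range(n))
        return DrugConsumption("SLIT", tablets, zeros, zeros)

    packs = tuple((1.0 if (y == 0 and scheme.titration_injections > 0) else 0.0)
                  for y in range(n))
    post = _post_titration_injections(schedule)
    if model.kind == "implied":
        weight_sum = sum(post)
        if weight_sum > 0:
            volume = tuple(model.total_maintenance_volume_ml * w / weight_sum
                           for w in post)
        else:
            volume = zeros
    else:  # mechanistic
        raw = [w * model.ml_per_injection for w in post]
        if raw:
            raw[0] = max(0.0, raw[0] - model.titration_vial_leftover_ml)
        volume = tuple(raw)
    return DrugConsumption("SCIT", zeros, packs, volume)
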