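"""Arm assembly: schedules -> direct + indirect costs -> adherence -> totals.

The engine composes the other modules into per-arm cost breakdowns over the
analysis horizon, applies discounting and adherence, and compares the two
arms. All internal amounts are unrounded DKK; Euro equivalents and half-up
rounding belong to the reporting layer.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .direct_costing import (SETTINGS, CareSettingDistribution, CostBreakdown,
                             PackPricing, PhaseCosts, Setting, SettingArmCosts,
                             SettingYearCosts, TariffSet, YearCosts,
                             mix_settings, scit_acquisition_cost,
                             setting_visit_cost, slit_acquisition_cost)
from .errors import (ConfigurationError, InvalidParameterError,
                     ScenarioOverrideError)
from .indirect_costing import (DiseaseBurdenParams, HumanCapitalParams,
                               SymptomMedication, disease_burden_cost,
                               per_visit_loss, symptom_med_cost)
from .rounding import round_half_up
from .schedules import (DAYS_PER_TREATMENT_YEAR, WEEKS_PER_YEAR,
                        ConsumptionModel, DosingScheme, Modality,
                        VisitSchedule, build_scit_visit_schedule,
                        build_slit_visit_schedule, drug_consumption)

#: Cost categories that adherence scaling may apply to.
ADHERENCE_CATEGORIES = ("acquisition", "hcp_interactions", "visit_indirect")


@dataclass(frozen=True)
class AdherenceScenario:
    """Proportion of patients adherent per arm, and the cost categories that
    are only incurred by adherent patients."""

    name: str
    slit_adherence: float = 1.0
    scit_adherence: float = 1.0
    applies_to: tuple[str, ...] = ADHERENCE_CATEGORIES

    def __post_init__(self) -> None:
        for attr in ("slit_adherence", "scit_adherence"):
            if not (0.0 <= getattr(self, attr) <= 1.0):
                raise InvalidParameterError(f"{attr} must lie in [0, 1]")
        unknown = set(self.applies_to) - set(ADHERENCE_CATEGORIES)
        if unknown:
            raise ConfigurationError(f"unknown adherence categories {unknown}")

    def fraction(self, modality: Modality) -> float:
        return self.slit_adherence if modality == "SLIT" else self.scit_adherence


FULL_ADHERENCE = AdherenceScenario(name="full", slit_adherence=1.0,
                                   scit_adherence=1.0)


@dataclass(frozen=True)
class AnalysisConfig:
    """Complete parameterization of one cost-minimization analysis."""

    horizon_years: int
    discount_rate: float
    exchange_rate_eur_per_dkk: float
    scit_scheme: DosingScheme
    slit_scheme: DosingScheme
    tariffs: TariffSet
    slit_pricing: PackPricing
    scit_titration_pricing: PackPricing
    scit_maintenance_pricing: PackPricing
    care_settings: Mapping[Modality, CareSettingDistribution]
    human_capital: HumanCapitalParams
    disease_burden: DiseaseBurdenParams
    symptom_medications: tuple[SymptomMedication, ...]
    consumption_model: ConsumptionModel = ConsumptionModel()
    adherence: AdherenceScenario = FULL_ADHERENCE
    scit_scheme_by_setting: Mapping[Setting, DosingScheme] = field(
        default_factory=dict)
    include_visit_indirect: bool = True
    include_disease_burden: bool = False
    include_symptom_meds: bool = False
    annual_control_start_year: int = 1
    drg_covers_scit_acquisition: bool = True
    weeks_per_year: float = WEEKS_PER_YEAR
    days_per_treatment_year: float = DAYS_PER_TREATMENT_YEAR

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise InvalidParameterError("horizon_years must be >= 1")
        if self.discount_rate < 0:
            raise InvalidParameterError("discount_rate must be >= 0")
        if self.exchange_rate_eur_per_dkk <= 0:
            raise InvalidParameterError("exchange rate must be > 0")
        if set(self.care_settings) != {"SCIT", "SLIT"}:
            raise ConfigurationError(
                "care_settings must map both 'SCIT' and 'SLIT'")


def discount(annual_costs: Sequence[float], rate: float) -> float:
    """Present value of a yearly cost stream, year 1 undiscounted."""
    if rate < 0:
        raise InvalidParameterError("discount rate must be >= 0")
    return sum(cost / (1.0 + rate) ** (year - 1)
               for year, cost in enumerate(annual_costs, start=1))


def to_eur(dkk: float, rate: float) -> float:
    """Convert DKK to EUR at the configured rate (unrounded)."""
    if rate <= 0:
        raise InvalidParameterError("exchange rate must be > 0")
    return dkk * rate


def _scit_scheme_for_setting(config: AnalysisConfig,
                             setting: Setting) -> DosingScheme:
    return config.scit_scheme_by_setting.get(setting, config.scit_scheme)


def _setting_arm_costs(config: AnalysisConfig, modality: Modality,
                       setting: Setting,
                       schedule: VisitSchedule,
                       scheme: DosingScheme) -> SettingArmCosts:
    """Costs of the whole course delivered 100% in one setting."""
    consumption = drug_consumption(
        schedule, scheme, config.consumption_model,
        days_per_treatment_year=config.days_per_treatment_year)
    visit_costs = setting_visit_cost(schedule, setting, config.tariffs)
    loss = per_visit_loss(config.human_capital)

    if modality == "SLIT":
        tablets = slit_acquisition_cost(consumption, config.slit_pricing)
        # SLIT acquisition is setting-independent; booked in the maintenance
        # phase (daily home use), so any valid distribution weights it fully.
        medication = [PhaseCosts(0.0, cost) for cost in tablets]
    else:
        medication = [PhaseCosts(*pair) for pair in scit_acquisition_cost(
            consumption, config.scit_titration_pricing,
            config.scit_maintenance_pricing, setting,
            drg_covers_acquisition=config.drg_covers_scit_acquisition)]

    years = []
    for year, visit_cost, med in zip(schedule.years, visit_costs, medication):
        visits = PhaseCosts(year.initiation_visits, year.maintenance_phase_visits)
        indirect = PhaseCosts(visits.initiation * loss, visits.maintenance * loss)
        years.append(SettingYearCosts(visit_cost=visit_cost, medication=med,
                                      indirect=indirect, visits=visits))
    return SettingArmCosts(modality=modality, setting=setting,
                           years=tuple(years))


def apply_adherence(breakdown: CostBreakdown, scenario: AdherenceScenario,
                    modality: Modality) -> CostBreakdown:
    """Scale the categories only incurred by adherent patients."""
    a = scenario.fraction(modality)
    scale_acq = a if "acquisition" in scenario.applies_to else 1.0
    scale_hcp = a if "hcp_interactions" in scenario.applies_to else 1.0
    scale_ind = a if "visit_indirect" in scenario.applies_to else 1.0
    years = tuple(
        replace(y,
                medication=y.medication * scale_acq,
                specialist=y.specialist * scale_hcp,
                hospital=y.hospital * scale_hcp,
                gp=y.gp * scale_hcp,
                indirect_visits=y.indirect_visits * scale_ind)
        for y in breakdown.years)
    return replace(breakdown, years=years)


def run_arm(config: AnalysisConfig, modality: Modality) -> CostBreakdown:
    """Per-year cost breakdown for one arm (undiscounted DKK).

    Deterministic: identical configs yield identical breakdowns.
    """
    if modality == "SLIT":
        schedule = build_slit_visit_schedule(config.slit_scheme,
                                             config.horizon_years)
        per_setting = {
            setting: _setting_arm_costs(config, modality, setting, schedule,
                                        config.slit_scheme)
            for setting in SETTINGS}
    elif modality == "SCIT":
        per_setting = {}
        for setting in SETTINGS:
            scheme = _scit_scheme_for_setting(config, setting)
            schedule = build_scit_visit_schedule(
                scheme, config.horizon_years,
                annual_control_start_year=config.annual_control_start_year,
                weeks_per_year=config.weeks_per_year)
            per_setting[setting] = _setting_arm_costs(
                config, modality, setting, schedule, scheme)
    else:
        raise ConfigurationError(f"unknown modality {modality!r}")

    breakdown = mix_settings(per_setting, config.care_settings[modality])

    extra = {}
    if not config.include_visit_indirect:
        extra["indirect_visits"] = 0.0
    if config.include_disease_burden:
        db = config.disease_burden
        # Equal-in-both-arms convention: active-treatment burden levels in
        # both arms; with the flag off, placebo levels apply instead.
        extra["indirect_disease"] = disease_burden_cost(
            db, config.human_capital, treated=db.apply_equally_to_both_arms)
    if config.include_symptom_meds:
        extra["symptom_meds"] = symptom_med_cost(config.symptom_medications)

    if extra:
        breakdown = replace(breakdown, years=tuple(
            replace(y, **extra) for y in breakdown.years))
    return apply_adherence(breakdown, config.adherence, modality)


COMPONENTS = ("medication", "specialist", "hospital", "gp", "symptom_meds",
              "direct", "indirect_visits", "indirect_disease", "indirect",
              "total")


def component_totals(breakdown: CostBreakdown, rate: float) -> dict[str, float]:
    """Discounted horizon totals per reporting component (DKK)."""
    return {c: discount(breakdown.component_years(c), rate) for c in COMPONENTS}


@dataclass(frozen=True)
class ComparisonResult:
    """Both arms' breakdowns and totals, with componentwise differences."""

    config: AnalysisConfig
    scit: CostBreakdown
    slit: CostBreakdown
    scit_totals: dict[str, float]
    slit_totals: dict[str, float]

    @property
    def difference(self) -> dict[str, float]:
        """SLIT minus SCIT per component (negative = saving with SLIT)."""
        return {c: self.slit_totals[c] - self.scit_totals[c] for c in COMPONENTS}

    def eur(self, totals: Mapping[str, float]) -> dict[str, float]:
        rate = self.config.exchange_rate_eur_per_dkk
        return {c: to_eur(v, rate) for c, v in totals.items()}

    @property
    def percent_saving(self) -> float:
        """Saving with SLIT as a percentage of the SCIT (comparator) total."""
        return -self.difference["total"] / self.scit_totals["total"] * 100.0


def compare(config: AnalysisConfig) -> ComparisonResult:
    """Run both arms and compare them componentwise."""
    scit = run_arm(config, "SCIT")
    slit = run_arm(config, "SLIT")
    rate = config.discount_rate
    return ComparisonResult(
        config=config, scit=scit, slit=slit,
        scit_totals=component_totals(scit, rate),
        slit_totals=component_totals(slit, rate),
    )


def _resolve_parent(obj, path_parts: Sequence[str], full_path: str):
    for part in path_parts:
        if dataclasses.is_dataclass(obj):
            if part not in {f.name for f in dataclasses.fields(obj)}:
                raise ScenarioOverrideError(
                    f"override path {full_path!r}: no field {part!r} on "
                    f"{type(obj).__name__}")
            obj = getattr(obj, part)
        elif isinstance(obj, Mapping):
            if part not in obj:
                raise ScenarioOverrideError(
                    f"override path {full_path!r}: no key {part!r}")
            obj = obj[part]
        else:
            raise ScenarioOverrideError(
                f"override path {full_path!r}: cannot descend into "
                f"{type(obj).__name__}")
    return obj


def _set_in(obj, parts: Sequence[str], value, full_path: str):
    head, *rest = parts
    if dataclasses.is_dataclass(obj):
        if head not in {f.name for f in dataclasses.fields(obj)}:
            raise ScenarioOverrideError(
                f"override path {full_path!r}: no field {head!r} on "
                f"{type(obj).__name__}")
        new = value if not rest else _set_in(getattr(obj, head), rest, value,
                                             full_path)
        return dataclasses.replace(obj, **{head: new})
    if isinstance(obj, Mapping):
        if head not in obj and rest:
            raise ScenarioOverrideError(
                f"override path {full_path!r}: no key {head!r}")
        updated = dict(obj)
        updated[head] = value if not rest else _set_in(obj[head], rest, value,
                                                       full_path)
        return updated
    raise ScenarioOverrideError(
        f"override path {full_path!r}: cannot descend into {type(obj).__name__}")


def with_overrides(config: AnalysisConfig,
                   overrides: Mapping[str, object]) -> AnalysisConfig:
    """Return a copy of ``config`` with dotted-path overrides applied.

    Paths resolve through nested dataclass fields and mapping keys, e.g.
    ``"discount_rate"``, ``"human_capital.hours_lost_per_visit"`` or
    ``"care_settings.SCIT"``.
    """
    for path, value in overrides.items():
        config = _set_in(config, path.split("."), value, path)
    return config
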