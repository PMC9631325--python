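"""Tariff-based microcosting of visits and drug acquisition, per care setting.

Each healthcare-professional interaction is priced with a flat per-visit
tariff that depends on the care setting (general practice, ENT allergy
specialist, or hospital). The hospital diagnosis-related-group (DRG) tariff
bundles the SCIT drug cost, so SCIT acquisition is only a separate cost in
the GP and specialist settings. Costs per setting are combined with the
care-setting distribution, with separate weights for the initiation and the
maintenance phase of treatment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

from .errors import ConfigurationError, InvalidParameterError, ModalityError
from .schedules import DrugConsumption, Modality, VisitSchedule

Setting = Literal["GP", "specialist", "hospital"]
SETTINGS: tuple[Setting, ...] = ("GP", "specialist", "hospital")

# Tariff codes (Danish tariff-card / DRG identifiers)
GP_CONSULTATION = "0101"
HOSPITAL_ADMINISTRATION = "49PR03"
SPECIALIST_SLIT_FIRST_DOSE = "0144"
SPECIALIST_SLIT_CONTROL = "2027"
SPECIALIST_SCIT_DOSE = "0143"
SPECIALIST_SCIT_CONTROL = "2026"


@dataclass(frozen=True)
class Tariff:
    setting: Setting
    code: str
    description: str
    unit_cost: float

    def __post_init__(self) -> None:
        if self.unit_cost < 0:
            raise InvalidParameterError("unit_cost must be >= 0")


class TariffSet:
    """Lookup table of per-visit tariffs keyed by (setting, code)."""

    def __init__(self, tariffs: Iterable[Tariff]):
        self._by_key: dict[tuple[str, str], Tariff] = {}
        for t in tariffs:
            key = (t.setting, t.code)
            if key in self._by_key:
                raise ConfigurationError(f"duplicate tariff {key}")
            self._by_key[key] = t

    def cost(self, setting: Setting, code: str) -> float:
        try:
            return self._by_key[(setting, code)].unit_cost
        except KeyError:
            raise ConfigurationError(
                f"missing tariff code {code!r} for setting {setting!r}") from None

    def __iter__(self):
        return iter(self._by_key.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, TariffSet) and self._by_key == other._by_key


@dataclass(frozen=True)
class PackPricing:
    """Drug pack price with derived per-unit price."""

    product: str
    pack_price: float
    pack_size: float
    unit: Literal["tablets", "ml", "pack"]

    def __post_init__(self) -> None:
        if self.pack_price <= 0 or self.pack_size <= 0:
            raise InvalidParameterError("pack_price and pack_size must be > 0")

    @property
    def per_unit_price(self) -> float:
        return self.pack_price / self.pack_size


@dataclass(frozen=True)
class CareSettingDistribution:
    """Proportions of care delivered in each setting, by treatment phase."""

    initiation: Mapping[Setting, float]
    maintenance: Mapping[Setting, float]

    def __post_init__(self) -> None:
        for phase_name, phase in (("initiation", self.initiation),
                                  ("maintenance", self.maintenance)):
            if set(phase) != set(SETTINGS):
                raise ConfigurationError(
                    f"{phase_name} proportions must cover exactly {SETTINGS}")
            for setting, p in phase.items():
                if not (0.0 <= p <= 1.0):
                    raise InvalidParameterError(
                        f"{phase_name}[{setting}] proportion outside [0, 1]")
            if abs(sum(phase.values()) - 1.0) > 1e-9:
                raise InvalidParameterError(
                    f"{phase_name} proportions must sum to 1")

    @classmethod
    def single_phase(cls, gp: float, specialist: float,
                     hospital: float) -> "CareSettingDistribution":
        """One distribution applied to both treatment phases."""
        phase = {"GP": gp, "specialist": specialist, "hospital": hospital}
        return cls(initiation=dict(phase), maintenance=dict(phase))

    @classmethod
    def degenerate(cls, setting: Setting) -> "CareSettingDistribution":
        return cls.single_phase(*(1.0 if s == setting else 0.0 for s in SETTINGS))


@dataclass(frozen=True)
class YearCosts:
    """One year of per-patient costs, split into reporting components (DKK)."""

    medication: float = 0.0
    specialist: float = 0.0
    hospital: float = 0.0
    gp: float = 0.0
    indirect_visits: float = 0.0
    indirect_disease: float = 0.0
    symptom_meds: float = 0.0

    @property
    def indirect(self) -> float:
        return self.indirect_visits + self.indirect_disease

    @property
    def direct(self) -> float:
        return (self.medication + self.specialist + self.hospital + self.gp
                + self.symptom_meds)

    @property
    def total(self) -> float:
        return self.direct + self.indirect


@dataclass(frozen=True)
class CostBreakdown:
    """Per-year cost components for one arm (undiscounted DKK)."""

    modality: Modality
    years: tuple[YearCosts, ...]

    def component_years(self, component: str) -> tuple[float, ...]:
        return tuple(getattr(y, component) for y in self.years)

    def component_total(self, component: str) -> float:
        return sum(self.component_years(component))


@dataclass(frozen=True)
class PhaseCosts:
    """Initiation/maintenance split of one quantity in one year."""

    initiation: float = 0.0
    maintenance: float = 0.0

    @property
    def total(self) -> float:
        return self.initiation + self.maintenance


@dataclass(frozen=True)
class SettingYearCosts:
    """One year of costs assuming 100% of care in a single setting."""

    visit_cost: PhaseCosts
    medication: PhaseCosts
    indirect: PhaseCosts
    visits: PhaseCosts


@dataclass(frozen=True)
class SettingArmCosts:
    """Full-horizon costs for one arm delivered entirely in one setting."""

    modality: Modality
    setting: Setting
    years: tuple[SettingYearCosts, ...]


def slit_acquisition_cost(consumption: DrugConsumption,
                          pricing: PackPricing) -> list[float]:
    """Per-year SLIT tablet acquisition cost (fractional packs allowed)."""
    if consumption.modality != "SLIT":
        raise ModalityError("slit_acquisition_cost requires SLIT consumption")
    if pricing.unit != "tablets":
        raise ConfigurationError(
            f"SLIT pricing must be per tablet, got unit {pricing.unit!r}")
    return [t * pricing.per_unit_price for t in consumption.tablets]


def scit_acquisition_cost(consumption: DrugConsumption,
                          titration_pricing: PackPricing,
                          maintenance_pricing: PackPricing,
                          setting: Setting,
                          drg_covers_acquisition: bool = True,
                          ) -> list[tuple[float, float]]:
    """Per-year SCIT acquisition cost as (titration, maintenance) pairs.

    In the hospital setting the DRG tariff covers the drug, so acquisition is
    zero there unless ``drg_covers_acquisition`` is disabled (used by the
    published all-hospital sensitivity scenario, which retained the pharmacy
    acquisition cost).
    """
    if consumption.modality != "SCIT":
        raise ModalityError("scit_acquisition_cost requires SCIT consumption")
    if maintenance_pricing.unit != "ml":
        raise ConfigurationError(
            f"SCIT maintenance pricing must be per ml, got {maintenance_pricing.unit!r}")
    if setting == "hospital" and drg_covers_acquisition:
        return [(0.0, 0.0) for _ in consumption.titration_packs]
    return [
        (packs * titration_pricing.per_unit_price,
         ml * maintenance_pricing.per_unit_price)
        for packs, ml in zip(consumption.titration_packs,
                             consumption.maintenance_volume_ml)
    ]


def setting_visit_cost(schedule: VisitSchedule, setting: Setting,
                       tariffs: TariffSet) -> list[PhaseCosts]:
    """Per-year visit cost in one care setting, split by treatment phase.

    GP and hospital bill a flat tariff per visit. The specialist setting uses
    distinct tariff codes: SLIT first dose (0144) and annual evaluation
    (2027); SCIT injection (0143) with one maintenance visit per year
    re-billed as the annual control (2026).
    """
    out: list[PhaseCosts] = []
    for year in schedule.years:
        if setting == "GP":
            unit = tariffs.cost("GP", GP_CONSULTATION)
            out.append(PhaseCosts(year.initiation_visits * unit,
                                  year.maintenance_phase_visits * unit))
        elif setting == "hospital":
            unit = tariffs.cost("hospital", HOSPITAL_ADMINISTRATION)
            out.append(PhaseCosts(year.initiation_visits * unit,
                                  year.maintenance_phase_visits * unit))
        elif setting == "specialist":
            if schedule.modality == "SLIT":
                init = year.first_dose * tariffs.cost(
                    "specialist", SPECIALIST_SLIT_FIRST_DOSE)
                maint = year.annual_control * tariffs.cost(
                    "specialist", SPECIALIST_SLIT_CONTROL)
            else:
                dose = tariffs.cost("specialist", SPECIALIST_SCIT_DOSE)
                control = tariffs.cost("specialist", SPECIALIST_SCIT_CONTROL)
                init = (year.titration + year.transition) * dose
                maint = ((year.maintenance - year.control_relabel) * dose
                         + year.control_relabel * control)
            out.append(PhaseCosts(init, maint))
        else:
            raise ConfigurationError(f"unknown care setting {setting!r}")
    return out


def mix_settings(per_setting: Mapping[Setting, SettingArmCosts],
                 dist: CareSettingDistribution) -> CostBreakdown:
    """Weight per-setting costs by the care-setting distribution.

    Initiation-phase quantities are weighted with the initiation proportions
    and maintenance-phase quantities with the maintenance proportions. The
    DRG rule emerges naturally: the hospital column carries zero SCIT
    medication, so the mixed medication cost is weighted by the proportion of
    care outside hospital.
    """
    if set(per_setting) != set(SETTINGS):
        raise ConfigurationError(
            f"per_setting must cover exactly {SETTINGS}")
    horizons = {len(c.years) for c in per_setting.values()}
    if len(horizons) != 1:
        raise ConfigurationError("per-setting breakdowns must share the horizon")
    modalities = {c.modality for c in per_setting.values()}
    if len(modalities) != 1:
        raise ModalityError("per-setting breakdowns must share the modality")
    (modality,) = modalities
    (horizon,) = horizons

    p_init = dist.initiation
    p_maint = dist.maintenance
    component_by_setting = {"GP": "gp", "specialist": "specialist",
                            "hospital": "hospital"}

    years = []
    for y in range(horizon):
        parts = {"medication": 0.0, "gp": 0.0, "specialist": 0.0,
                 "hospital": 0.0, "indirect_visits": 0.0}
        for setting in SETTINGS:
            sy = per_setting[setting].years[y]
            comp = component_by_setting[setting]
            parts[comp] += (p_init[setting] * sy.visit_cost.initiation
                            + p_maint[setting] * sy.visit_cost.maintenance)
            parts["medication"] += (p_init[setting] * sy.medication.initiation
                                    + p_maint[setting] * sy.medication.maintenance)
            parts["indirect_visits"] += (p_init[setting] * sy.indirect.initiation
                                         + p_maint[setting] * sy.indirect.maintenance)
        years.append(YearCosts(**parts))
    return CostBreakdown(modality=modality, years=tuple(years))
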