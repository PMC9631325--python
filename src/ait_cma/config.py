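"""YAML serialization of analysis configurations.

The bundled ``data/default_config.yaml`` mirrors :func:`ait_cma.defaults.
default_config` exactly; ``load_config()`` with no path returns that base
case. Dosing schemes may be given inline or by built-in name
("conventional", "accelerated", "slit-daily").
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .direct_costing import (CareSettingDistribution, PackPricing, Tariff,
                             TariffSet)
from .engine import AdherenceScenario, AnalysisConfig
from .errors import ConfigurationError
from .indirect_costing import (DiseaseBurdenParams, HumanCapitalParams,
                               SymptomMedication)
from .schedules import BUILTIN_SCHEMES, ConsumptionModel, DosingScheme


def _scheme_to_obj(scheme: DosingScheme) -> Any:
    if BUILTIN_SCHEMES.get(scheme.name) == scheme:
        return scheme.name
    d = dataclasses.asdict(scheme)
    d["transition_intervals_weeks"] = list(scheme.transition_intervals_weeks)
    return d


def _scheme_from_obj(obj: Any) -> DosingScheme:
    if isinstance(obj, str):
        try:
            return BUILTIN_SCHEMES[obj]
        except KeyError:
            raise ConfigurationError(f"unknown built-in scheme {obj!r}") from None
    obj = dict(obj)
    obj["transition_intervals_weeks"] = tuple(
        obj.get("transition_intervals_weeks", ()))
    return DosingScheme(**obj)


def _dist_to_obj(dist: CareSettingDistribution) -> dict:
    return {"initiation": dict(dist.initiation),
            "maintenance": dict(dist.maintenance)}


def config_to_dict(config: AnalysisConfig) -> dict:
    return {
        "horizon_years": config.horizon_years,
        "discount_rate": config.discount_rate,
        "exchange_rate_eur_per_dkk": config.exchange_rate_eur_per_dkk,
        "schemes": {
            "SCIT": _scheme_to_obj(config.scit_scheme),
            "SLIT": _scheme_to_obj(config.slit_scheme),
            "SCIT_by_setting": {
                setting: _scheme_to_obj(scheme)
                for setting, scheme in config.scit_scheme_by_setting.items()},
        },
        "tariffs": [dataclasses.asdict(t) for t in config.tariffs],
        "pricing": {
            "slit": dataclasses.asdict(config.slit_pricing),
            "scit_titration": dataclasses.asdict(config.scit_titration_pricing),
            "scit_maintenance": dataclasses.asdict(
                config.scit_maintenance_pricing),
        },
        "care_settings": {m: _dist_to_obj(d)
                          for m, d in config.care_settings.items()},
        "human_capital": dataclasses.asdict(config.human_capital),
        "disease_burden": dataclasses.asdict(config.disease_burden),
        "symptom_medication": [dataclasses.asdict(m)
                               for m in config.symptom_medications],
        "consumption_model": dataclasses.asdict(config.consumption_model),
        "adherence": dataclasses.asdict(config.adherence),
        "flags": {
            "include_visit_indirect": config.include_visit_indirect,
            "include_disease_burden": config.include_disease_burden,
            "include_symptom_meds": config.include_symptom_meds,
            "annual_control_start_year": config.annual_control_start_year,
            "drg_covers_scit_acquisition": config.drg_covers_scit_acquisition,
        },
        "conventions": {
            "weeks_per_year": config.weeks_per_year,
            "days_per_treatment_year": config.days_per_treatment_year,
        },
    }


def config_from_dict(data: Mapping[str, Any]) -> AnalysisConfig:
    try:
        schemes = data["schemes"]
        adherence = dict(data["adherence"])
        adherence["applies_to"] = tuple(adherence.get("applies_to", ()))
        return AnalysisConfig(
            horizon_years=data["horizon_years"],
            discount_rate=data["discount_rate"],
            exchange_rate_eur_per_dkk=data["exchange_rate_eur_per_dkk"],
            scit_scheme=_scheme_from_obj(schemes["SCIT"]),
            slit_scheme=_scheme_from_obj(schemes["SLIT"]),
            scit_scheme_by_setting={
                setting: _scheme_from_obj(obj)
                for setting, obj in schemes.get("SCIT_by_setting",
                                                {}).items()},
            tariffs=TariffSet(Tariff(**t) for t in data["tariffs"]),
            slit_pricing=PackPricing(**data["pricing"]["slit"]),
            scit_titration_pricing=PackPricing(
                **data["pricing"]["scit_titration"]),
            scit_maintenance_pricing=PackPricing(
                **data["pricing"]["scit_maintenance"]),
            care_settings={
                m: CareSettingDistribution(**d)
                for m, d in data["care_settings"].items()},
            human_capital=HumanCapitalParams(**data["human_capital"]),
            disease_burden=DiseaseBurdenParams(**data["disease_burden"]),
            symptom_medications=tuple(
                SymptomMedication(**m) for m in data["symptom_medication"]),
            consumption_model=ConsumptionModel(**data["consumption_model"]),
            adherence=AdherenceScenario(**adherence),
            include_visit_indirect=data["flags"]["include_visit_indirect"],
            include_disease_burden=data["flags"]["include_disease_burden"],
            include_symptom_meds=data["flags"]["include_symptom_meds"],
            annual_control_start_year=data["flags"]["annual_control_start_year"],
            drg_covers_scit_acquisition=data["flags"][
                "drg_covers_scit_acquisition"],
            weeks_per_year=data["conventions"]["weeks_per_year"],
            days_per_treatment_year=data["conventions"][
                "days_per_treatment_year"],
        )
    except KeyError as exc:
        raise ConfigurationError(f"config is missing key {exc}") from exc


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config),
                                         sort_keys=False))


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load a config from YAML; with no path, the bundled base case."""
    if path is None:
        text = (resources.files("ait_cma") / "data" /
                "default_config.yaml").read_text()
    else:
        text = Path(path).read_text()
    return config_from_dict(yaml.safe_load(text))
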