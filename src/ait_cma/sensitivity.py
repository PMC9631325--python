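"""One-way sensitivity battery and report rendering.

Scenarios are declarative override sets (dotted config path -> value), so the
published battery is data rather than code and new scenarios need no code
changes. Reports render the base-case component table, the scenario table and
the annual cost profile as CSV, plus a JSON bundle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .defaults import ADHERENCE_ALLAM, ADHERENCE_LEMBERG, default_config
from .direct_costing import CareSettingDistribution, CostBreakdown
from .engine import (AnalysisConfig, ComparisonResult, compare, to_eur,
                     with_overrides)
from .rounding import round_half_up
from .schedules import ACCELERATED


@dataclass(frozen=True)
class ScenarioSpec:
    """A named one-way scenario: overrides applied to the base config."""

    name: str
    overrides: Mapping[str, object] = field(default_factory=dict)
    note: str = ""


def builtin_scenarios(base: AnalysisConfig | None = None) -> list[ScenarioSpec]:
    """The published scenario battery: base case plus twelve variants.

    The specialist-initiation scenario needs the base maintenance-phase
    distribution, so the battery is constructed relative to ``base``
    (defaulting to the bundled base case).
    """
    base = base or default_config()

    def single(setting: str) -> dict[str, object]:
        dist = CareSettingDistribution.degenerate(setting)
        return {"care_settings": {"SCIT": dist, "SLIT": dist}}

    specialist_initiation = {
        "care_settings": {
            modality: CareSettingDistribution(
                initiation={"GP": 0.0, "specialist": 1.0, "hospital": 0.0},
                maintenance=dict(base.care_settings[modality].maintenance))
            for modality in ("SCIT", "SLIT")}
    }

    hospital_only = single("hospital")
    # The published all-hospital scenario retained the pharmacy acquisition
    # cost of SCIT despite the DRG bundling rule used in the base case.
    hospital_only["drg_covers_scit_acquisition"] = False

    return [
        ScenarioSpec("Base case"),
        ScenarioSpec("3% discount rate", {"discount_rate": 0.03}),
        ScenarioSpec("5% discount rate", {"discount_rate": 0.05}),
        ScenarioSpec("No indirect costs", {"include_visit_indirect": False}),
        ScenarioSpec(
            "Include disease-related absenteeism and presenteeism "
            "(equal in both arms)",
            {"include_disease_burden": True},
            note="adds the same pollen-season burden to both arms"),
        ScenarioSpec("Adherence in line with Allam et al.",
                     {"adherence": ADHERENCE_ALLAM}),
        ScenarioSpec("Adherence in line with Lemberg et al.",
                     {"adherence": ADHERENCE_LEMBERG}),
        ScenarioSpec(
            "All hospital-treated patients treated with accelerated "
            "SCIT up-dosing",
            {"scit_scheme_by_setting": {"hospital": ACCELERATED}}),
        ScenarioSpec("All patients treated by a GP", single("GP")),
        ScenarioSpec("All patients treated in the hospital setting",
                     hospital_only),
        ScenarioSpec("All patients treated by an ENT specialist",
                     single("specialist")),
        ScenarioSpec(
            "All treatment initiations in the ENT specialist setting",
            specialist_initiation,
            note="maintenance phase keeps the base-case setting split"),
        ScenarioSpec("Including symptom-relieving medication costs",
                     {"include_symptom_meds": True}),
    ]


@dataclass(frozen=True)
class SensitivityRow:
    scenario: ScenarioSpec
    result: ComparisonResult


@dataclass(frozen=True)
class SensitivityTable:
    """Ordered scenario results; EUR figures are always recomputed from DKK."""

    rows: tuple[SensitivityRow, ...]

    def to_frame(self) -> pd.DataFrame:
        records = []
        for row in self.rows:
            res = row.result
            rate = res.config.exchange_rate_eur_per_dkk
            scit = res.scit_totals["total"]
            slit = res.slit_totals["total"]
            records.append({
                "analysis": row.scenario.name,
                "scit_dkk": round_half_up(scit),
                "slit_dkk": round_half_up(slit),
                "difference_dkk": round_half_up(slit - scit),
                "scit_eur": round_half_up(to_eur(scit, rate)),
                "slit_eur": round_half_up(to_eur(slit, rate)),
                "difference_eur": round_half_up(to_eur(slit - scit, rate)),
            })
        return pd.DataFrame.from_records(records)


def run_sensitivity(config: AnalysisConfig,
                    scenarios: Sequence[ScenarioSpec] | None = None,
                    ) -> SensitivityTable:
    """Run each scenario's overrides against ``config``, in input order."""
    if scenarios is None:
        scenarios = builtin_scenarios(config)
    rows = tuple(
        SensitivityRow(scenario=s, result=compare(with_overrides(config,
                                                                 s.overrides)))
        for s in scenarios)
    return SensitivityTable(rows=rows)


_COMPONENT_ROWS = (
    ("Total direct cost", "direct"),
    ("Medication", "medication"),
    ("Allergy specialist", "specialist"),
    ("Hospital", "hospital"),
    ("GP", "gp"),
    ("Total indirect cost", "indirect"),
    ("Total cost", "total"),
)


def breakdown_frame(result: ComparisonResult) -> pd.DataFrame:
    """Base-case component table (DKK and EUR, both arms and difference)."""
    rate = result.config.exchange_rate_eur_per_dkk
    records = []
    for label, component in _COMPONENT_ROWS:
        scit = result.scit_totals[component]
        slit = result.slit_totals[component]
        records.append({
            "component": label,
            "scit_dkk": round_half_up(scit),
            "slit_dkk": round_half_up(slit),
            "difference_dkk": round_half_up(slit - scit),
            "scit_eur": round_half_up(to_eur(scit, rate)),
            "slit_eur": round_half_up(to_eur(slit, rate)),
            "difference_eur": round_half_up(to_eur(slit - scit, rate)),
        })
    return pd.DataFrame.from_records(records)


def annual_profile_frame(result: ComparisonResult) -> pd.DataFrame:
    """Per-year stacked component data (undiscounted DKK) for both arms."""
    records = []
    for arm, breakdown in (("SCIT", result.scit), ("SLIT", result.slit)):
        for i, year in enumerate(breakdown.years, start=1):
            records.append({
                "arm": arm, "year": i,
                "medication_dkk": year.medication,
                "hcp_interactions_dkk": year.specialist + year.hospital + year.gp,
                "indirect_dkk": year.indirect,
                "symptom_meds_dkk": year.symptom_meds,
                "total_dkk": year.total,
            })
    return pd.DataFrame.from_records(records)


def render_reports(out_dir: str | Path, result: ComparisonResult,
                   table: SensitivityTable) -> dict[str, Path]:
    """Write the component table, scenario table, annual profile and a JSON
    bundle under ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "table5": out / "table5.csv",
        "table6": out / "table6.csv",
        "annual_profile": out / "annual_profile.csv",
        "report": out / "report.json",
    }
    breakdown_frame(result).to_csv(paths["table5"], index=False)
    table.to_frame().to_csv(paths["table6"], index=False)
    annual_profile_frame(result).to_csv(paths["annual_profile"], index=False)
    bundle = {
        "base_case": breakdown_frame(result).to_dict(orient="records"),
        "scenarios": table.to_frame().to_dict(orient="records"),
        "annual_profile": annual_profile_frame(result).to_dict(orient="records"),
        "note": "care-setting distribution is calibrated, not published",
    }
    paths["report"].write_text(json.dumps(bundle, indent=2))
    return paths
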