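"""Randomized parameter-set generation and care-setting calibration.

``generate_config`` draws structurally valid analysis configurations for
property testing (every type invariant holds by construction). The
calibration routine back-solves the one unpublished base-case input — the
care-setting distribution — from published component costs by grid search on
the simplex with local refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .direct_costing import (SETTINGS, CareSettingDistribution, PackPricing,
                             Tariff, TariffSet)
from .defaults import (DEFAULT_SYMPTOM_MEDICATIONS, EXCHANGE_RATE_EUR_PER_DKK,
                       default_config)
from .direct_costing import (GP_CONSULTATION, HOSPITAL_ADMINISTRATION,
                             SPECIALIST_SCIT_CONTROL, SPECIALIST_SCIT_DOSE,
                             SPECIALIST_SLIT_CONTROL,
                             SPECIALIST_SLIT_FIRST_DOSE)
from .engine import AnalysisConfig, run_arm, with_overrides
from .errors import InvalidParameterError
from .indirect_costing import DiseaseBurdenParams, HumanCapitalParams
from .schedules import (CONVENTIONAL, SLIT_DAILY, ConsumptionModel,
                        DosingScheme, Modality)


@dataclass(frozen=True)
class GeneratorSpec:
    """Ranges for randomized but structurally valid parameter sets."""

    seed: int = 0
    tariff_range: tuple[float, float] = (50.0, 3000.0)
    pack_price_range: tuple[float, float] = (100.0, 5000.0)
    salary_range: tuple[float, float] = (150_000.0, 600_000.0)
    unemployment_range: tuple[float, float] = (0.0, 0.2)
    hours_lost_range: tuple[float, float] = (0.0, 8.0)
    titration_injections_range: tuple[int, int] = (4, 20)
    maintenance_interval_range: tuple[float, float] = (4.0, 10.0)
    horizon_range: tuple[int, int] = (1, 5)

    def __post_init__(self) -> None:
        for name in ("tariff_range", "pack_price_range", "salary_range",
                     "unemployment_range", "hours_lost_range",
                     "titration_injections_range",
                     "maintenance_interval_range", "horizon_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise InvalidParameterError(f"{name} is not well-ordered")


def _random_distribution(rng: np.random.Generator) -> CareSettingDistribution:
    def simplex() -> dict[str, float]:
        p = rng.dirichlet(np.ones(len(SETTINGS)))
        p = p / p.sum()  # exact simplex within float tolerance
        return dict(zip(SETTINGS, map(float, p)))

    return CareSettingDistribution(initiation=simplex(), maintenance=simplex())


def generate_config(spec: GeneratorSpec) -> AnalysisConfig:
    """A complete, schema-valid random config; identical seeds give identical
    configs."""
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform

    titration = int(rng.integers(*spec.titration_injections_range,
                                 endpoint=True))
    scit_scheme = DosingScheme(
        name=f"random-scit-{spec.seed}", modality="SCIT",
        titration_injections=titration,
        titration_span_weeks=float(titration),
        transition_injections=2, transition_intervals_weeks=(2.0, 4.0),
        maintenance_interval_weeks=float(u(*spec.maintenance_interval_range)),
    )
    tariffs = TariffSet([
        Tariff("specialist", SPECIALIST_SLIT_FIRST_DOSE, "random",
               float(u(*spec.tariff_range))),
        Tariff("specialist", SPECIALIST_SLIT_CONTROL, "random",
               float(u(*spec.tariff_range))),
        Tariff("specialist", SPECIALIST_SCIT_DOSE, "random",
               float(u(*spec.tariff_range))),
        Tariff("specialist", SPECIALIST_SCIT_CONTROL, "random",
               float(u(*spec.tariff_range))),
        Tariff("hospital", HOSPITAL_ADMINISTRATION, "random",
               float(u(*spec.tariff_range))),
        Tariff("GP", GP_CONSULTATION, "random", float(u(*spec.tariff_range))),
    ])
    human_capital = HumanCapitalParams(
        proportion_male=float(u(0, 1)),
        annual_salary_male=float(u(*spec.salary_range)),
        annual_salary_female=float(u(*spec.salary_range)),
        unemployment_rate=float(u(*spec.unemployment_range)),
        hours_lost_per_visit=float(u(*spec.hours_lost_range)),
    )
    return AnalysisConfig(
        horizon_years=int(rng.integers(*spec.horizon_range, endpoint=True)),
        discount_rate=float(u(0.0, 0.08)),
        exchange_rate_eur_per_dkk=EXCHANGE_RATE_EUR_PER_DKK,
        scit_scheme=scit_scheme,
        slit_scheme=SLIT_DAILY,
        tariffs=tariffs,
        slit_pricing=PackPricing("random SLIT tablet",
                                 float(u(*spec.pack_price_range)), 30,
                                 "tablets"),
        scit_titration_pricing=PackPricing(
            "random titration pack", float(u(*spec.pack_price_range)), 1,
            "pack"),
        scit_maintenance_pricing=PackPricing(
            "random maintenance pack", float(u(*spec.pack_price_range)), 5,
            "ml"),
        care_settings={"SCIT": _random_distribution(rng),
                       "SLIT": _random_distribution(rng)},
        human_capital=human_capital,
        disease_burden=DiseaseBurdenParams(),
        symptom_medications=DEFAULT_SYMPTOM_MEDICATIONS,
        consumption_model=ConsumptionModel(
            total_maintenance_volume_ml=float(u(0.0, 40.0))),
    )


@dataclass(frozen=True)
class CalibrationResult:
    """Fitted care-setting distribution with residuals against the targets."""

    modality: Modality
    distribution: CareSettingDistribution
    residuals: dict[str, float]
    objective: float


_CALIBRATION_COMPONENTS = ("gp", "specialist", "hospital", "medication")


def _component_matrix(config: AnalysisConfig,
                      modality: Modality,
                      components: tuple[str, ...]) -> np.ndarray:
    """Rows: care setting; columns: mixed-breakdown component totals when
    100% of care happens in that setting (the mixture is linear in the
    shared per-phase proportions)."""
    rows = []
    for setting in SETTINGS:
        cfg = with_overrides(config, {
            "care_settings": {
                **dict(config.care_settings),
                modality: CareSettingDistribution.degenerate(setting)}})
        breakdown = run_arm(cfg, modality)
        rows.append([breakdown.component_total(c) for c in components])
    return np.asarray(rows)


def _simplex_grid(step: float, centre: np.ndarray | None = None,
                  radius: float | None = None) -> np.ndarray:
    """(gp, specialist, hospital) points on the unit simplex at ``step``
    resolution, optionally restricted to a box around ``centre``."""
    if centre is None:
        g_values = s_values = np.arange(0.0, 1.0 + step / 2, step)
    else:
        def window(c: float) -> np.ndarray:
            lo = max(0.0, c - radius)
            hi = min(1.0, c + radius)
            return np.arange(lo, hi + step / 2, step)

        g_values, s_values = window(centre[0]), window(centre[1])
    g, s = np.meshgrid(g_values, s_values, indexing="ij")
    g, s = g.ravel(), s.ravel()
    h = 1.0 - g - s
    keep = h > -1e-12
    return np.column_stack([g[keep], s[keep], np.clip(h[keep], 0.0, None)])


def calibrate_setting_distribution(
        targets: Mapping[str, float],
        config: AnalysisConfig,
        modality: Modality,
        grid_step: float = 0.01,
        refine_steps: tuple[float, ...] = (0.001, 0.0001),
) -> CalibrationResult:
    """Back-solve a shared (initiation = maintenance) care-setting
    distribution from component cost targets.

    Least-squares fit of the proportions on the simplex, minimizing squared
    DKK residuals, by exhaustive grid search at ``grid_step`` resolution
    followed by local refinement. Deterministic.
    """
    components = tuple(c for c in _CALIBRATION_COMPONENTS if c in targets)
    if not components:
        raise InvalidParameterError("no calibration targets given")
    target_vec = np.array([targets[c] for c in components], dtype=float)
    if np.any(target_vec < 0):
        raise InvalidParameterError("component cost targets must be >= 0")

    coeff = _component_matrix(config, modality, components)  # (3, k)

    def best_on(points: np.ndarray) -> tuple[np.ndarray, float]:
        predictions = points @ coeff
        sq = ((predictions - target_vec) ** 2).sum(axis=1)
        i = int(np.argmin(sq))
        return points[i], float(sq[i])

    best, objective = best_on(_simplex_grid(grid_step))
    radius = grid_step
    for step in refine_steps:
        best, objective = best_on(_simplex_grid(step, centre=best,
                                                radius=radius))
        radius = step

    fitted = CareSettingDistribution.single_phase(
        gp=float(best[0]), specialist=float(best[1]),
        hospital=float(best[2]))
    predicted = best @ coeff
    residuals = {c: float(p - t)
                 for c, p, t in zip(components, predicted, target_vec)}
    return CalibrationResult(modality=modality, distribution=fitted,
                             residuals=residuals, objective=objective)


def calibrate_base_case(config: AnalysisConfig,
                        targets: Mapping[str, Mapping[str, float]],
                        ) -> tuple[AnalysisConfig, dict[str, CalibrationResult]]:
    """Calibrate both arms' distributions and return the updated config."""
    results = {
        modality: calibrate_setting_distribution(targets[modality], config,
                                                 modality)
        for modality in ("SCIT", "SLIT")}
    fitted = {m: r.distribution for m, r in results.items()}
    return with_overrides(config, {"care_settings": fitted}), results
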