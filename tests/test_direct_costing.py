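"""Tariff microcosting, acquisition costs and setting mixtures."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ait_cma.defaults import (DEFAULT_TARIFFS, SCIT_MAINTENANCE_PRICING,
                              SCIT_TITRATION_PRICING, SLIT_TABLET_PRICING)
from ait_cma.direct_costing import (CareSettingDistribution, PhaseCosts,
                                    SettingArmCosts, SettingYearCosts, Tariff,
                                    TariffSet, mix_settings,
                                    scit_acquisition_cost, setting_visit_cost,
                                    slit_acquisition_cost)
from ait_cma.errors import (ConfigurationError, InvalidParameterError,
                            ModalityError)
from ait_cma.rounding import round_half_up
from ait_cma.schedules import (CONVENTIONAL, SLIT_DAILY, ConsumptionModel,
                               DrugConsumption, build_scit_visit_schedule,
                               build_slit_visit_schedule, drug_consumption)


@pytest.fixture(scope="module")
def scit_schedule():
    return build_scit_visit_schedule(CONVENTIONAL, 3)


@pytest.fixture(scope="module")
def slit_schedule():
    return build_slit_visit_schedule(SLIT_DAILY, 3)


class TestAcquisitionCosts:
    def test_slit_three_year_cost(self, slit_schedule):
        consumption = drug_consumption(slit_schedule, SLIT_DAILY)
        cost = sum(slit_acquisition_cost(consumption, SLIT_TABLET_PRICING))
        assert round_half_up(cost) == 26858  # 1,092 tablets at 737.87/30

    def test_zero_tablets_cost_nothing(self):
        consumption = DrugConsumption("SLIT", (0.0,), (0.0,), (0.0,))
        assert slit_acquisition_cost(consumption, SLIT_TABLET_PRICING) == [0.0]

    def test_one_treatment_year_of_tablets(self):
        consumption = DrugConsumption("SLIT", (364.0,), (0.0,), (0.0,))
        cost = slit_acquisition_cost(consumption, SLIT_TABLET_PRICING)
        assert cost[0] == pytest.approx(8952.8, abs=0.1)

    def test_unit_mismatch_rejected(self, slit_schedule):
        consumption = drug_consumption(slit_schedule, SLIT_DAILY)
        with pytest.raises(ConfigurationError):
            slit_acquisition_cost(consumption, SCIT_MAINTENANCE_PRICING)

    def test_scit_implied_model_gp_setting(self, scit_schedule):
        consumption = drug_consumption(
            scit_schedule, CONVENTIONAL,
            ConsumptionModel(kind="implied", total_maintenance_volume_ml=19.0))
        pairs = scit_acquisition_cost(consumption, SCIT_TITRATION_PRICING,
                                      SCIT_MAINTENANCE_PRICING, "GP")
        total = sum(t + m for t, m in pairs)
        assert total == pytest.approx(9991.6)  # 2,306.10 + 19 ml x 404.50

    def test_scit_hospital_drg_covers_drug(self, scit_schedule):
        consumption = drug_consumption(scit_schedule, CONVENTIONAL)
        pairs = scit_acquisition_cost(consumption, SCIT_TITRATION_PRICING,
                                      SCIT_MAINTENANCE_PRICING, "hospital")
        assert all(pair == (0.0, 0.0) for pair in pairs)

    def test_titration_pack_only(self):
        consumption = DrugConsumption("SCIT", (0.0,), (1.0,), (0.0,))
        pairs = scit_acquisition_cost(consumption, SCIT_TITRATION_PRICING,
                                      SCIT_MAINTENANCE_PRICING, "specialist")
        assert pairs[0][0] == pytest.approx(2306.10)

    def test_slit_consumption_rejected(self, slit_schedule):
        consumption = drug_consumption(slit_schedule, SLIT_DAILY)
        with pytest.raises(ModalityError):
            scit_acquisition_cost(consumption, SCIT_TITRATION_PRICING,
                                  SCIT_MAINTENANCE_PRICING, "GP")


class TestSettingVisitCost:
    def test_slit_gp_flat_tariff(self, slit_schedule):
        costs = setting_visit_cost(slit_schedule, "GP", DEFAULT_TARIFFS)
        assert sum(c.total for c in costs) == pytest.approx(591.40)  # 4 visits

    def test_scit_hospital_drg_per_visit(self, scit_schedule):
        costs = setting_visit_cost(scit_schedule, "hospital", DEFAULT_TARIFFS)
        assert sum(c.total for c in costs) == pytest.approx(39.4 * 2129)

    def test_scit_specialist_maintenance_year(self, scit_schedule):
        costs = setting_visit_cost(scit_schedule, "specialist", DEFAULT_TARIFFS)
        # year 2: 7.7 injection visits plus one annual control visit
        assert costs[1].total == pytest.approx(7.7 * 485.43 + 555.72)

    def test_slit_specialist_uses_first_dose_then_annual_tariff(
            self, slit_schedule):
        costs = setting_visit_cost(slit_schedule, "specialist",
                                   DEFAULT_TARIFFS)
        assert costs[0].initiation == pytest.approx(478.76)
        assert sum(c.maintenance for c in costs) == pytest.approx(3 * 555.72)

    def test_missing_tariff_names_the_code(self, slit_schedule):
        tariffs = TariffSet([Tariff("GP", "0101", "gp", 147.85)])
        with pytest.raises(ConfigurationError, match="0144"):
            setting_visit_cost(slit_schedule, "specialist", tariffs)


def _arm_costs(setting, visit_costs, medication, indirect=None):
    indirect = indirect or [(0.0, 0.0)] * len(visit_costs)
    years = tuple(
        SettingYearCosts(visit_cost=PhaseCosts(*v), medication=PhaseCosts(*m),
                         indirect=PhaseCosts(*i), visits=PhaseCosts(1, 1))
        for v, m, i in zip(visit_costs, medication, indirect))
    return SettingArmCosts(modality="SCIT", setting=setting, years=years)


def _per_setting(values):
    return {s: _arm_costs(s, [(v, v)], [(v / 2, v / 2)])
            for s, v in zip(("GP", "specialist", "hospital"), values)}


class TestMixSettings:
    def test_degenerate_distribution_recovers_single_setting(self):
        per_setting = _per_setting((10.0, 100.0, 1000.0))
        mixed = mix_settings(per_setting,
                             CareSettingDistribution.degenerate("GP"))
        assert mixed.years[0].gp == pytest.approx(20.0)
        assert mixed.years[0].specialist == 0.0
        assert mixed.years[0].hospital == 0.0
        assert mixed.years[0].medication == pytest.approx(10.0)

    def test_uniform_thirds_average_components(self):
        per_setting = _per_setting((30.0, 30.0, 30.0))
        third = 1.0 / 3.0
        mixed = mix_settings(
            per_setting,
            CareSettingDistribution.single_phase(third, third, third))
        for component in ("gp", "specialist", "hospital"):
            assert getattr(mixed.years[0], component) == pytest.approx(20.0)
        assert mixed.years[0].medication == pytest.approx(30.0)

    @given(props=st.lists(st.floats(min_value=0.01, max_value=1.0),
                          min_size=3, max_size=3))
    @settings(deadline=None, max_examples=50)
    def test_mixture_is_convex(self, props):
        total = sum(props)
        gp, spec, hosp = (p / total for p in props)
        values = (10.0, 100.0, 1000.0)
        per_setting = _per_setting(values)
        mixed = mix_settings(
            per_setting,
            CareSettingDistribution.single_phase(gp, spec, hosp))
        visit_total = (mixed.years[0].gp + mixed.years[0].specialist
                       + mixed.years[0].hospital)
        assert 2 * min(values) - 1e-9 <= visit_total <= 2 * max(values) + 1e-9

    def test_mismatched_horizons_rejected(self):
        per_setting = _per_setting((1.0, 2.0, 3.0))
        per_setting["GP"] = _arm_costs("GP", [(1, 1), (1, 1)],
                                       [(0, 0), (0, 0)])
        with pytest.raises(ConfigurationError):
            mix_settings(per_setting,
                         CareSettingDistribution.degenerate("GP"))


class TestCareSettingDistribution:
    def test_proportions_must_sum_to_one(self):
        with pytest.raises(InvalidParameterError):
            CareSettingDistribution.single_phase(0.5, 0.5, 0.5)

    def test_proportions_must_be_fractions(self):
        with pytest.raises(InvalidParameterError):
            CareSettingDistribution.single_phase(1.5, -0.5, 0.0)

    def test_phases_may_differ(self):
        dist = CareSettingDistribution(
            initiation={"GP": 0.0, "specialist": 1.0, "hospital": 0.0},
            maintenance={"GP": 0.5, "specialist": 0.25, "hospital": 0.25})
        assert dist.initiation["specialist"] == 1.0
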