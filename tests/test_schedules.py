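"""Visit schedules and drug consumption for both immunotherapy arms."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ait_cma.errors import InvalidParameterError, ModalityError
from ait_cma.schedules import (ACCELERATED, CONVENTIONAL, SLIT_DAILY,
                               ConsumptionModel, DosingScheme,
                               build_scit_visit_schedule,
                               build_slit_visit_schedule, drug_consumption,
                               maintenance_visits_per_year)


class TestMaintenanceRate:
    @pytest.mark.parametrize("interval, weeks, expected", [
        (6, 52, 8.7),      # the conventional 6-weekly maintenance figure
        (52, 52, 1.0),
        (4, 52, 13.0),
    ])
    def test_rate(self, interval, weeks, expected):
        assert maintenance_visits_per_year(interval, weeks) == expected

    @pytest.mark.parametrize("interval", [0, -1])
    def test_non_positive_interval_rejected(self, interval):
        with pytest.raises(InvalidParameterError):
            maintenance_visits_per_year(interval)


class TestScitSchedule:
    def test_conventional_year1_composition(self):
        schedule = build_scit_visit_schedule(CONVENTIONAL, 3)
        y1 = schedule.years[0]
        assert (y1.titration, y1.transition, y1.maintenance) == (15, 2, 5)
        assert y1.total == 22
        # year-1 total is the exact sum of its categories (conservation)
        assert y1.total == y1.titration + y1.transition + y1.maintenance

    def test_maintenance_years_at_steady_state(self):
        schedule = build_scit_visit_schedule(CONVENTIONAL, 3)
        assert [y.total for y in schedule.years[1:]] == [8.7, 8.7]
        assert schedule.total_visits == pytest.approx(39.4)

    def test_accelerated_year1_total_is_12(self):
        schedule = build_scit_visit_schedule(ACCELERATED, 3)
        assert schedule.years[0].total == 12

    def test_horizon_1_is_prefix_of_horizon_3(self):
        short = build_scit_visit_schedule(CONVENTIONAL, 1)
        long = build_scit_visit_schedule(CONVENTIONAL, 3)
        assert short.years == long.years[:1]
        assert short.years[0].total == 22

    def test_annual_control_flag(self):
        schedule = build_scit_visit_schedule(CONVENTIONAL, 3)
        assert [y.control_relabel for y in schedule.years] == [1, 1, 1]
        later = build_scit_visit_schedule(CONVENTIONAL, 3,
                                          annual_control_start_year=2)
        assert [y.control_relabel for y in later.years] == [0, 1, 1]

    def test_slit_scheme_rejected(self):
        with pytest.raises(ModalityError):
            build_scit_visit_schedule(SLIT_DAILY, 3)

    @given(horizon=st.integers(min_value=1, max_value=12))
    @settings(deadline=None)
    def test_total_monotone_in_horizon(self, horizon):
        shorter = build_scit_visit_schedule(CONVENTIONAL, horizon)
        longer = build_scit_visit_schedule(CONVENTIONAL, horizon + 1)
        assert longer.total_visits >= shorter.total_visits

    @given(titration=st.integers(min_value=1, max_value=30),
           interval=st.floats(min_value=1.0, max_value=12.0),
           horizon=st.integers(min_value=1, max_value=6))
    @settings(deadline=None, max_examples=50)
    def test_packing_never_overfills_the_year(self, titration, interval,
                                              horizon):
        scheme = DosingScheme(
            name="fuzz", modality="SCIT",
            titration_injections=titration,
            titration_span_weeks=float(titration),
            transition_injections=2, transition_intervals_weeks=(2.0, 4.0),
            maintenance_interval_weeks=interval)
        schedule = build_scit_visit_schedule(scheme, horizon)
        y1 = schedule.years[0]
        assert y1.maintenance >= 0
        # packed maintenance doses fit in the remaining weeks of year 1
        consumed = titration + 6 + y1.maintenance * interval
        assert consumed <= 52 + interval


class TestSlitSchedule:
    @pytest.mark.parametrize("horizon, expected_total", [(1, 2), (3, 4), (5, 6)])
    def test_one_first_dose_plus_annual_evaluations(self, horizon,
                                                    expected_total):
        schedule = build_slit_visit_schedule(SLIT_DAILY, horizon)
        assert schedule.total_visits == expected_total
        assert schedule.years[0].first_dose == 1
        assert all(y.annual_control == 1 for y in schedule.years)

    def test_zero_horizon_rejected(self):
        with pytest.raises(InvalidParameterError):
            build_slit_visit_schedule(SLIT_DAILY, 0)

    def test_scit_scheme_rejected(self):
        with pytest.raises(ModalityError):
            build_slit_visit_schedule(CONVENTIONAL, 3)

    def test_slit_scheme_with_injections_rejected(self):
        with pytest.raises(InvalidParameterError):
            DosingScheme(name="bad", modality="SLIT", titration_injections=3)


class TestDrugConsumption:
    def test_slit_daily_tablet_count(self):
        schedule = build_slit_visit_schedule(SLIT_DAILY, 3)
        consumption = drug_consumption(schedule, SLIT_DAILY)
        # one tablet/day over a 52-week (364-day) treatment year
        assert consumption.total_tablets == 1092
        assert consumption.total_maintenance_volume_ml == 0

    def test_implied_model_with_zero_volume(self):
        schedule = build_scit_visit_schedule(CONVENTIONAL, 3)
        consumption = drug_consumption(
            schedule, CONVENTIONAL,
            ConsumptionModel(kind="implied", total_maintenance_volume_ml=0.0))
        assert sum(consumption.titration_packs) == 1
        assert consumption.total_maintenance_volume_ml == 0

    def test_implied_model_allocates_by_post_titration_injections(self):
        schedule = build_scit_visit_schedule(CONVENTIONAL, 3)
        consumption = drug_consumption(
            schedule, CONVENTIONAL,
            ConsumptionModel(kind="implied", total_maintenance_volume_ml=19.0))
        assert consumption.total_maintenance_volume_ml == pytest.approx(19.0)
        # year weights 7 : 8.7 : 8.7 (transition + maintenance injections)
        assert consumption.maintenance_volume_ml[0] == pytest.approx(
            19.0 * 7 / 24.4)

    def test_mechanistic_model_volume(self):
        schedule = build_scit_visit_schedule(CONVENTIONAL, 3)
        consumption = drug_consumption(
            schedule, CONVENTIONAL,
            ConsumptionModel(kind="mechanistic", ml_per_injection=1.0,
                             titration_vial_leftover_ml=2.5))
        # 24.4 post-titration injections x 1 ml, less 2.5 ml vial leftover
        assert consumption.total_maintenance_volume_ml == pytest.approx(21.9)

    def test_modality_mismatch_rejected(self):
        schedule = build_scit_visit_schedule(CONVENTIONAL, 3)
        with pytest.raises(ModalityError):
            drug_consumption(schedule, SLIT_DAILY)
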