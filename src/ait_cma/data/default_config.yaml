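horizon_years: 3
discount_rate: 0.0
exchange_rate_eur_per_dkk: 0.134342
schemes:
  SCIT: conventional
  SLIT: slit-daily
  SCIT_by_setting: {}
tariffs:
- setting: specialist
  code: '0144'
  description: ENT specialist first SLIT dose
  unit_cost: 478.76
- setting: specialist
  code: '2027'
  description: ENT specialist annual allergy control visit, SLIT
  unit_cost: 555.72
- setting: specialist
  code: '0143'
  description: ENT specialist SCIT dose, single allergy
  unit_cost: 485.43
- setting: specialist
  code: '2026'
  description: ENT specialist annual allergy control visit, SCIT
  unit_cost: 555.72
- setting: hospital
  code: 49PR03
  description: Hospital visit for uncomplicated SLIT or SCIT administration (DRG)
  unit_cost: 2129.0
- setting: GP
  code: '0101'
  description: GP consultation subsequent to diagnosis
  unit_cost: 147.85
pricing:
  slit:
    product: SQ tree SLIT-tablet
    pack_price: 737.87
    pack_size: 30
    unit: tablets
  scit_titration:
    product: birch SCIT titration pack (4 x 5 ml)
    pack_price: 2306.1
    pack_size: 1
    unit: pack
  scit_maintenance:
    product: birch SCIT 100,000 SQ-U/ml maintenance pack
    pack_price: 2022.5
    pack_size: 5
    unit: ml
care_settings:
  SCIT:
    initiation:
      GP: 0.07815
      specialist: 0.81563
      hospital: 0.10622
    maintenance:
      GP: 0.07815
      specialist: 0.81563
      hospital: 0.10622
  SLIT:
    initiation:
      GP: 0.4544
      specialist: 0.3619
      hospital: 0.1837
    maintenance:
      GP: 0.4544
      specialist: 0.3619
      hospital: 0.1837
human_capital:
  mean_age: 36.1
  proportion_male: 0.47
  annual_salary_male: 381400.0
  annual_salary_female: 296000.0
  workforce_entry_age: 18.0
  retirement_age: 67.0
  unemployment_rate: 0.033
  working_days_per_year: 220.0
  annual_working_hours: 1701.9199999999998
  hours_lost_per_visit: 2.0
disease_burden:
  tps_days: 50.0
  placebo_sick_day_rate: 0.0129
  sick_day_relative_risk: 0.5800000000000001
  placebo_productivity: 0.893
  productivity_gain_points: 0.034
  apply_equally_to_both_arms: true
  tps_workday_fraction: 1.0
symptom_medication:
- name: desloratadine tablets
  proportion_using: 0.668
  seasonal_dose: 21.7
  pack_price: 183.75
  pack_size: 100
  unit: tablets
  pack_ml: null
  drops_per_ml: null
- name: olopatadine eyedrops
  proportion_using: 0.396
  seasonal_dose: 38.0
  pack_price: 96.25
  pack_size: 5
  unit: drops
  pack_ml: 5.0
  drops_per_ml: 20.0
- name: mometasone nasal spray
  proportion_using: 0.479
  seasonal_dose: 38.4
  pack_price: 34.2
  pack_size: 140
  unit: sprays
  pack_ml: null
  drops_per_ml: null
consumption_model:
  kind: implied
  total_maintenance_volume_ml: 19.0
  ml_per_injection: 1.0
  titration_vial_leftover_ml: 2.5
adherence:
  name: full
  slit_adherence: 1.0
  scit_adherence: 1.0
  applies_to:
  - acquisition
  - hcp_interactions
  - visit_indirect
flags:
  include_visit_indirect: true
  include_disease_burden: false
  include_symptom_meds: false
  annual_control_start_year: 1
  drg_covers_scit_acquisition: true
conventions:
  weeks_per_year: 52
  days_per_treatment_year: 364
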