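# ait-cma

A cost-minimization model comparing sublingual immunotherapy (SLIT, a daily
at-home tablet) with subcutaneous immunotherapy (SCIT, clinic-administered
injections) for moderate-to-severe allergic rhinitis induced by birch-group
pollen, from the Danish societal perspective.

The package is aimed at health economists and HTA analysts: it rebuilds the
full decision-analytic costing — dosing-rule-driven visit schedules,
tariff-based microcosting across three care settings (general practice, ENT
allergy specialist, hospital), drug acquisition, human-capital productivity
losses, discounting, adherence — plus the one-way sensitivity battery and a
calibration utility for the unpublished care-setting distribution.

## The model in brief

Under assumed clinical equivalence, the comparison reduces to 3-year
per-patient costs

C_arm = Σ_y δ(y) [ C_drug(y) + Σ_s p_s · C_visits(s, y) + L · V(y) ],

where δ(y) = (1+r)^−(y−1) discounts year y, p_s is the proportion of care in
setting s, C_visits prices the visit schedule with flat per-visit tariffs,
and indirect costs value each of the V(y) healthcare-professional
interactions at L = 2 h × the employment-adjusted hourly wage
(381.97 DKK/visit). SCIT generates 22 interactions in year 1 (15 weekly
titration + 2 transition + 5 six-weekly maintenance injections) and 8.7/year
thereafter; SLIT generates a supervised first dose plus one annual
evaluation (4 visits over 3 years) and 364 tablets per 52-week treatment
year. In the hospital setting the DRG tariff bundles the SCIT drug cost.
See `docs/methods.md` for every convention and parameter.

## Worked example

```python
from ait_cma import compare, default_config, round_half_up, to_eur

config = default_config()          # 3-year Danish base case
result = compare(config)

for component in ("medication", "specialist", "hospital", "gp", "indirect"):
    print(f"{component:>12}: SCIT {round_half_up(result.scit_totals[component]):>8,.0f}"
          f"  SLIT {round_half_up(result.slit_totals[component]):>8,.0f}")
print(f"{'total':>12}: SCIT {round_half_up(result.scit_totals['total']):>8,.0f}"
      f"  SLIT {round_half_up(result.slit_totals['total']):>8,.0f}")
print(f"saving with SLIT: {-result.difference['total']:,.0f} DKK"
      f" = {to_eur(-result.difference['total'], config.exchange_rate_eur_per_dkk):,.0f} EUR")
```

prints

```
  medication: SCIT    8,930  SLIT   26,858
  specialist: SCIT   15,772  SLIT      777
    hospital: SCIT    8,910  SLIT    1,564
          gp: SCIT      455  SLIT      269
    indirect: SCIT   15,050  SLIT    1,528
       total: SCIT   49,117  SLIT   30,996
saving with SLIT: 18,121 DKK = 2,434 EUR
```

i.e. the tablet's higher acquisition cost (+17,928 DKK) is more than offset
by fewer clinic visits and the associated productivity losses, a 3-year
saving of ~18,121 DKK (~2,434 EUR) per patient. The care-setting proportions
behind the specialist/hospital/GP split are calibrated (back-solved from the
published component costs), not published inputs — reports label them so.

## Analysis drivers

The numbered scripts under `analysis/` re-run the study end to end and write
their tables under `results/`:

1. `01_schedules_and_consumption.py` — visit schedules and drug quantities
   for both arms (conventional and accelerated SCIT up-dosing).
2. `02_base_case.py` — calibrates the care-setting distribution from the
   published component costs and produces the base-case breakdown table.
3. `03_sensitivity.py` — the 13-scenario one-way battery, the annual cost
   profile, and a JSON report bundle.

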