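# Methods

## The model

`ait_cma` is a deterministic cost-minimization model comparing two allergy
immunotherapy (AIT) modalities for moderate-to-severe allergic rhinitis
induced by pollen from the birch homologous group, from the Danish societal
perspective:

* **SCIT** — subcutaneous immunotherapy (clinic-administered birch allergen
  injections), and
* **SLIT** — a daily sublingual immunotherapy tablet taken at home after a
  supervised first dose.

Cost-minimization assumes the two treatments are clinically equivalent, so
only costs are compared. Per-patient costs are accumulated over a 3-year
horizon (the guideline-recommended course) in 2021 Danish Kroner, with Euro
equivalents at the 2021 ECB 365-day average rate (1 DKK = 0.134342 EUR).
Future costs are undiscounted in the base case, as is conventional for
budget-impact-style short horizons; discount rates enter through scenarios.

Costs comprise:

1. **Drug acquisition.** SLIT: one tablet per day at the list price
   737.87 DKK / 30 tablets. SCIT: one titration pack (2,306.10 DKK) during
   up-dosing, then maintenance vials at 2,022.50 DKK / 5 ml. In the hospital
   setting the DRG tariff bundles the SCIT drug, so SCIT acquisition is a
   separate cost only in the GP and specialist settings.
2. **Healthcare-professional (HCP) interactions**, priced with flat
   per-visit tariffs by care setting: GP 147.85; hospital (DRG) 2,129;
   ENT specialist 478.76 (SLIT first dose), 555.72 (annual control, either
   modality) and 485.43 (SCIT injection).
3. **Indirect costs** by the human capital approach: 2 hours of gross wages
   lost per HCP interaction.

## Visit schedules

SCIT follows the conventional initial therapy: 15 weekly titration
injections, transition injections of the full maintenance dose 2 and a
further 4 weeks later, then ongoing 6-weekly maintenance. One clinic visit
per injection. Year-1 maintenance visits are derived by packing 6-weekly
doses into the remainder of the 52-week year after titration (15 wk) and
transition (6 wk): floor(31/6) = 5, giving the year-1 total of
15 + 2 + 5 = 22 interactions. Subsequent years use the steady-state rate
52/6 = 8.7 visits/year (half-up, one decimal), carried as a real number —
never rounded to whole visits — through all costing; the 3-year course is
39.4 interactions.

The accelerated (hospital) scheme shortens up-dosing to 8 injections over
16 weeks. Its regimen definition fixes the first-year course at 12
injections in total; because no 6-weekly packing of the remaining weeks
yields that count (the packing rule would give 15), the scheme carries an
explicit `first_year_maintenance = 2` field rather than a derived value.
The packing rule remains the default for schemes that do not state a
first-year count.

SLIT generates one supervised first-dose visit plus one annual evaluation
per treatment year: 4 visits over 3 years. The first annual evaluation falls
at the end of year 1 (1 + 3 visits), the convention consistent with the
published indirect total (4 × 381.98 ≈ 1,528 DKK).

**Annual control visit.** One visit per year — in every year including
year 1 — is billed at the specialist annual-control tariff (555.72) instead
of the injection tariff; for SCIT it consumes one maintenance visit. The
year-1 control is adopted because the published specialist-only totals
require it (44,378 DKK is reproduced with three control visits, not two);
`annual_control_start_year` exposes the alternative convention.

## Drug consumption

A treatment year is 52 weeks = 364 days for tablet counting, the convention
under which 3 years of daily tablets (1,092) price to the published
26,858 DKK; 360-, 365- and 365.25-day years do not.

SCIT maintenance volume offers two models:

* **implied** (default): a configured total volume over the horizon,
  19.0 ml by default — the value implied by the published GP-only SCIT
  total (acquisition 9,991.6 = 2,306.10 + 19.0 × 404.50) — allocated across
  years in proportion to post-titration injections (7 : 8.7 : 8.7).
* **mechanistic** (documented, non-default): one 1-ml dose per
  post-titration injection less the unused titration-vial volume
  (default 2.5 ml), i.e. 24.4 − 2.5 = 21.9 ml. It does not reproduce the
  published totals, which is why it is not the default.

## Indirect costs

Hourly wage = sex-weighted mean annual salary (0.47 × 381,400 +
0.53 × 296,000 = 336,138 DKK) × (1 − unemployment 3.3%) / effective annual
working hours. The default working year is 220 workdays × 8 h = 1,760
contracted hours scaled by the 96.7% employment rate (1,701.92 effective
hours), so the employment-adjusted wage equals the contracted wage over a
full working year: 190.99 DKK/h, 381.97 DKK per 2-hour visit. This is the
unique convention (to within ~0.1 h) reproducing both published indirect
totals, 15,050 DKK (39.4 SCIT visits) and 1,528 DKK (4 SLIT visits). The
whole cohort (mean age 36.1, workforce entry 18, retirement 67) is of
working age throughout the horizon, so no ageing adjustment is made.

The disease-burden scenario prices pollen-season (50 days, no weekend
adjustment by default — `tps_workday_fraction` exposes one) absenteeism and
presenteeism at the daily wage: placebo-arm sick-day rate 1.29% of season
days, reduced by 42% on treatment (relative risk 0.58); on-the-job
productivity 89.3% with placebo, +3.4 points on treatment. Both arms are
assumed actively treated, so the same burden is added to each and the
between-arm difference is unchanged — the published scenario's absolute
totals (65,669/47,547) imply a per-year burden no documented combination of
the trial parameters reproduces, so this scenario is validated through the
difference-invariance property, not absolute totals.

Symptom-relief medication (scenario): expected cost per season-year =
Σ proportion-using × seasonal dose × unit price, with eyedrops converted at
the standard 20 drops/ml. The defaults yield ≈45.6 DKK/year, ≈137 DKK over
3 years, matching the published increment.

## Care settings and mixing

The distribution of care across GP / ENT specialist / hospital is the one
base-case input without published numerical values. Per-setting costs are
computed as if 100% of care occurred in that setting, split into an
initiation phase (SCIT up-dosing + transition; the SLIT first dose) and a
maintenance phase (everything else), then combined as a convex mixture with
per-phase proportions. SCIT acquisition rides along: the hospital column
carries zero medication, so mixing automatically weights the drug cost by
the proportion of care outside hospital.

**Calibration.** The distribution is back-solved from the published
component costs by least squares on the simplex: an exhaustive 1-percentage-
point grid (the brute-force oracle) refined locally to 0.01 pp. Mixture
components are linear in shared per-phase proportions, so the fit is well
posed; synthetic round-trips recover known distributions to < 0.01 pp. A
single distribution per modality, shared by both phases, reproduces every
published component within 1.7 DKK: SCIT ≈ 7.8% GP / 81.6% specialist /
10.6% hospital; SLIT ≈ 45.4% / 36.2% / 18.4%. These fitted values are
frozen in the default config and labelled calibrated wherever reported;
they are model outputs standing in for an unpublished figure, not published
inputs.

## Engine conventions

* **Discounting:** present value Σ cost_y / (1+r)^(y−1), year 1
  undiscounted. The published 3%/5% totals depend on the unpublished annual
  cost profile; the model matches their ordering (47,511 < 48,129 < 49,117
  pattern) but not the printed figures to the DKK.
* **Adherence scenarios** scale acquisition, HCP-interaction and
  visit-indirect costs by the adherent proportion (SLIT/SCIT: 81%/83% from
  the German registry analysis; 61.0%/67.6% from the single-center dropout
  analysis). The published adherence totals are not a uniform scaling of the
  base case (their mechanics are unstated), so these rows are validated by
  scaling properties.
* **Rounding:** internal arithmetic is unrounded; DKK/EUR values are
  half-up rounded to integers only in reports. The percent saving is
  computed as difference ÷ SCIT total (36.9% in the base case; the published
  summary prints 36.7%).
* **Scenario battery:** declarative overrides (dotted config path → value);
  13 built-in analyses. The all-hospital scenario retains the pharmacy
  acquisition cost of SCIT (overriding the DRG bundling rule), which is how
  the published 108,924 DKK total is constituted. The
  accelerated-up-dosing row applies the accelerated scheme to the hospital
  setting only; its published totals are internally inconsistent (the SLIT
  arm changes although the scenario touches only the SCIT scheme) and are
  reported, not matched.

## Synthetic configurations

`scenario_gen.generate_config` draws structurally valid random
parameterizations — tariffs 50–3,000 DKK, pack prices 100–5,000 DKK,
salaries 150–600 k DKK, unemployment 0–20%, 0–8 h lost per visit, 4–20
titration injections, 4–10-week maintenance intervals, horizons 1–5 years,
Dirichlet setting distributions — for fuzzing the whole pipeline and for
calibration round-trips. These sets exercise the model's invariants
(nonnegativity, convexity, determinism); they do not emulate sampling
variation in real Danish registry or trial data, so passing property tests
demonstrates structural correctness of the accounting, not external
validity of any particular parameter estimate.

## Known limitations

* The care-setting distribution is calibrated, not observed; conclusions
  that depend on it inherit the identifiability caveat that several
  near-simplex solutions fit the published components almost equally well.
* No payer split, co-payment modelling, price indexation, friction-cost
  method, QALYs, or probabilistic sensitivity analysis.
* Adherence is a proportional cost scaling, not a time-varying dropout
  process.
* Individual injection doses/strengths within titration are out of scope;
  only counts and the titration-vial leftover volume are modelled.
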