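# phcguide — investment guide posts for primary health care

`phcguide` is a projection framework for the resources low- and
middle-income countries (LMICs) need to strengthen **primary health
care (PHC)** on the road to universal health coverage.  It is aimed at
health economists and health-systems modellers who want a tested,
reproducible implementation of the full chain from intervention
catalog to investment guide posts:

1. **Three nested PHC measures.** Measure 1 covers preventive/public
   health interventions and general outpatient care; measure 2 adds
   general inpatient care (normal delivery, basic emergency obstetric
   care) and full health-sector system support; measure 3 adds
   cross-sectoral investments (water and sanitation, air quality, food
   safety).  Of a 188-intervention essential package, 143/152/160
   interventions fall in measures 1/2/3, and each measure carries
   explicit allocation shares over shared system costs (district
   hospital infrastructure 33% under measure 1 vs 81% under measures
   2–3; provincial 3% vs 27%; governance and financing 80% vs 100%;
   cold chain always in full).

2. **Ingredients-based costing.** Every investment is quantities ×
   prices.  For intervention *i* in country *c* and year *t*, people
   reached are `N_ct · target_i · need_i · cov_it`, and the incremental
   commodity cost is

   `ΔC_ict = N_ct · target_i · need_i · (cov_it − cov_i,2015) · units_i · p_i · π_c`

   with `π_c` the country price index.  The workforce requirement is
   bottom-up — service minutes divided by available minutes per
   full-time-equivalent year — expressed as a PHC share of the full
   package and applied to a density benchmark.  Capital modelled for
   2016–19 is redistributed uniformly over 2020–30.

3. **Coverage scale-up by system maturity.** Countries hold their
   baseline through 2019 and then move linearly to maturity-specific
   2030 targets (conflict 0.70 → strongest systems 0.95); the
   counterfactual is a *flatline* at baseline coverage.

4. **Impact.** A declared coverage-effectiveness stand-in converts
   coverage gains into deaths averted per cause group,
   `1 − Π_i (1 − e_i·Δcov_i)`, capped by the cause's deaths.  Abridged
   period life tables (`mx → qx → lx → Lx → Tx → ex`, radix 100 000)
   give life expectancy at birth for 2015 and 2030; healthy life-years
   compare disability-weighted person-years between flatline and
   scale-up scenarios.

5. **Financing.** Current health expenditure (% of GDP) is projected
   under business-as-usual (each country's own trend), +1 and +2
   percentage-point scenarios; a country has a *funding gap* in a year
   when incremental PHC costs exceed incremental funds.

Because the original 67-country inputs are not public, the framework
ships a **synthetic cohort generator**: 67 LMICs over three income
groups and five system-maturity categories with income-graded GDP,
prices, coverage, workforce and mortality.  All guide posts below
describe that synthetic cohort, not any real country.

## Worked example

```bash
python analysis/05_report.py 1     # seed 1
```

prints (abridged):

```
Measure-1 investment guide posts (US$2014 per capita, seed 1):
                     additional_per_capita  current_phc_per_capita  total_recurrent_per_capita_2030  workers_per_1000_2030  le_gain_years
all                                   30.1                    54.6                             80.2                    6.7            5.8
income:low                            31.9                    21.7                             49.5                    6.7            7.0
income:lower-middle                   30.1                    34.1                             60.0                    6.7            5.8
income:upper-middle                   27.9                   117.1                            139.5                    6.7            4.5

Annual additional cost (billion US$2014):
  measure 1: 59.9   measure 2: 76.3   measure 3: 83.4

Gap countries in 2030 by scenario:
  bau 26   progress1 22   ambitious2 15
```

Reading the numbers: the synthetic cohort needs about **$30 per person
per year** of additional PHC investment under measure 1; low-income
countries must roughly **double** current recurrent PHC spending
($21.7 current + $27.7 additional = $49.5 by 2030 — an exact
accounting identity in the report).  The workforce benchmark implies
6.7 workers per 1000 population for PHC by 2030.  Scaling up coverage
averts deaths and raises life expectancy most where mortality is
highest (7.0 years in the low-income group).  Under
business-as-usual financing 26 of 67 countries cannot fund their
measure-1 costs in 2030; a 2-percentage-point-of-GDP increase reduces
that to 15.

The other drivers (`analysis/01_simulate.py` … `04_finance.py`) run
the stages separately and write tidy tables under `results/`.

## Layout

```
src/phcguide/        library: synthetic_data, catalog, coverage,
                     costing, impact, financing, reporting
analysis/            numbered narrative drivers (simulate → report)
tests/               pytest suite incl. acceptance properties
scripts/acceptance.py  end-to-end reproduction script
docs/methods.md      model description, parameters, limitations
```
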