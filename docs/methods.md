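# Methods

This note documents the model behind `phcguide`: what each stage
assumes, the parameters that matter, what the synthetic cohort does
and does not emulate, and the numerical choices made where the design
was genuinely open.

## The three PHC measures

PHC is operationalised as three nested intervention sets plus
allocation shares over shared health-system costs.  The default
catalog has 188 interventions with 143 in measure 1, 152 in measure 2
and 160 in measure 3 (nested by construction; the remainder is
specialised care outside PHC).  The intervention *list* is synthetic:
only the counts, the platform taxonomy and a set of named exemplar
services (vaccination, family planning, normal delivery and basic
emergency obstetric care entering at measure 2, water-sanitation at
measure 3) are fixed; the remaining entries carry randomised costing
parameters.  Measure-level allocation shares are data, not knobs:
district/provincial hospital infrastructure 33%/3% under measure 1
and 81%/27% once general inpatient care is included; governance and
financing 80% vs 100%; health-information-system scope
facility-only → full sector → full sector plus census; emergency
preparedness as a laboratory share (at the district-hospital rate)
under measure 1 and in full thereafter; cash transfers absent,
birth-linked, or general; cross-sectoral costs only under measure 3;
cold chain, emergency relief and post-conflict reconstruction always
in full.

## Synthetic cohort

The generator draws 67 countries across three income groups
(default split 35/40/25%) and, uniformly within income group, five
system-maturity categories (conflict, vulnerable, hs1–hs3).  Key
priors (all configurable, all flowing from one seeded
`numpy.random.Generator`):

| quantity | family | group means |
|---|---|---|
| GDP per capita 2015 (US$2014) | lognormal | 700 / 2 300 / 7 500 by income |
| CHE % GDP 2015, trend | normal | ≈5.5%, +0.05 pp/yr ± 0.04 |
| baseline coverage | beta (conc. 12) | 0.22–0.58 by maturity, ×0.85/1.0/1.15 by income |
| workforce density (/1000) | lognormal | 1.4 / 4.6 / 7.9 by income |
| current PHC spending pc | lognormal | 25 / 34 / 110 by income |
| price index | lognormal | 0.80 / 1.00 / 1.40 by income |
| adult mortality | Gompertz `a·e^{b·age}` | a = 8.0/6.5/5.0 ×10⁻⁵, b ≈ 0.09 |
| infant / child mortality | level | 55/32/12 and 6.5/3.2/1.0 per 1000 |

Population pyramids use income-specific geometric age templates with
old-age attrition past 65 and income-graded growth (2.7%/1.5%/0.6%
per year).  The resulting cohort has a crude death rate near 8 per
1000 and female life expectancies of 66/69/72 years by income group.
The generator enforces the orderings the analysis relies on (poorer
groups: lower coverage, prices and workforce, higher mortality) in
expectation; they are verified by Monte-Carlo tests at n = 1000.

What the cohort does **not** emulate: real country identities or any
calibration to UN World Population Prospects; migration; mortality
trends over time (rates are held at 2015 levels, so the flatline 2030
life table equals the 2015 one); intervention-specific target-group
demographics (all interventions target population fractions, not age
bands).  Passing tests therefore demonstrate the *mechanics* of the
framework, not country-level forecasts.

## Coverage

Coverage holds at baseline through 2019 (limited early progress) and
rises linearly to a maturity-specific 2030 target: conflict 0.70,
vulnerable 0.80, hs1 0.85, hs2 0.90, hs3 0.95.  The mapping is
config-exposed because the source model differentiates speed by
maturity without publishing targets or functional form; linearity is
the least-structured choice.  Coverage is never scaled down: baselines
at or above target stay flat.  The counterfactual (flatline) holds the
2015 baseline throughout.

## Costing

All costs are incremental to the flatline; a zero scale-up yields an
empty ledger.  Direct intervention costs follow the ingredients rule
(people reached × units × price × country price index), split into
recurrent commodities and a capital equipment part via each
intervention's capital share, plus a 10% programme-support markup
(the source includes programme support in full without printing a
rate; 10% is a standard planning figure).

**Workforce.** Service minutes under the scale-up path, divided by
99 000 minutes per FTE-year, give the bottom-up PHC requirement; its
ratio to the full-package requirement is applied to a density
benchmark of 8.8 workers per 1000 (chosen so the cohort's needed PHC
density lands in the upper-middle single digits).  Incremental workers
are floored at zero against both the flatline requirement and the
current PHC workforce, so zero scale-up costs nothing and nested
measures cost monotonically more.  Salary: $4 200 per FTE-year × price
index.

**System components.** Infrastructure, equipment, supply chain, cold
chain, information systems, governance, financing, emergency
preparedness, cash transfers and cross-sectoral investment are
per-capita reference bases (US$2014, documented in
`costing.ReferenceParams`) scaled by population, price index, the
measure's allocation shares, and a *scale-up intensity*: the summed
coverage gain of the measure's package normalised by 94 (half the
188-intervention package moving from 0 to 1).  Intensity makes system
costs proportional to the effort actually undertaken — zero under a
zero scale-up, increasing in the nested measures — which is the one
structural assumption added beyond the published rules.  The supply
chain share is the measure's commodity cost over the full package's,
per year.

**Capital redistribution.** Facility and equipment capital is
modelled in 2016–19 at the terminal (2030) intensity and then spread
uniformly over 2020–30, conserving the total exactly; the uniform
schedule is our choice (redistribution is stated, its schedule is
not).

Accounting: amounts are non-negative by construction; grouped totals
must re-sum to line items within 1e-6 relative tolerance (tests use
tighter).

## Impact

The original disease-specific impact models are replaced by a
declared stand-in: intervention *i* averts a fraction
`e_i · Δcov_i(t)` of deaths from its cause group, combined across
interventions on the residual, `1 − Π(1 − e_i·Δcov_i)`, hence never
exceeding the cause's deaths.  Effectiveness values are part of the
synthetic catalog (beta prior, mean ≈ 0.04 per intervention);
**absolute impact magnitudes are therefore not comparable with
published totals** — structure, signs, monotonicity and accounting
identities are the test surface.  Coverage decreases contribute zero
(with a warning).  Tuberculosis, NTD and cancer-screening deaths are
computed in the same way but subtracted from the 2030 death counts in
a separate cell-wise adjustment step, mirroring their
outside-the-main-tool treatment.

**Life tables.** Abridged (0, 1–4, 5-year bands, open 85+),
`qx = n·mx / (1 + (n − ax)·mx)` capped at 1, last interval `qx = 1`
and `Lx = lx/mx`; separation factors `ax = n/2` except 0.3 for the
infant interval (standard demographic practice; unspecified in the
source).  Averted deaths convert to rate reductions via the age
group's mid-year person-years.  Stillbirths are carried as a cause but
excluded from all-cause rates (they are not deaths of the living
population).  The reported life-expectancy gain is the 2030 scale-up
e₀ (sex-averaged) minus the 2015 baseline; with static rates the 2030
flatline equals 2015.  A constant-hazard table reproduces the
exponential closed form e₀ = 1/m within 0.5 years across hazards
0.001–0.1.

**Healthy life-years.** Person-years in cause-specific disabled
states (cases in need not effectively covered) are compared between
scenarios with GBD-scale disability weights (editable via a delimited
table); averted deaths and stillbirths accrue remaining healthy life
expectancy bounded by the 2030 horizon.  HLY from averted deaths in
year *y* count `min(remaining healthy e, 2031 − y)` years.

## Financing

Business-as-usual extrapolates each country's OLS trend of CHE % GDP
(≥3 historical points; clamped to [1, 25]%).  The +1pp/+2pp scenarios
interpolate linearly from the 2019 level to the target in 2030,
**floored at the country's own trend**: a scenario is a funding
increase, so countries already trending above the target path keep
their trend.  (Without the floor, steep-trend countries would receive
*less* under the nominally more ambitious scenario, breaking the
gap-count monotonicity the framework asserts.)  Incremental funds are
per-capita spending above the 2019 level times population, floored at
zero; the gap is `max(0, incremental PHC cost − allocation ×
incremental funds)` with the allocatable share defaulting to 1.0 —
i.e. *all* incremental health funds count against PHC costs, a
deliberately generous default that is prominently configurable.

## Reporting

Guide posts are emitted per income group, per maturity category and
for all countries; per-capita values are population-weighted means
(weight year 2020 by default; the source does not state its weight
year).  The identity *total recurrent per-capita 2030 = current PHC
expenditure + additional recurrent per-capita* holds exactly on every
row.  Display rounding (integer percents, half-up) never enters
internal arithmetic.

## Problem sizes and determinism

The default study conditions are 67 countries × 188 interventions ×
3 measures × 3 scenarios; a full run takes well under a minute on one
CPU and is byte-deterministic in the seed.  Tests exercise the same
conditions plus reduced cohorts for the hand-computed oracle
(5 countries, 2 interventions) and determinism checks.

## Known limitations

* The intervention catalog, effectiveness values and all per-capita
  system bases are synthetic stand-ins; only the published counts,
  shares and identities are authoritative.
* Efficiency gains from reorienting tertiary care to PHC are out of
  scope, as in the source framework.
* Current PHC expenditure is consumed as an input (recurrent only),
  not estimated from health-accounts microdata; guide-post totals are
  correspondingly conservative.
* The eight-group presentation uses the generator's group mix; the
  true 67-country composition is unpublished and configurable.
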