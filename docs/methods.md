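# Methods

This note documents the model implemented by `tfamm`, the choices made
where the design was genuinely open, and what the bundled data do and do
not represent.

## Model structure

The engine is a comparative risk assessment (CRA) scenario model of the
same family as PRIME-style and burden-of-disease macrosimulations: a
single dietary risk factor (industrially produced trans fat from PHO)
linked to two mortality outcomes (CHD and stroke) in a population of
adults 25+, stratified by sex and twelve 5-year age groups (25–29 …
80+). It is a comparative-statics model: it compares annual deaths under
the baseline exposure with deaths under a counterfactual exposure in the
same year. It has no time dimension — no lag between exposure change and
mortality response, no cohort dynamics — and no morbidity component
(no YLD/DALY, no quality-of-life weighting).

**Exposure.** Per-capita TFA intake is reconstructed from PHO market
volumes: each use channel (bakery, dairy/ice cream, confectionery,
breads/cereals, food commerce, household oils) carries a PHO mass
(g/person/day) and a TFA fraction of its fat. Market data carry no
age/sex detail, so the TFA mass is uniform across strata; the percent of
energy may still differ by stratum if stratum-specific energy intakes
are supplied (the bundled data use one national mean). Intake as % of
energy (9 kcal per gram of fat) is modelled as log-normal across
individuals, parameterized by its arithmetic mean and a coefficient of
variation (CV), and discretized by CDF increments onto 25 bins of width
0.1% from "<0.1" to ">2.4"; the open top bin absorbs the upper tail and
is represented by an effective midpoint of 2.45 (configurable).

**Dose-response.** Relative risk is log-linear in exposure:
`RR(x) = RR^((x−y)/u)` with `u = 2` (% energy) and `y = 0.05` (the
first-bin midpoint, where RR ≡ 1). The bundled CHD table is the
prospective-cohort meta-analysis per 2% energy: 1.42 (1.28–1.57) at
25–34, 1.40 (1.27–1.54), 1.33 (1.22–1.45), 1.27 (1.18–1.36), 1.22
(1.15–1.29) and 1.16 (1.11–1.21) at 75+. Below the TMREL (default 0)
and below `y`, RR clamps to exactly 1: "minimum theoretical risk of
zero" is read as zero *excess* risk, since RR = 0 is undefined in a
multiplicative model, and no protective extrapolation is allowed.

**Stroke from CHD.** The convention "stroke risk is half of CHD" is
implemented as excess-risk halving, `RR_stroke = 1 + (RR_CHD − 1)/2`
(default), with a log-scale alternative `sqrt(RR_CHD)` as a switch.
Literal division by two would turn a harmful exposure protective and is
not offered. Whether the original convention halved on the excess or
the log scale is not documented; the two differ by < 1% in RR here.

**Burden.** Per outcome × sex × age stratum:
`PIF = (ΣRRᵢPᵢ − ΣRRᵢP′ᵢ)/ΣRRᵢPᵢ` over the bins, `DPP = PIF × deaths`,
`YLL = DPP × L(age)`, `YPLL = DPP × max(0, pension_age − age_mid)` and
`cost = YPLL × wage × LFPR(sex, age)`. The representative age of death
in a stratum is its midpoint (42.5 for 40–44; 82.5 for 80+). Pension
ages default to 65 (men) and 60 (women), workforce entry at 15; there is
no discounting or wage growth (a deliberate simplification — the
human-capital valuation is undiscounted present-year productivity). CHD
and stroke are computed independently and summed, with no interaction or
competing-risk adjustment. Deaths are exact counts; stochasticity enters
only through the uncertainty module.

## Scenarios

A scenario is an ordered list of rules, each a glob pattern over channel
ids with an action: `cap` (TFA fraction of fat becomes `min(old, L)`)
or `eliminate` (TFA fraction becomes 0; PHO mass is unchanged, standing
in for replacement with unhydrogenated fats). The first matching rule
wins, which lets a specific rule precede a `*` catch-all; an unmatched
channel is a configuration error. Applying a scenario twice equals
applying it once.

## Monte Carlo uncertainty

Each of the 5,000 default draws samples:

- one RR per outcome × age band from a log-normal whose median is the
  point RR and whose sigma is `(ln CI_hi − ln CI_lo)/(2·1.96)` — the
  standard sampling model for ratio measures. Draws are perfectly
  correlated across exposure bins within a band (they share the sampled
  RR) and independent across bands and outcomes; the true correlation
  structure of the meta-analytic estimates is unknown, and this choice
  is the conventional middle ground.
- one multiplicative factor, normal with mean 1 and a relative standard
  error of 5% (configurable), applied jointly to the baseline and
  counterfactual exposure means — market-volume error moves both sides
  of a scenario. Prevalence bins are re-derived from each sampled mean
  rather than perturbed directly, keeping every draw a valid log-normal.

The full pipeline is recomputed per draw; 95% UIs are empirical
2.5th/97.5th percentiles with linear interpolation and no bias
correction. Point estimates are computed at the central parameter
values, not the draw mean. A fixed seed gives bit-identical results;
UI endpoints move by well under 2% when the draw count grows tenfold.

## Deterministic sensitivity

Three standard variants ship as defaults: TMREL raised to 0.2% of
energy, and all relative risks scaled by 0.9 / 1.1. RR scaling acts on
the excess risk (`RR′ = 1 + f·(RR − 1)`) by default; a multiplicative
mode (`RR′ = f·RR`) is available but is a much stronger perturbation —
×0.9 pushes the small stroke RRs below 1 (protective), which the engine
reports as negative DPP rather than masking. On the calibrated bundle
the excess-risk variants move total DPP by about −9% / +9%, and the
TMREL variant is negligible for the PHO-ban scenario because almost no
baseline exposure mass lies below 0.2% of energy.

## The calibrated Brazil-2018 bundle

The bundle emulates a country case study whose exact inputs are not
public at model granularity. Its construction, in order:

1. **Channels.** Six channels with fixed PHO masses summing to
   5.8 g/day (2.5 g/day in household oils); relative TFA fractions are
   rescaled so total TFA intake is exactly 1.2 g/day. The national mean
   energy intake, 1,588 kcal/day, is *back-solved* from the published
   chain (1.2 g/day ≡ 0.68% of energy) and should be read as an
   effective denominator, not a dietary-survey estimate.
2. **Scenario caps.** The nominal regulatory limits (2% of a food's
   total fat for oils/margarines, 5% for other foods; 2% universal) act
   on the final food's fat base, which market data do not carry. The
   bundle therefore solves *effective* caps on the TFA share of PHO fat
   (scalar root-finding) so that scenario A lands on 0.57% of energy and
   scenario B on a 54.6% intake reduction (0.31%), keeping the nominal
   5:2 ratio between the food and oil caps in scenario A. The published
   "14–16%" reduction attributed to scenario A is internally
   inconsistent with its own printed 0.57% (which implies 16.2%); the
   bundle follows the printed exposure value.
3. **Mortality.** Deaths follow a log-normal-in-age bump (peak ≈ 78 y)
   with one exponential tilt parameter, solved so the PHO-ban scenario
   yields 21.1k YPLL; four outcome × sex scalars then match the ban's
   published DPP splits (CHD 3,300 M / 3,500 F; stroke 1,900 M /
   1,800 F). The resulting total, ≈236k CVD deaths/year among adults
   25+, is consistent with Brazil's 2018 vital statistics.
4. **Life table and wage.** A Brazil-shaped residual-life-expectancy
   profile is scaled (×0.45) so the ban yields 75.5k YLL, and the mean
   annual wage (≈US$10.3k) is solved so the ban's productivity saving is
   US$166.75M. The published YLL per averted death (≈7.2 years) is far
   below any period or aspirational life table under any plausible age
   mix of averted deaths, so the scaled profile must be read as an
   effective valuation schedule, not demography — this is the bundle's
   most artificial element.

Scenarios A and B and all sex-specific cost splits are *emergent*: the
pipeline produces DPP ≈ 1,900 / 6,300, YLL ≈ 13.5k / 45.1k, YPLL ≈
3.8k / 12.7k and savings ≈ US$30.1M / 100.1M, each within ~7% of the
published 2.0k / 6.3k, 14.5k / 45k, 4.1k / 12.6k and US$32.1M /
100.2M. That agreement — two partial-coverage scenarios reproduced from
a calibration that only pins the full-elimination endpoint and the
intake chain — is the substantive regression evidence; the regression
tests therefore hold the intake chain to printed precision and the
scenario burdens to a ±10% calibration slack. One published quantity is
not reproducible: the sensitivity span "−7% (lower RR) to +17% (higher
RR)". Excess-risk ±10% scaling gives −9.1%/+9.0% (lower bound within 2
points, upper off by 8) and multiplicative scaling gives −73%/+65%; no
scaling convention produces an asymmetric −7/+17, and the corresponding
check is left failing rather than fitted.

## Synthetic data

`make_synthetic_bundle` draws stratum populations and an age-increasing
mortality profile reproducibly from a seed, with exact exposure and risk
parameters, and computes the implied DPP by continuous quadrature
(20,000-point grid) of the same log-normal/log-linear model. It
emulates the *structure* of real inputs — strata, channels, scenarios —
but none of their messiness: no reporting error in deaths, no
miscoded ages, no heaping, no correlation between exposure and
mortality data quality. Recovery tests on it therefore validate the
numerics (discretization, aggregation, scenario algebra), not the
model's epidemiological adequacy on real data.

## Numerical choices and limitations

- Bin masses are CDF increments; the top bin absorbs the tail. The
  binned mean tracks the analytic log-normal mean within 2% for means
  in [0.2, 1.0] % of energy and CV in [0.2, 0.6]; accuracy degrades
  below that range (bins coarse relative to the mean) and above it
  (top-bin truncation). The 25-bin PIF agrees with 2,500-bin quadrature
  within 1% for baseline means up to ≈0.8% of energy — comfortably
  covering the 0.68% operating point.
- The exposure CV is not identified by market data and defaults to 0.5;
  the PIF is only weakly sensitive to it under a log-linear RR, but it
  is an explicit parameter, not a hidden constant.
- A mean of exactly 0 produces a degenerate distribution with all mass
  in the first bin (RR ≡ 1), so a PHO ban yields PIF = PAF exactly.
- `brentq` root-finding tolerances and the 5e-3 relative calibration
  gate are fixed in `fixtures.py`; calibration failure raises rather
  than returning a silently drifted bundle.
- Problem sizes used throughout (25 bins, 12 age groups × 2 sexes × 2
  outcomes = 48 strata, 5,000 draws, 200-replicate coverage experiments
  at 400 draws) keep a full run in seconds while leaving percentile
  noise well inside the tolerances tested.
- Outputs are annual and static: no lag structure, no compounding of
  scenario effects over years, no absenteeism/presenteeism costs, no
  ruminant TFA, and no dietary-survey ingestion — intake derives from
  market data by design.
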