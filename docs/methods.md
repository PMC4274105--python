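# Methods

`pollenbeetle` is a stochastic, spatially explicit, individual-based model of
the evolution of pyrethroid resistance in pollen beetle (*Meligethes
aeneus*) populations on oilseed rape (OSR) landscapes. This note documents
the model, its parameters, the numerical choices, and what the synthetic
components do and do not capture.

## Model overview

The landscape is a torus of 1-ha cells (default 10x10: 80 arable fields, 10
wild-host refuges, 5 overwintering habitats, 5 empty). Arable fields grow
OSR once in a strict 4-year rotation (phases staggered uniformly at
random), spring-sown (SOSR) with probability 5% (25% in the W75 scenarios),
winter-sown (WOSR) otherwise. Weather is uniform across the landscape; all
development is driven by thermal time (degree-days, base 0 degC) and day
length.

The beetle is univoltine. Hibernating adults leave the overwintering cells
when the daily mean temperature exceeds 9 degC on five consecutive days,
feed for 400 dd, then reproduce for 1000 dd and die of old age. Females
mate once (probability per day rises with male density in the cell,
calibrated so that 50% of females are mated after 3 days at 25 males/m^2),
store the mate's genotype, and lay up to 10 batches of Uniform{15..35} eggs
every 85 dd — 250 eggs on average. Offspring genotypes follow single-locus
Mendelian segregation. Eggs, larvae and pupae develop in 100, 250 and 600
dd. The new generation feeds without mating and moves to the overwintering
habitat when the daily mean falls below 12 degC on five consecutive days
(after midsummer; forced on 1 November otherwise).

Natural mortality combines two independent competing risks
(multiplicatively on survival): a background hazard fixed so each juvenile
stage loses an expected 33% (so 1 - 0.67^3 ~ 70% from egg to adult), and a
density-dependent hazard active above a threshold density K (insects per
host plant) that relaxes back to K with time-constant T. Larvae: K =
100/62 insects per plant (OSR/wild), T = 5 d. Adults: K = 100/62 before
winter (T = 100 d) and 70/44 after (T = 50 d). Eggs and pupae are exempt
from density mortality; adults have no background mortality.

Adults move daily. In a host-free cell movement is forced; otherwise the
daily probability is piecewise linear in adult density — maximal (0.35 on
OSR, 0.65 on wild hosts) at low density, declining to 0.05 between the
first two knots, flat, then returning to the maximum as crowding sets in
(knots 2.5/10/70/100 per plant on OSR, 1.5/6.2/44/62 on wild hosts).
Destinations are sampled with probability proportional to attractiveness
over torus distance (V/d^alpha, alpha = 1): flowering OSR V = 1, wild hosts
V = 0.2; the autumn relocation uses the overwintering cells instead.
Movement is instantaneous at the end of the daily step; juveniles never
move.

Insecticide efficacy is 1 for `Dmax` days after application and declines
linearly to 0 over `Ddecl` days. Exposure follows Haber's rule: the dose
over a step is the time-integral of efficacy of all active treatments in
the cell. Dose times a genotype-specific susceptibility factor S gives a
damage increment, mapped to mortality by a cumulative hazard
(P = 1 - exp(-damage)); damage resets once no treatment covers the cell.
Heterozygote susceptibility is the dominance-weighted homozygote average
S_RS = (w S_RR + S_SS)/(w + 1). The lambda-cyhalothrin preset carries the
field-trial calibrated values (Dmax 4.7 d, Ddecl 6 d, S_SS 0.86, S_RR
0.003, w 48.6); pymetrozine (1.5 d, 10.6 d, S_SS 0.72) shares the
resistance parameters for sensitivity runs. Farmers spray either on
calendar dates (10, or 10 and 20, days after the field's flowering onset)
or when scouted adult density reaches a per-crop threshold (15/plant WOSR
and 5/plant SOSR for the high threshold; 5/plant for the low), at most
twice per field-season, with a re-treatment gap of one full efficacy span.

A *resistance outbreak* is the first day starting at least 183 consecutive
days with the R-allele frequency (over all living individuals) above 50%,
reported in years as day/365.25. Scenario experiments run one simulation
per combination of independently seeded landscape arrangements and weather
series (6 x 6 by default) and summarise the distribution of outbreak years.

## Super-individual representation and scaling

The population is held as cohorts: groups identical in cell, stage, adult
phase, sex, genotype, thermal age, mating state and accumulated damage,
with integer counts. All stochastic fates are binomial/multinomial per
cohort, which is exact in distribution because every rate in the model is
per-individual. Cohorts are re-merged daily after bucketing thermal age (5
dd, configurable) and damage (0.01). A population scale factor (default
1e-3 for desk runs) multiplies the initial count (1e9) while every density
is computed as count/(scale x plants), so per-plant and per-m^2 densities —
and hence all rates — are unchanged by scaling. What scaling does change is
demographic noise (stronger drift, and possible extinction of heavily
suppressed populations that would persist at full scale).

## Synthetic weather

Real runs of such models use a stochastic weather generator calibrated to
station records; here daily means are an annual sinusoid plus AR(1) noise,
with day length from the standard solar-declination formula. Site presets
("rothamsted-like", "brooms-barn-like", "berlin-like") differ in annual
mean, amplitude and latitude, with Berlin more continental (colder winter,
warmer summer). The day-to-day standard deviation (3.2 degC, lag-1
autocorrelation 0.7) was set so that 5-day warm spells fire the spring
trigger in March–April, as observed for the real system — with little
short-term variability a smooth sinusoid would not cross 9 degC until late
April and the whole phenology would lag. The generator does not reproduce
rainfall, wind, inter-annual regimes or observed extremes; conclusions
about absolute dates or about site differences are only qualitative.

## Crop phenology

A parametric thermal-time/photoperiod model: emergence 120 dd after sowing;
flowering once thermal time since emergence reaches a crop-specific
requirement (WOSR 1400 dd, SOSR 550 dd) *and* day length is at least 12.5 h;
flowering ends after 700 dd. Defaults were chosen so that, under the
maritime preset, WOSR sown around 1 September flowers from mid-April to
mid-June and SOSR sown around 1 April flowers June–July, reproducing the
seasonal flowering-area profile of the study system and its overlap with
the beetle's reproductive period. Sowing dates vary uniformly within a week
of the nominal date, which staggers flowering onsets across fields; the
photoperiod threshold is low enough that thermal time, not day length, sets
the onset (a binding photoperiod gate would synchronise every field to the
same calendar day and make density thresholds fire everywhere at once).

## Numerical and design choices

- **Sub-step order** within a day: weather, sowing/phenology, seasonal
  transitions, treatment decisions, insecticide mortality, natural
  mortality, development, mating/oviposition, movement. Treatment decisions
  therefore see pre-mortality densities; movement is last and cannot
  cascade.
- **Mating hazard**: the published description fixes only the two
  half-saturation constants; implemented as the memoryless exponential
  hazard p = 1 - 0.5^((d/d50)(dt/t50)), which reproduces both anchors and
  is monotone in density.
- **Density mortality**: the published semantics are "time T required to
  decline to the threshold K". Two forms are provided: survival
  (K/d)^(dt/T) (default) and linear excess removal, deaths (d-K)/T per day
  (`density_form="excess"`). With density recomputed each step — the
  behaviour chosen here, since recruitment is continuous — both decay the
  excess toward K exponentially with time-constant T rather than reaching K
  at exactly T.
- **Exposure**: only foliage-active stages (larvae and non-hibernating
  adults) receive dose from a contact insecticide; eggs inside buds and
  pupae in the soil are concealed.
- **Season's end**: the autumn trigger retires the spent parental
  generation; juveniles keep developing and relocate on emergence, and any
  still immature on 1 November die (univoltine winter kill). An early cold
  spell therefore delays, rather than destroys, the new generation.
- **Cumulative-hazard kill mapping**: chosen so survival depends only on
  total integrated exposure, never on how steps are partitioned, and so the
  damage-reset rule is well defined.
- **Old age**: adults die at the end of the 1000-dd reproduction window;
  the fraction of all insects reaching old age is an emergent output (a few
  per mil to a few percent depending on conditions), not a fitted quantity.
- **Seeds**: three independent streams (landscape, weather, demography) so
  the Monte Carlo axes vary independently; everything is bit-reproducible
  from the seeds.

## Virtual plot trials and calibration

The calibration harness simulates one field of 3 check + 3 treated plots
with 150,000 individually tracked insects, Hardy-Weinberg genotypes at a
configured R frequency (0.5/25/55% for the low/moderate/high resistance
classes), 40% daily movement with uniformly random destination plots, and
insecticide mortality in treated plots only. Daily control is
100 x (1 - mean treated count / mean check count), recorded after the day's
mortality and before the end-of-step movement. No natural mortality is
simulated inside a trial: it would apply equally to both arms and cancels
from the ratio in expectation. The calibration objective is RMSE normalised
by the mean observed control, averaged over resistance classes; the
optimiser is pluggable with scipy's differential evolution as default. In
self-calibration experiments (observations generated by the simulator
itself) the fit recovers S_SS to within 0.1 and the dominance weight within
a factor of two; w is weakly identified above ~20 because heterozygote
susceptibility saturates.

## Known limitations

- The published account of the source system reports ~75% egg-to-adult
  mortality alongside 250 eggs per female at demographic equilibrium; these
  are mutually inconsistent for a closed population (the product of
  juvenile survival, realized fecundity and adult survival must be ~1), and
  this implementation settles at ~97% cohort-mean juvenile mortality, just
  above the 66–96% field range, with the excess absorbed by larval
  crowding. Equilibrium adult numbers (above the 1e9 initialisation) and
  per-plant densities in infested crop (>15 adults/plant) do match the
  published behaviour.
- Resistance spreads faster here (outbreaks in ~4–6 years under dominant
  inheritance at desk scale) than the published 12–17 years; the *ordering*
  of management scenarios — double calendar fastest, high threshold slowest,
  dominant faster than intermediate, more spring crop no slower — is the
  level at which results are comparable, and is what the tests assert.
- Desk-scale populations (1e-3 and below) can be eradicated outright by
  sustained spraying of a fully susceptible population; at full scale rare
  survivors would persist.
- No wind, rainfall, long-range migration, within-cell structure, farm-level
  rotation constraints, compound mixtures/alternations, or fitness costs of
  resistance.
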