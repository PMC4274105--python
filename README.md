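# pollenbeetle

A stochastic, spatially explicit, individual-based simulator of insecticide
resistance evolution in pollen beetle (*Meligethes aeneus*) populations on
oilseed rape (OSR) landscapes — for researchers in resistance management and
pest ecology who want to compare crop-management strategies *in silico*.

The model couples, on a daily time step:

- a torus landscape of 1-ha cells (arable fields under a 4-year OSR
  rotation, wild-host refuges, overwintering habitats),
- weather-driven insect and crop phenology (thermal time in degree-days,
  base 0 °C, plus photoperiod),
- cohort-based beetle demography: development (egg→larva→pupa→adult in
  100/250/600 dd), density-dependent mating, Mendelian single-locus
  inheritance of a resistance allele, background and density-dependent
  natural mortality,
- density- and host-dependent dispersal with distance/attractiveness
  destination sampling,
- insecticide treatments under calendar or scouting-threshold rules, with
  Haber's-rule dose integration over a plateau-then-linear-decline efficacy
  curve and genotype-specific susceptibility
  `S_RS = (w·S_RR + S_SS)/(w+1)` (dominance weight *w*),
- a Monte Carlo harness measuring the time until a *resistance outbreak* —
  the R-allele frequency exceeding 50 % for at least six months.

A population scale factor maps the field-scale initial population (10⁹
insects) to desk-scale runs while leaving every per-plant density, and hence
every rate, unchanged. See `docs/methods.md` for the full model description
and its limitations.

## Worked example

```python
import pollenbeetle as pb

cfg = pb.SimulationConfig(
    years=20, scale=1e-3,          # 10^6 insects standing in for 10^9
    strategy="HT",                 # spray at 15 (WOSR) / 5 (SOSR) adults per plant
    dominance_w=48.6,              # dominant resistance allele
    landscape_seed=0, weather_seed=1, demography_seed=2,
)
res = pb.run_simulation(cfg)
print(res.summary())
```

prints

```
{'outbreak_year': 3.780971937029432, 'final_q': 0.9957089708431194,
 'n_treatments': 735, 'years': 20, 'scale': 0.001, 'strategy': 'HT',
 'p_sosr': 0.05, 'dominance_w': 48.6}
```

Starting from an allele frequency of 0.1 %, threshold-triggered spraying of
the flowering crop drives the resistance allele above the 50 % outbreak
criterion about 3.8 years into this run (desk-scale dynamics are faster than
the published field-scale system; scenario *orderings* are the comparable
quantity), and by year 20 the allele is essentially fixed (`final_q` ≈ 1.0).
`res.trajectory_frame()` gives the daily allele frequency and stage counts,
`res.treatments_frame()` the per-field spray log.

Scenario comparison across a landscape × weather factorial:

```python
design = pb.MonteCarloDesign(
    n_landscapes=3, n_weather_series=2, master_seed=11,
    scenarios={
        "C1": {"strategy": "C1", "dominance_w": 48.6},
        "C2": {"strategy": "C2", "dominance_w": 48.6},
    },
)
runs = pb.run_monte_carlo(design, pb.SimulationConfig(years=30, scale=1e-3,
                                                      stop_at_outbreak=True))
print(pb.summarize_monte_carlo(runs, censor_years=30)[["median", "mean"]])
```

```
          median      mean
scenario
C1          5.31      5.31
C2          3.82      3.34
```

Two calendar sprays per season (C2) select for resistance faster than one
(C1), the pattern the model is built to rank.

A command-line interface mirrors the library:

```bash
pollenbeetle simulate --seed 1 --scale 1e-3 --out-dir out/
pollenbeetle montecarlo --scenario C2=C2,0.05,48.6 --landscapes 3 --weather-series 2
pollenbeetle trial --compound lambda-cyhalothrin --r-freq 0.005
pollenbeetle make-weather --site berlin-like --years 50 --out weather.csv
```

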