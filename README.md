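# careimmune

An agent-based model of how care giving for the sick could have shaped the
evolution of immune strategies in hominins, together with the factorial
simulation experiment and regression analysis used to interrogate it.

Life-history theory predicts a trade-off between the two arms of the
immune system: **innate** responses are cheap to develop but costly every
time they are deployed, while **acquired** responses carry a high up-front
cost, an immunological memory, and cheap re-deployment. Care behaviours —
provisioning sick kin, and protecting them from extrinsic hazards — change
exactly the variables (nutrition, pathogen exposure, extrinsic mortality)
that this trade-off turns on. `careimmune` puts a population of foraging,
asexually reproducing hominins on a 40 × 40 resource grid, lets a socially
transmitted disease circulate through it, makes the innate/acquired
*priority* a heritable trait, and measures which strategy spreads over
~50 generations under 144 combinations of care intensity, disease
mortality, transmissibility and extrinsic mortality.

The package is aimed at evolutionary anthropologists and modellers of
life-history / host–pathogen dynamics who want a fast, reproducible,
fully-tested reimplementation of this class of model in scientific Python.

## The model in brief

Each time step (one year), in order: patches regrow (suspended while the
population exceeds 150), agents age and forage (adults take a full
10-point patch, children take 5), the disease spreads (one Bernoulli draw
at transmissibility *p* per susceptible with an infected neighbour within
radius 5; immunological memory blocks contact infection), kin give care
(an agent may nurse one infected parent/offspring per step, transferring
the care intensity *k* ∈ {0, 10, 20} and shielding the recipient from
extrinsic mortality), extrinsic mortality strikes uncared-for agents while
the population exceeds 150, the infected roll disease mortality and then
fight the infection (innate: pay 5; acquired first use: pay 10 if holding
> 10, gaining a 5-year memory at 1/year upkeep; recall: pay 1), the
disease is re-seeded into half the population if it went extinct, adults
with > 20 points pay 20 to reproduce (strategy inherited with
probability 0.75, capped at 200 agents), and the old (≥ 60) and starving
die. Runs last 750 steps; runs that go extinct or reach 100% prevalence
halt and are excluded from analysis.

The endpoint analysis averages the final 100 steps of each run, averages
replicates within each parameter cell, and fits ordinary least squares
with standardized coefficients (β = b·SD(x)/SD(y)) for disease
prevalence, the acquired/innate shares within each care stratum, the age
structure, and the reproductive rate.

## Worked example

```python
from careimmune import ParameterSet, run_single, summarize_run

params = ParameterSet(
    care_intensity=10, disease_mortality_pct=10,
    transmissibility_pct=50, extrinsic_mortality_pct=5,
)
result = run_single(params, seed=42)
print("completed:", result.completed, "steps:", result.n_steps)
print(summarize_run(result).round(1))
```

prints

```
completed: True steps: 750
prevalence            23.3
rate_of_care          51.0
pct_acquired          51.8
pct_innate            48.2
pct_immature          67.1
pct_mature            32.9
reproductive_rate     26.4
mean_population      186.6
```

Reading the numbers: over the last century of this run, 23.3% of the
population caught the disease in an average year, half of the infected
received kin care, 51.8% of agents prioritized acquired immunity, the
population was two-thirds children (care and provisioning keep the young
alive), about a quarter of adults reproduced each year, and the population
hovered near 187 of the 200-agent carrying capacity. Identical
`(params, seed)` pairs reproduce this table bit-for-bit.

The same pipeline from the shell:

```bash
careimmune simulate --seed 42 --out out/single      # one run
careimmune sweep --replicates 5 --master-seed 1 --out out/sweep
careimmune analyze --summaries out/sweep/summaries.csv --out out/tables
careimmune plot --trajectories out/sweep/trajectories.csv --out out/figs
careimmune reproduce-study --replicates 5 --master-seed 1 --out out/repro
```

`sweep` writes `summaries.csv` (one row per surviving parameter cell),
`per_run.csv`, `excluded.csv`, `trajectories.csv` and a `meta.json` with
every seed needed to reproduce any single run. `analyze` writes one CSV
per regression (predictor, |β|, t, p) plus `models.csv` (R², F, df, n).

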