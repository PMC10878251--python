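# Methods

`careimmune` simulates the coevolution of kin-directed care giving and
immune strategy in a small hominin population, and analyses the simulated
endpoint the way a factorial in-silico experiment is analysed: many
independent runs over a full parameter grid, last-window averaging, and
standardized multiple regression on the per-cell summaries.

## The model

### Habitat and foraging

The habitat is a bounded, non-wrapping 40 × 40 grid of resource patches
(one patch ≈ 5 km², one time step = one year). A full patch holds 10
resource points. Each step, every patch holding less than 10 is reset to
10 — *unless* the population exceeds 150 agents, in which case regrowth is
suspended entirely, representing a population pressing against the
carrying capacity of its environment.

Agents forage once per step, in a freshly randomized order. An agent may
move to any patch within Euclidean distance 5 of its position (the grid
does not wrap; a torus option was considered and rejected to keep the
habitat area fixed at 8000 km²). Adults (age ≥ 15) require a full patch,
harvest 10 points and exhaust the patch for the step. Children require a
patch holding at least 5, harvest 5, and the patch is closed for the step
only once it drops below 5 — so a child's leftovers can feed one more
child but never an adult. An agent that finds no eligible patch stays
put, earns nothing, and is flagged as having failed to forage.

### Disease

A socially transmitted disease circulates. Each step, every susceptible
agent with at least one infected agent within Euclidean distance 5 takes a
single Bernoulli draw at the transmissibility probability (one draw per
susceptible, not one per infected neighbour). Agents infected this step do
not transmit until the next step. Agents holding immunological memory (see
below) cannot be infected by contact while the memory clock runs.

Whenever prevalence reaches zero, the disease is re-seeded by infecting
half the living population (rounded up), chosen uniformly at random.
Re-seeding deliberately ignores memory: it models re-introduction from
outside the community, and it keeps the cheap-recall pathway of acquired
immunity exercised. The model is a tool for studying immune strategy under
*endemic* disease, not for studying whether a disease establishes.

The step's infected count is censused immediately after transmission — at
the year's infection peak, before any infections are fought off. This
census is the numerator of disease prevalence, the denominator of the rate
of care, and the trigger of the 100%-prevalence halt. A separate
end-of-step count (`n_infected_end`) records who is still sick at the end
of the year. The choice matters: most infections in this economy are
cleared the same year they are caught, so an end-of-step census sees only
the residue.

### Immunity

Each agent carries one heritable trait: whether it *prioritizes* innate or
acquired immunity. When an infected agent fights the disease (once per
step, after a disease-mortality roll at the configured percentage), it
deploys its prioritized arm with probability 0.75 and the other arm
otherwise, re-drawn each step:

- **Innate**: pay 5 points, clear the infection, gain nothing else.
  Unaffordable → remain infected and face next year's mortality roll.
- **Acquired, first exposure**: requires *strictly more than* 10 points;
  pay 10, clear, and record the disease for 5 steps of immunological
  memory. Otherwise remain infected.
- **Acquired, recalled**: with live memory, pay 1 point and clear; the
  memory clock is not refreshed.

Memory costs 1 point per step of maintenance, charged from the step after
it is gained, so a fresh memory spans exactly five usable years and five
payments; an agent that cannot pay loses the memory at once. While the
clock runs the agent is immune to contact infection (but not to
re-seeding).

### Care

Care flows along the parent–offspring bond in both directions. Each step,
in randomized order, every agent may nurse at most one infected relative
(parent or own offspring) that has not yet been cared for this step,
chosen uniformly at random. At care intensity *k* > 0 the carer must hold
at least *k* points and transfers exactly *k* (no partial care); at *k* =
0 care is pure protection with no transfer. A cared-for agent is shielded
from extrinsic mortality for the remainder of the step. One recipient can
receive care from at most one carer per step.

### Demography

Agents age at the start of each step and die at 60. Extrinsic mortality
(predation, accidents) operates only while the population exceeds 150:
each uncared-for agent then dies with the configured probability.
Reproduction is asexual: adults aged 15–44 holding strictly more than 20
points pay 20 and produce one offspring (age 0, no resources, parent's
patch, uninfected). Offspring inherit the parent's strategy with
probability 0.75. Births stop the moment the population reaches the
carrying capacity of 200; at most one birth per agent per step. At the end
of the step, agents that hold zero resources *and* failed this year's
forage attempt die of starvation (newborns made no attempt and are
exempt).

### Initialization and runs

A run starts with 100 agents at uniform-random patches, uniform integer
ages 0–60, a fair coin for strategy, and empty resource scores. For five
warm-up years agents only age and forage; then half the population is
infected. A run lasts 750 steps (~50 generations) and halts early — and is
excluded from all analysis — if the population dies out or the infected
census covers every living agent.

## The experiment

The factorial sweep crosses care intensity {0, 10, 20} × disease mortality
{0, 5, 10, 15}% × transmissibility {25, 50, 75}% × extrinsic mortality
{0, 1, 5, 10}% — 144 cells. Replicate *r* of cell *c* is seeded from
`SeedSequence((master_seed, c, r))` (31-bit), so any run can be reproduced
in isolation and execution order is irrelevant. Each completed run is
summarized by the mean of the emergent variables over its final 100 steps;
cell summaries average completed replicates. The default replication in
this package's reproduction pipeline is 5 per cell (720 runs, a few
minutes on one CPU); the reference experiment used 100.

Emergent variables (all percentages): disease prevalence (infected census
over census population), rate of care (cared-for over infected census),
acquired- and innate-priority shares, immature (< 15) and mature shares,
and reproductive rate (reproducing mature agents over mature agents).

## The analysis

`fit_standardized_ols` fits ordinary least squares with an intercept via
statsmodels and reports coefficients on the standardized scale
(b·SD(x)/SD(y)); t and two-sided p values come from the unstandardized fit
(they are identical), with model-level R² and F. Tables print |beta| with
the sign carried by t, alpha = 0.05, no multiple-testing correction.
Constant predictors are dropped with a warning; rank-deficient designs
raise an error naming the collinear columns. The suite fits: prevalence on
the swept parameters plus rate of care (all cells); the acquired- and
innate-priority shares within each care stratum on disease
characteristics, prevalence and rate of care; and the age-structure and
reproductive-rate models (all cells). Within a care stratum the care
intensity is constant, so the stratum models use rate of care in its
place. Complementary responses (acquired/innate, immature/mature) obey an
exact mirror identity — equal R², F, |t|, |beta|, opposite t signs — which
the tests assert.

## Numerical and implementation choices

- All state lives in flat numpy arrays (capacity 200 slots, recycled on
  death). One `numpy.random.Generator` (PCG64) per run drives every draw,
  so a (parameters, seed) pair fixes the full trajectory bit-for-bit.
- Foraging and care are the only phases with within-step contention; they
  are numba kernels iterating in a randomized order, with all randomness
  (a permutation plus one uniform per slot) supplied by the caller. The
  uniform-among-k choice uses `floor(u·k)`.
- Every expenditure is guarded: resource scores never go negative.
- Ties and degenerate inputs: an empty eligible-patch set fails the forage
  attempt; zero infected gives rate of care 0; an empty population makes
  the emergent variables undefined (rejected); `full_prevalence` is only
  flagged for a non-empty census.
- Per-step bookkeeping tallies (income, combat, maintenance, birth costs,
  resources removed by death) make an exact conservation ledger testable:
  the change in total resources each step equals income minus those sinks,
  with care transfers cancelling.

## What the simulation does and does not establish

The generator *is* the study system: all inputs are simulated, so the
tests establish internal properties (conservation, caps, contact
geometry, window pricing, heritability frequencies, regression
correctness) and the qualitative response surface of *this* model —
e.g. extrinsic mortality strongly increases the immature share, disease
mortality increases the acquired-priority share within provisioning
strata, and mortality pressure raises the reproductive rate. Nothing here
measures real hominin populations.

Two quantitative regimes of the original study do not emerge under this
implementation of the written model description: a grand-mean disease
prevalence near 42% with very large between-cell spread, and an
acquired-priority share near 65% in all care strata. In this
implementation the foraging economy is productive enough that almost all
infections are cleared in the year they are caught; prevalence is then
governed by the extinction/re-seeding cycle (self-regulating at roughly
20–25% of the census) and the two strategies are nearly neutral, drifting
around 50%. Sustaining the reference values would require a long-lived
pool of agents unable to afford clearance for years at a time, and no
reading of the written mechanics we tested (transmission compounding,
episode-locked arm choice, capacity-check timing, starvation variants)
produces that pool. The reproduction pipeline therefore reports these
quantities as measured, and the corresponding endpoint checks document the
discrepancy rather than masking it.

## Known limitations

- No within-host dynamics, single pathogen, no pathogen evolution, no
  sexual reproduction, no developmental plasticity of immune investment.
- The sweep executes serially; runs are seed-independent, so
  parallelization would be trivial but is intentionally left out.
- Trajectory plots are a qualitative aid; no statistics are computed from
  them.
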