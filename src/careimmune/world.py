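"""World state and the complete yearly update schedule.

The habitat is a bounded (non-wrapping) 40x40 grid of resource patches; the
population is a roster of at most ``carrying_capacity`` agents held in flat
numpy arrays (a slot is reused once its occupant dies).  One call to
:meth:`WorldState.advance_step` runs the full schedule for one simulated
year:

    clear per-step flags -> patch regrowth -> aging -> foraging ->
    disease transmission -> kin care -> extrinsic mortality (N > 150) ->
    combat (disease-mortality roll, then immune response) ->
    memory maintenance -> reseed disease if extinct -> reproduction ->
    old-age / starvation cull -> record step

Every stochastic draw of a run comes from a single ``numpy.random.Generator``
seeded at construction, so equal (params, seed) gives identical trajectories.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._kernels import care_kernel, forage_kernel, radius_offsets
from .params import ACQUIRED, INNATE, ParameterSet

__all__ = [
    "WorldState",
    "StepRecord",
    "initialize_world",
    "choose_modality",
]


@dataclass(frozen=True)
class StepRecord:
    """Per-step census and bookkeeping tallies.

    ``n_infected`` is the step's infected census, tallied after transmission
    (when the year's infections are at their peak, before any are fought
    off); it is what disease prevalence, the rate-of-care denominator and
    the 100%-prevalence halt are computed from.  ``n_infected_end`` is the
    diagnostic count of agents still infected at the end of the step.
    All other population counts are taken at the end of the step (after the
    cull).  The cost tallies make the resource ledger exactly checkable:

        sum(score_after) - sum(score_before)
            = total_foraged - total_combat_cost - total_memory_cost
              - total_birth_cost - total_death_score_loss
    """

    step_index: int
    n_total: int
    n_infected: int
    n_immature: int
    n_mature: int
    n_reproduced: int
    n_cared_for: int
    n_acquired_priority: int
    n_innate_priority: int
    n_deaths_disease: int
    n_deaths_extrinsic: int
    n_deaths_age: int
    n_deaths_starvation: int
    n_infected_end: int
    n_alive_at_census: int
    n_new_infections: int
    n_reseeded: int
    full_prevalence: bool
    total_foraged: int
    total_combat_cost: int
    total_memory_cost: int
    total_care_transferred: int
    total_birth_cost: int
    total_death_score_loss: int
    total_score: int


def choose_modality(strategy, u, use_prob: float = 0.75):
    """Immune arm actually deployed this step.

    With probability ``use_prob`` the agent uses its prioritized arm,
    otherwise the other one.  Accepts scalars or arrays (one uniform
    deviate per agent).
    """
    strategy = np.asarray(strategy)
    return np.where(np.asarray(u) < use_prob, strategy, 1 - strategy)


class WorldState:
    """Mutable simulation state: patches, agent roster, RNG, step log."""

    def __init__(self, params: ParameterSet, seed: int | None = None, rng=None):
        self.params = params
        self.rng = rng if rng is not None else np.random.default_rng(seed)
        cap = params.carrying_capacity
        self.capacity = cap

        # agent roster (slot arrays; a dead slot is recycled for newborns)
        self.alive = np.zeros(cap, dtype=bool)
        self.agent_id = np.full(cap, -1, dtype=np.int64)
        self.parent_id = np.full(cap, -1, dtype=np.int64)
        self.age = np.zeros(cap, dtype=np.int64)
        self.x = np.zeros(cap, dtype=np.int64)
        self.y = np.zeros(cap, dtype=np.int64)
        self.score = np.zeros(cap, dtype=np.int64)
        self.strategy = np.zeros(cap, dtype=np.int64)
        self.infected = np.zeros(cap, dtype=bool)
        self.memory = np.zeros(cap, dtype=np.int64)
        self.cared_for = np.zeros(cap, dtype=bool)
        self.forage_failed = np.zeros(cap, dtype=bool)
        self.memory_gained = np.zeros(cap, dtype=bool)  # set in combat, this step
        self.births_count = np.zeros(cap, dtype=np.int64)
        self.next_id = 0

        # habitat
        self.resources = np.full(
            (params.grid_width, params.grid_height),
            params.patch_max_resources,
            dtype=np.int64,
        )
        self.foraged = np.zeros_like(self.resources, dtype=bool)
        self._offs_dx, self._offs_dy = radius_offsets(params.movement_radius)

        self.step_index = 0
        self.step_log: list[StepRecord] = []

    # ------------------------------------------------------------------
    # roster helpers
    # ------------------------------------------------------------------
    @property
    def n_alive(self) -> int:
        return int(self.alive.sum())

    def alive_slots(self) -> np.ndarray:
        return np.flatnonzero(self.alive)

    def add_agent(
        self,
        x: int,
        y: int,
        age: int,
        strategy: int,
        score: int = 0,
        infected: bool = False,
        memory: int = 0,
        parent_id: int = -1,
    ) -> int:
        """Place one agent in the first free slot; returns the slot index."""
        free = np.flatnonzero(~self.alive)
        if free.size == 0:
            raise RuntimeError("population is at carrying capacity")
        i = int(free[0])
        self.alive[i] = True
        self.agent_id[i] = self.next_id
        self.next_id += 1
        self.parent_id[i] = parent_id
        self.age[i] = age
        self.x[i] = x
        self.y[i] = y
        self.score[i] = score
        self.strategy[i] = strategy
        self.infected[i] = infected
        self.memory[i] = memory
        self.cared_for[i] = False
        self.forage_failed[i] = False
        self.memory_gained[i] = False
        self.births_count[i] = 0
        return i

    def _kill(self, mask: np.ndarray) -> tuple[int, int]:
        """Remove agents under ``mask``; returns (count, resource loss)."""
        n = int(mask.sum())
        if n == 0:
            return 0, 0
        loss = int(self.score[mask].sum())
        self.alive[mask] = False
        self.infected[mask] = False
        self.memory[mask] = 0
        return n, loss

    # ------------------------------------------------------------------
    # schedule phases
    # ------------------------------------------------------------------
    def clear_step_flags(self) -> None:
        self.cared_for[:] = False
        self.forage_failed[:] = False

    def regrow_patches(self) -> None:
        """Reset depleted patches to full unless the population is over the
        regrowth cutoff; per-step foraged flags are cleared regardless."""
        if self.n_alive <= self.params.regrowth_cutoff:
            np.maximum(
                self.resources, self.params.patch_max_resources, out=self.resources
            )
        self.foraged[:] = False

    def increment_ages(self) -> None:
        self.age[self.alive] += 1

    def forage_all(self) -> int:
        """All agents forage in a random order; returns total income."""
        p = self.params
        order = self.rng.permutation(self.capacity)
        u = self.rng.random(self.capacity)
        return int(
            forage_kernel(
                order,
                u,
                self.alive,
                self.age,
                self.x,
                self.y,
                self.score,
                self.forage_failed,
                self.resources,
                self.foraged,
                self._offs_dx,
                self._offs_dy,
                p.adult_age,
                p.adult_forage_yield,
                p.child_forage_yield,
                p.grid_width,
                p.grid_height,
            )
        )

    def transmit(self) -> int:
        """Spread disease from the pre-phase infected set; returns new cases.

        Each susceptible with at least one infected agent within the
        infection radius takes a single Bernoulli draw at the
        transmissibility probability.  Agents infected during this phase do
        not transmit until the next step, and agents holding immunological
        memory cannot be infected by contact while the memory clock runs.
        """
        p = self.params
        u = self.rng.random(self.capacity)
        alive_idx = self.alive_slots()
        inf_mask = self.infected[alive_idx]
        infectors = alive_idx[inf_mask]
        susceptible = alive_idx[~inf_mask & (self.memory[alive_idx] == 0)]
        if infectors.size == 0 or susceptible.size == 0:
            return 0
        dx = self.x[susceptible][:, None] - self.x[infectors][None, :]
        dy = self.y[susceptible][:, None] - self.y[infectors][None, :]
        r2 = p.infection_radius * p.infection_radius
        exposed = ((dx * dx + dy * dy) <= r2).any(axis=1)
        at_risk = susceptible[exposed]
        newly = at_risk[u[at_risk] < p.transmissibility_pct / 100.0]
        self.infected[newly] = True
        return int(newly.size)

    def exposure_set(self) -> np.ndarray:
        """Slots of susceptibles with an infected agent in radius (no RNG)."""
        p = self.params
        alive_idx = self.alive_slots()
        inf_mask = self.infected[alive_idx]
        infectors = alive_idx[inf_mask]
        susceptible = alive_idx[~inf_mask & (self.memory[alive_idx] == 0)]
        if infectors.size == 0 or susceptible.size == 0:
            return np.empty(0, dtype=np.int64)
        dx = self.x[susceptible][:, None] - self.x[infectors][None, :]
        dy = self.y[susceptible][:, None] - self.y[infectors][None, :]
        r2 = p.infection_radius * p.infection_radius
        return susceptible[((dx * dx + dy * dy) <= r2).any(axis=1)]

    def give_care(self) -> tuple[int, int]:
        """Kin care phase; returns (care events, resources transferred)."""
        order = self.rng.permutation(self.capacity)
        u = self.rng.random(self.capacity)
        events, transferred = care_kernel(
            order,
            u,
            self.alive,
            self.infected,
            self.cared_for,
            self.score,
            self.agent_id,
            self.parent_id,
            self.params.care_intensity,
        )
        return int(events), int(transferred)

    def apply_extrinsic_mortality(self) -> tuple[int, int]:
        """Density-triggered hazard on uncared-for agents.

        Inactive while the population is at or below the regrowth cutoff
        (150); cared-for agents are exempt.  Returns (deaths, score loss).
        """
        p = self.params
        if self.n_alive <= p.regrowth_cutoff or p.extrinsic_mortality_pct <= 0:
            return 0, 0
        u = self.rng.random(self.capacity)
        doomed = (
            self.alive
            & ~self.cared_for
            & (u < p.extrinsic_mortality_pct / 100.0)
        )
        return self._kill(doomed)

    def combat_all(self) -> dict[str, int]:
        """Disease-mortality roll, then one immune response per infected agent.

        Survivors deploy their prioritized arm with probability
        ``strategy_use_prob``.  Innate: pay 5 if affordable, clear, no
        memory.  Acquired with live memory: pay the recall cost 1 and clear
        (memory clock untouched).  Acquired without memory: needs strictly
        more than 10 points to pay 10, clear, and start the 5-step memory.
        Agents that cannot pay stay infected and face next step's mortality
        roll again.
        """
        p = self.params
        infected = self.alive & self.infected
        u_mort = self.rng.random(self.capacity)
        dead = infected & (u_mort < p.disease_mortality_pct / 100.0)
        n_dead, loss = self._kill(dead)

        survivors = self.alive & self.infected
        u_mod = self.rng.random(self.capacity)
        modality = choose_modality(self.strategy, u_mod, p.strategy_use_prob)

        innate_users = survivors & (modality == INNATE)
        innate_clear = innate_users & (self.score >= p.innate_cost)
        self.score[innate_clear] -= p.innate_cost
        self.infected[innate_clear] = False

        acquired_users = survivors & (modality == ACQUIRED)
        recall = (
            acquired_users
            & (self.memory > 0)
            & (self.score >= p.acquired_recall_cost)
        )
        self.score[recall] -= p.acquired_recall_cost
        self.infected[recall] = False

        first_use = (
            acquired_users
            & (self.memory == 0)
            & (self.score > p.acquired_first_threshold)
        )
        self.score[first_use] -= p.acquired_first_cost
        self.infected[first_use] = False
        self.memory[first_use] = p.memory_duration
        self.memory_gained[first_use] = True

        cost = int(
            innate_clear.sum() * p.innate_cost
            + recall.sum() * p.acquired_recall_cost
            + first_use.sum() * p.acquired_first_cost
        )
        return {
            "n_deaths_disease": n_dead,
            "death_score_loss": loss,
            "combat_cost": cost,
            "n_cleared": int(innate_clear.sum() + recall.sum() + first_use.sum()),
        }

    def maintain_memory(self) -> int:
        """Charge 1 point per step of held memory; lapse if unaffordable.

        Charging starts the step after the memory was gained, so a full
        memory is usable for ``memory_duration`` further steps and spans
        exactly ``memory_duration`` maintenance payments.  Returns total
        maintenance paid.
        """
        p = self.params
        holding = self.alive & (self.memory > 0) & ~self.memory_gained
        lapsed = holding & (self.score < p.memory_maintenance_cost)
        paying = holding & ~lapsed
        self.score[paying] -= p.memory_maintenance_cost
        self.memory[paying] -= 1
        self.memory[lapsed] = 0
        self.memory_gained[:] = False
        return int(paying.sum() * p.memory_maintenance_cost)

    def reseed_if_extinct(self) -> int:
        """Re-introduce the disease whenever prevalence hits zero.

        Infects ceil(N * seed_infection_fraction) living agents chosen
        uniformly without replacement; immunological memory does not block
        infection (it only matters at combat).  Returns agents infected.
        """
        alive_idx = self.alive_slots()
        if alive_idx.size == 0 or self.infected[alive_idx].any():
            return 0
        k = math.ceil(alive_idx.size * self.params.seed_infection_fraction)
        chosen = self.rng.choice(alive_idx, size=k, replace=False)
        self.infected[chosen] = True
        return k

    def reproduce_all(self) -> int:
        """Asexual reproduction, randomized parent order; returns births.

        Parents must be adults under the reproduction stop age holding
        strictly more than the 20-point threshold; each birth costs 20 and
        is blocked once the population reaches carrying capacity.
        Offspring inherit the parent's strategy with probability 0.75,
        start at age 0 with no resources on the parent's patch, and are
        uninfected.
        """
        p = self.params
        order = self.rng.permutation(self.capacity)
        u_inherit = self.rng.random(self.capacity)
        eligible = (
            self.alive
            & (self.age >= p.adult_age)
            & (self.age < p.reproduction_stop_age)
            & (self.score > p.reproduction_threshold)
        )
        room = p.carrying_capacity - self.n_alive
        births = 0
        free = np.flatnonzero(~self.alive)
        for i in order:
            if births >= room:
                break
            if not eligible[i]:
                continue
            self.score[i] -= p.reproduction_cost
            if u_inherit[i] < p.strategy_inheritance_prob:
                child_strategy = int(self.strategy[i])
            else:
                child_strategy = 1 - int(self.strategy[i])
            j = int(free[births])
            self.alive[j] = True
            self.agent_id[j] = self.next_id
            self.next_id += 1
            self.parent_id[j] = self.agent_id[i]
            self.age[j] = 0
            self.x[j] = self.x[i]
            self.y[j] = self.y[i]
            self.score[j] = 0
            self.strategy[j] = child_strategy
            self.infected[j] = False
            self.memory[j] = 0
            self.cared_for[j] = False
            self.forage_failed[j] = False
            self.memory_gained[j] = False
            self.births_count[j] = 0
            self.births_count[i] += 1
            births += 1
        return births

    def age_and_starvation_cull(self) -> dict[str, int]:
        """End-of-step cull: old age (>= 60), then starvation.

        Starvation removes agents with zero resources whose forage attempt
        this step failed; newborns made no attempt and are exempt.
        """
        p = self.params
        aged_out = self.alive & (self.age >= p.max_age)
        n_age, loss_age = self._kill(aged_out)
        starved = self.alive & (self.score == 0) & self.forage_failed
        n_starved, _ = self._kill(starved)  # starved agents carry no resources
        return {
            "n_deaths_age": n_age,
            "n_deaths_starvation": n_starved,
            "death_score_loss": loss_age,
        }

    # ------------------------------------------------------------------
    # full step
    # ------------------------------------------------------------------
    def advance_step(self) -> StepRecord:
        """Run one full year of the schedule and append a StepRecord."""
        self.clear_step_flags()
        self.regrow_patches()
        self.increment_ages()
        total_foraged = self.forage_all()
        n_new = self.transmit()
        # the step's infected census: taken at the year's infection peak,
        # after transmission and before any infections are fought off
        n_infected_census = int((self.alive & self.infected).sum())
        n_alive_at_census = self.n_alive
        full_prevalence = n_infected_census == n_alive_at_census > 0
        n_cared, transferred = self.give_care()
        n_ext, loss_ext = self.apply_extrinsic_mortality()
        combat = self.combat_all()
        memory_cost = self.maintain_memory()
        n_reseeded = self.reseed_if_extinct()
        n_births = self.reproduce_all()
        cull = self.age_and_starvation_cull()

        self.step_index += 1
        alive = self.alive
        n_total = int(alive.sum())
        record = StepRecord(
            step_index=self.step_index,
            n_total=n_total,
            n_infected=n_infected_census,
            n_immature=int((alive & (self.age < self.params.adult_age)).sum()),
            n_mature=int((alive & (self.age >= self.params.adult_age)).sum()),
            n_reproduced=n_births,
            n_cared_for=n_cared,
            n_acquired_priority=int((alive & (self.strategy == ACQUIRED)).sum()),
            n_innate_priority=int((alive & (self.strategy == INNATE)).sum()),
            n_deaths_disease=combat["n_deaths_disease"],
            n_deaths_extrinsic=n_ext,
            n_deaths_age=cull["n_deaths_age"],
            n_deaths_starvation=cull["n_deaths_starvation"],
            n_infected_end=int((alive & self.infected).sum()),
            n_alive_at_census=n_alive_at_census,
            n_new_infections=n_new,
            n_reseeded=n_reseeded,
            full_prevalence=full_prevalence,
            total_foraged=total_foraged,
            total_combat_cost=combat["combat_cost"],
            total_memory_cost=memory_cost,
            total_care_transferred=transferred,
            total_birth_cost=n_births * self.params.reproduction_cost,
            total_death_score_loss=(
                loss_ext + combat["death_score_loss"] + cull["death_score_loss"]
            ),
            total_score=int(self.score[alive].sum()),
        )
        self.step_log.append(record)
        return record

    def step_log_frame(self) -> pd.DataFrame:
        # vars() is much cheaper than dataclasses.asdict for flat records
        return pd.DataFrame([vars(r) for r in self.step_log])


def initialize_world(params: ParameterSet, seed: int) -> WorldState:
    """Build and warm up a world.

    Places ``initial_population`` agents uniformly at random on the grid
    with a 50/50 strategy draw, uniform integer ages in [0, max_age] and no
    resources; runs ``warmup_steps`` forage-only years (agents age and
    collect, nothing else happens); then infects half the population at
    random.
    """
    world = WorldState(params, seed=seed)
    p = params
    n = p.initial_population
    xs = world.rng.integers(0, p.grid_width, size=n)
    ys = world.rng.integers(0, p.grid_height, size=n)
    ages = world.rng.integers(0, p.max_age + 1, size=n)
    strategies = (world.rng.random(n) < 0.5).astype(np.int64)
    for i in range(n):
        world.add_agent(
            x=int(xs[i]),
            y=int(ys[i]),
            age=int(ages[i]),
            strategy=int(strategies[i]),
        )
    for _ in range(p.warmup_steps):
        world.clear_step_flags()
        world.regrow_patches()
        world.increment_ages()
        world.forage_all()
    world.reseed_if_extinct()
    return world
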