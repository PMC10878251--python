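"""Unit tests for each phase of the yearly schedule on scripted worlds."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from careimmune import ACQUIRED, INNATE, choose_modality
from careimmune.params import ParameterSet


def binomial_3se(n: int, p: float) -> float:
    return 3 * np.sqrt(p * (1 - p) / n)


# ---------------------------------------------------------------------------
# patch regrowth
# ---------------------------------------------------------------------------
class TestRegrowth:
    def test_depleted_patches_reset_below_cutoff(self, make_world):
        w = make_world()
        for i in range(100):
            w.add_agent(x=0, y=0, age=30, strategy=INNATE)
        w.resources[5, 5] = 0
        w.foraged[5, 5] = True
        w.regrow_patches()
        assert w.resources[5, 5] == 10
        assert not w.foraged.any()

    def test_no_regrowth_above_cutoff_but_flags_clear(self, make_world):
        w = make_world()
        for i in range(151):
            w.add_agent(x=0, y=0, age=30, strategy=INNATE)
        w.resources[5, 5] = 0
        w.foraged[:, :] = True
        w.regrow_patches()
        assert w.resources[5, 5] == 0
        assert not w.foraged.any()

    def test_full_patches_unchanged(self, make_world):
        w = make_world()
        w.add_agent(x=0, y=0, age=30, strategy=INNATE)
        before = w.resources.copy()
        w.regrow_patches()
        np.testing.assert_array_equal(w.resources, before)


# ---------------------------------------------------------------------------
# foraging
# ---------------------------------------------------------------------------
class TestForage:
    def test_adult_strips_one_in_radius_patch(self, make_world):
        w = make_world(seed=3)
        i = w.add_agent(x=20, y=20, age=30, strategy=INNATE)
        income = w.forage_all()
        assert income == 10
        assert w.score[i] == 10
        x, y = w.x[i], w.y[i]
        assert (x - 20) ** 2 + (y - 20) ** 2 <= 25
        assert w.resources[x, y] == 0
        assert w.foraged[x, y]
        assert not w.forage_failed[i]

    def test_child_takes_half_patch_and_leaves_child_eligible_remainder(
        self, make_world
    ):
        w = make_world(seed=3)
        i = w.add_agent(x=20, y=20, age=5, strategy=INNATE)
        income = w.forage_all()
        assert income == 5
        assert w.score[i] == 5
        x, y = w.x[i], w.y[i]
        assert w.resources[x, y] == 5
        # at exactly the child threshold the patch stays open this step
        assert not w.foraged[x, y]

    def test_child_exhausting_a_half_patch_closes_it(self, make_world):
        w = make_world(seed=3)
        w.resources[:, :] = 5
        i = w.add_agent(x=20, y=20, age=5, strategy=INNATE)
        w.forage_all()
        assert w.resources[w.x[i], w.y[i]] == 0
        assert w.foraged[w.x[i], w.y[i]]

    def test_adult_ignores_partial_patches(self, make_world):
        w = make_world(seed=3)
        w.resources[:, :] = 9
        i = w.add_agent(x=20, y=20, age=30, strategy=INNATE)
        income = w.forage_all()
        assert income == 0
        assert w.forage_failed[i]
        assert (w.x[i], w.y[i]) == (20, 20)

    def test_no_eligible_patch_leaves_agent_in_place(self, make_world):
        w = make_world(seed=3)
        w.foraged[:, :] = True
        i = w.add_agent(x=20, y=20, age=30, strategy=INNATE, score=7)
        income = w.forage_all()
        assert income == 0
        assert w.score[i] == 7
        assert (w.x[i], w.y[i]) == (20, 20)
        assert w.forage_failed[i]

    def test_moves_respect_grid_bounds_and_radius(self, make_world):
        # corner agent: all visited patches stay inside the grid and radius
        for seed in range(20):
            w = make_world(seed=seed)
            i = w.add_agent(x=0, y=0, age=30, strategy=INNATE)
            w.forage_all()
            x, y = w.x[i], w.y[i]
            assert 0 <= x < 40 and 0 <= y < 40
            assert x * x + y * y <= 25

    def test_two_agents_cannot_share_one_full_patch(self, make_world):
        w = make_world(seed=7)
        w.resources[:, :] = 0
        w.resources[20, 20] = 10
        a = w.add_agent(x=20, y=20, age=30, strategy=INNATE)
        b = w.add_agent(x=20, y=20, age=30, strategy=INNATE)
        income = w.forage_all()
        assert income == 10
        assert sorted([w.score[a], w.score[b]]) == [0, 10]


# ---------------------------------------------------------------------------
# transmission
# ---------------------------------------------------------------------------
class TestTransmission:
    def test_no_infected_neighbor_never_infects(self, make_world):
        w = make_world(seed=0, transmissibility_pct=75)
        s = w.add_agent(x=0, y=0, age=30, strategy=INNATE)
        w.add_agent(x=39, y=39, age=30, strategy=INNATE, infected=True)
        for _ in range(50):
            w.transmit()
        assert not w.infected[s]

    def test_at_risk_set_matches_brute_force_distance_oracle(self, make_world):
        w = make_world(seed=42)
        rng = np.random.default_rng(9)
        pos = rng.integers(0, 40, size=(30, 2))
        infected = rng.choice(30, size=7, replace=False)
        slots = []
        for k in range(30):
            slots.append(
                w.add_agent(
                    x=int(pos[k, 0]), y=int(pos[k, 1]), age=30,
                    strategy=INNATE, infected=k in infected,
                )
            )
        slots = np.array(slots)
        expected = set()
        d = cdist(pos.astype(float), pos[infected].astype(float))
        for k in range(30):
            if k not in infected and (d[k] <= 5).any():
                expected.add(slots[k])
        assert set(w.exposure_set()) == expected

    def test_transmission_frequency_matches_probability(self, make_world):
        # one infected centre agent, ring of susceptibles: each exposed
        # susceptible is one Bernoulli draw at 75%
        hits = trials = 0
        w = make_world(seed=123, transmissibility_pct=75)
        centre = w.add_agent(x=20, y=20, age=30, strategy=INNATE, infected=True)
        subjects = [
            w.add_agent(x=18 + dx, y=18 + dy, age=30, strategy=INNATE)
            for dx in range(5)
            for dy in range(5)
            if (dx, dy) != (2, 2)
        ]
        for _ in range(500):
            w.infected[:] = False
            w.infected[centre] = True
            new = w.transmit()
            hits += new
            trials += len(subjects)
        assert abs(hits / trials - 0.75) < binomial_3se(trials, 0.75)

    def test_new_infections_do_not_transmit_within_the_step(self, make_world):
        # chain A(inf) - B - C where only B is within range of A and only C
        # within range of B: C must never catch it in a single phase
        w = make_world(seed=0, transmissibility_pct=75)
        w.add_agent(x=0, y=0, age=30, strategy=INNATE, infected=True)
        w.add_agent(x=5, y=0, age=30, strategy=INNATE)
        c = w.add_agent(x=10, y=0, age=30, strategy=INNATE)
        for _ in range(200):
            w.infected[:] = False
            w.infected[0] = True
            w.transmit()
            assert not w.infected[c]


# ---------------------------------------------------------------------------
# modality choice
# ---------------------------------------------------------------------------
class TestModality:
    @pytest.mark.parametrize("strategy", [INNATE, ACQUIRED])
    def test_prioritized_arm_used_75pct(self, strategy, rng):
        n = 10_000
        draws = choose_modality(np.full(n, strategy), rng.random(n), 0.75)
        frac = (draws == strategy).mean()
        assert abs(frac - 0.75) < binomial_3se(n, 0.75)

    def test_degenerate_probability_always_prioritized(self, rng):
        draws = choose_modality(np.full(100, ACQUIRED), rng.random(100), 1.0)
        assert (draws == ACQUIRED).all()


# ---------------------------------------------------------------------------
# care
# ---------------------------------------------------------------------------
class TestCare:
    def _family(self, w, care_ok=True):
        parent = w.add_agent(x=10, y=10, age=40, strategy=INNATE,
                             score=25 if care_ok else 9)
        child = w.add_agent(
            x=10, y=10, age=5, strategy=INNATE, infected=True,
            parent_id=int(w.agent_id[parent]),
        )
        return parent, child

    def test_parent_provisions_infected_child(self, make_world):
        w = make_world(seed=1, care_intensity=20)
        parent, child = self._family(w)
        events, transferred = w.give_care()
        assert (events, transferred) == (1, 20)
        assert w.score[parent] == 5
        assert w.score[child] == 20
        assert w.cared_for[child]

    def test_zero_intensity_protects_without_transfer(self, make_world):
        w = make_world(seed=1, care_intensity=0)
        child = w.add_agent(x=10, y=10, age=20, strategy=INNATE, score=0)
        parent = w.add_agent(
            x=10, y=10, age=45, strategy=INNATE, score=0, infected=True,
        )
        w.parent_id[child] = w.agent_id[parent]
        events, transferred = w.give_care()
        assert (events, transferred) == (1, 0)
        assert w.cared_for[parent]
        assert w.score[parent] == 0 and w.score[child] == 0

    def test_insolvent_carer_gives_nothing(self, make_world):
        w = make_world(seed=1, care_intensity=10)
        parent, child = self._family(w, care_ok=False)
        events, _ = w.give_care()
        assert events == 0
        assert not w.cared_for[child]
        assert w.score[parent] == 9

    def test_non_relatives_never_care(self, make_world):
        w = make_world(seed=1, care_intensity=10)
        w.add_agent(x=10, y=10, age=40, strategy=INNATE, score=50)
        stranger = w.add_agent(x=10, y=10, age=40, strategy=INNATE, infected=True)
        events, _ = w.give_care()
        assert events == 0
        assert not w.cared_for[stranger]

    def test_one_care_event_per_carer_and_per_recipient(self, make_world):
        w = make_world(seed=1, care_intensity=10)
        parent = w.add_agent(x=10, y=10, age=40, strategy=INNATE,
                             score=100, infected=True)
        pid = int(w.agent_id[parent])
        kids = [
            w.add_agent(x=10, y=10, age=20, strategy=INNATE, score=100,
                        parent_id=pid)
            for _ in range(3)
        ]
        events, transferred = w.give_care()
        # parent may nurse at most one child; each kid may nurse the parent
        # once, but the parent is protected after the first event
        assert w.cared_for[parent]
        assert events <= 1 + 1  # parent cared once; at most one kid cared
        assert transferred == 10 * events

    def test_care_conserves_resources(self, make_world):
        w = make_world(seed=6, care_intensity=20)
        for k in range(40):
            parent = w.add_agent(x=k, y=k, age=40, strategy=INNATE, score=60)
            w.add_agent(x=k, y=k, age=10, strategy=INNATE, infected=True,
                        parent_id=int(w.agent_id[parent]))
        total_before = w.score[w.alive].sum()
        w.give_care()
        assert w.score[w.alive].sum() == total_before


# ---------------------------------------------------------------------------
# extrinsic mortality
# ---------------------------------------------------------------------------
class TestExtrinsicMortality:
    def test_inactive_at_cutoff_population(self, make_world):
        w = make_world(seed=2, extrinsic_mortality_pct=10)
        for _ in range(150):
            w.add_agent(x=1, y=1, age=30, strategy=INNATE)
        deaths, _ = w.apply_extrinsic_mortality()
        assert deaths == 0
        assert w.n_alive == 150

    def test_cared_for_agents_are_exempt(self, make_world):
        for seed in range(30):
            w = make_world(seed=seed, extrinsic_mortality_pct=10)
            slots = [w.add_agent(x=1, y=1, age=30, strategy=INNATE)
                     for _ in range(200)]
            protected = slots[:50]
            w.cared_for[protected] = True
            w.apply_extrinsic_mortality()
            assert w.alive[protected].all()

    def test_death_rate_matches_binomial_oracle(self, make_world):
        deaths = trials = 0
        for seed in range(50):
            w = make_world(seed=seed, extrinsic_mortality_pct=10)
            for _ in range(200):
                w.add_agent(x=1, y=1, age=30, strategy=INNATE)
            d, _ = w.apply_extrinsic_mortality()
            deaths += d
            trials += 200
        assert abs(deaths / trials - 0.10) < binomial_3se(trials, 0.10)


# ---------------------------------------------------------------------------
# combat
# ---------------------------------------------------------------------------
def combat_one(make_world, *, strategy, score, memory=0, use_prob=1.0, dm=0):
    """One infected agent through the combat phase with a forced modality."""
    w = make_world(
        seed=0,
        disease_mortality_pct=dm,
        strategy_use_prob=use_prob,
    )
    i = w.add_agent(x=0, y=0, age=30, strategy=strategy, score=score,
                    infected=True, memory=memory)
    info = w.combat_all()
    return w, i, info


class TestCombat:
    def test_innate_clears_at_exact_cost(self, make_world):
        w, i, _ = combat_one(make_world, strategy=INNATE, score=5)
        assert not w.infected[i]
        assert w.score[i] == 0
        assert w.memory[i] == 0  # innate clearing grants no memory

    def test_innate_insufficient_funds_stays_infected(self, make_world):
        w, i, _ = combat_one(make_world, strategy=INNATE, score=4)
        assert w.infected[i]
        assert w.score[i] == 4

    def test_acquired_first_use_needs_strictly_more_than_ten(self, make_world):
        w, i, _ = combat_one(make_world, strategy=ACQUIRED, score=10)
        assert w.infected[i]  # 10 points is not enough: threshold is strict
        w, i, _ = combat_one(make_world, strategy=ACQUIRED, score=11)
        assert not w.infected[i]
        assert w.score[i] == 1
        assert w.memory[i] == 5

    def test_recall_costs_one_and_leaves_memory_clock(self, make_world):
        w, i, _ = combat_one(make_world, strategy=ACQUIRED, score=2, memory=3)
        assert not w.infected[i]
        assert w.score[i] == 1
        assert w.memory[i] == 3

    def test_recall_requires_one_point(self, make_world):
        w, i, _ = combat_one(make_world, strategy=ACQUIRED, score=0, memory=3)
        assert w.infected[i]

    def test_mortality_roll_precedes_any_response(self, make_world):
        w, i, info = combat_one(make_world, strategy=INNATE, score=100, dm=100)
        assert not w.alive[i]
        assert info["n_deaths_disease"] == 1
        assert info["combat_cost"] == 0

    def test_disease_mortality_rate_matches_binomial_oracle(self, make_world):
        deaths = trials = 0
        for seed in range(40):
            w = make_world(seed=seed, disease_mortality_pct=15,
                           strategy_use_prob=1.0)
            for _ in range(200):
                w.add_agent(x=0, y=0, age=30, strategy=INNATE, score=0,
                            infected=True)
            info = w.combat_all()
            deaths += info["n_deaths_disease"]
            trials += 200
        assert abs(deaths / trials - 0.15) < binomial_3se(trials, 0.15)


# ---------------------------------------------------------------------------
# memory maintenance
# ---------------------------------------------------------------------------
class TestMemoryMaintenance:
    def test_pays_one_point_per_step(self, make_world):
        w = make_world(seed=0)
        i = w.add_agent(x=0, y=0, age=30, strategy=ACQUIRED, score=10, memory=5)
        cost = w.maintain_memory()
        assert cost == 1
        assert (w.score[i], w.memory[i]) == (9, 4)

    def test_memory_expires_after_final_payment(self, make_world):
        w = make_world(seed=0)
        i = w.add_agent(x=0, y=0, age=30, strategy=ACQUIRED, score=1, memory=1)
        w.maintain_memory()
        assert (w.score[i], w.memory[i]) == (0, 0)

    def test_unaffordable_maintenance_lapses_immediately(self, make_world):
        w = make_world(seed=0)
        i = w.add_agent(x=0, y=0, age=30, strategy=ACQUIRED, score=0, memory=4)
        cost = w.maintain_memory()
        assert cost == 0
        assert w.memory[i] == 0

    def test_no_memory_no_cost(self, make_world):
        w = make_world(seed=0)
        i = w.add_agent(x=0, y=0, age=30, strategy=ACQUIRED, score=7, memory=0)
        assert w.maintain_memory() == 0
        assert w.score[i] == 7


# ---------------------------------------------------------------------------
# reseeding
# ---------------------------------------------------------------------------
class TestReseed:
    def test_reseeds_half_when_extinct(self, make_world):
        w = make_world(seed=4)
        for _ in range(100):
            w.add_agent(x=0, y=0, age=30, strategy=INNATE)
        assert w.reseed_if_extinct() == 50
        assert (w.alive & w.infected).sum() == 50

    def test_ceiling_rule_on_odd_population(self, make_world):
        w = make_world(seed=4)
        for _ in range(151):
            w.add_agent(x=0, y=0, age=30, strategy=INNATE)
        assert w.reseed_if_extinct() == 76

    def test_no_reseed_while_disease_circulates(self, make_world):
        w = make_world(seed=4)
        w.add_agent(x=0, y=0, age=30, strategy=INNATE, infected=True)
        w.add_agent(x=0, y=0, age=30, strategy=INNATE)
        assert w.reseed_if_extinct() == 0


# ---------------------------------------------------------------------------
# reproduction
# ---------------------------------------------------------------------------
class TestReproduction:
    def test_birth_requires_strict_threshold(self, make_world):
        w = make_world(seed=0)
        w.add_agent(x=0, y=0, age=30, strategy=INNATE, score=20)
        assert w.reproduce_all() == 0
        w2 = make_world(seed=0)
        parent = w2.add_agent(x=3, y=4, age=30, strategy=INNATE, score=21)
        assert w2.reproduce_all() == 1
        assert w2.score[parent] == 1
        child = [i for i in w2.alive_slots() if i != parent][0]
        assert w2.age[child] == 0
        assert w2.score[child] == 0
        assert not w2.infected[child]
        assert (w2.x[child], w2.y[child]) == (3, 4)
        assert w2.parent_id[child] == w2.agent_id[parent]

    @pytest.mark.parametrize("age", [14, 45, 59])
    def test_age_gates(self, make_world, age):
        w = make_world(seed=0)
        w.add_agent(x=0, y=0, age=age, strategy=INNATE, score=100)
        assert w.reproduce_all() == 0

    def test_carrying_capacity_blocks_births(self, make_world):
        w = make_world(seed=0)
        for _ in range(200):
            w.add_agent(x=0, y=0, age=30, strategy=INNATE, score=100)
        assert w.reproduce_all() == 0
        assert w.n_alive == 200

    def test_capacity_admits_partial_cohort(self, make_world):
        w = make_world(seed=0)
        for _ in range(198):
            w.add_agent(x=0, y=0, age=30, strategy=INNATE, score=100)
        assert w.reproduce_all() == 2
        assert w.n_alive == 200

    def test_strategy_inheritance_frequency(self, make_world):
        matches = births = 0
        for seed in range(100):
            w = make_world(seed=seed)
            for _ in range(100):
                w.add_agent(x=0, y=0, age=30, strategy=ACQUIRED, score=100)
            n = w.reproduce_all()
            births += n
            kids = w.alive.copy()
            kids[:100] = False
            matches += (w.strategy[kids] == ACQUIRED).sum()
        assert births >= 10_000
        assert abs(matches / births - 0.75) < binomial_3se(births, 0.75)


# ---------------------------------------------------------------------------
# cull
# ---------------------------------------------------------------------------
class TestCull:
    def test_old_age_is_fatal(self, make_world):
        w = make_world(seed=0)
        i = w.add_agent(x=0, y=0, age=60, strategy=INNATE, score=100)
        info = w.age_and_starvation_cull()
        assert info["n_deaths_age"] == 1
        assert not w.alive[i]

    def test_starvation_requires_failed_forage_and_empty_score(self, make_world):
        w = make_world(seed=0)
        starved = w.add_agent(x=0, y=0, age=30, strategy=INNATE, score=0)
        w.forage_failed[starved] = True
        fed = w.add_agent(x=0, y=0, age=30, strategy=INNATE, score=0)
        broke_but_fed = w.add_agent(x=0, y=0, age=30, strategy=INNATE, score=5)
        w.forage_failed[broke_but_fed] = True
        info = w.age_and_starvation_cull()
        assert info["n_deaths_starvation"] == 1
        assert not w.alive[starved]
        assert w.alive[fed] and w.alive[broke_but_fed]

    def test_newborns_survive_their_birth_step(self, make_world):
        w = make_world(seed=0)
        w.add_agent(x=0, y=0, age=30, strategy=INNATE, score=21)
        w.reproduce_all()
        info = w.age_and_starvation_cull()
        assert info["n_deaths_starvation"] == 0
        assert w.n_alive == 2
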