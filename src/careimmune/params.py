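"""Model parameters.

A :class:`ParameterSet` holds the four experimentally varied parameters
(disease mortality, transmissibility, extrinsic mortality, care intensity)
together with every fixed model constant (grid size, caps, ages, costs,
probabilities).  The fixed defaults encode the study conditions; the swept
fields are restricted to their factorial levels when validated strictly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping

__all__ = ["ParameterSet", "SWEPT_LEVELS", "validate_params", "INNATE", "ACQUIRED"]

# Immune strategy / modality codes used throughout the array representation.
INNATE = 0
ACQUIRED = 1

#: Factorial levels of the four swept parameters (3 x 4 x 3 x 4 = 144 cells).
SWEPT_LEVELS: dict[str, tuple] = {
    "care_intensity": (0, 10, 20),
    "disease_mortality_pct": (0, 5, 10, 15),
    "transmissibility_pct": (25, 50, 75),
    "extrinsic_mortality_pct": (0, 1, 5, 10),
}


@dataclass(frozen=True)
class ParameterSet:
    """All parameters of one model configuration.

    Swept parameters default to mid-range levels so that a bare
    ``ParameterSet()`` describes one sensible run; the sweep machinery
    overrides them cell by cell.
    """

    # --- swept parameters -------------------------------------------------
    disease_mortality_pct: float = 10.0   # % chance an infected agent dies per step
    transmissibility_pct: float = 50.0    # % chance of catching it from a neighbour
    extrinsic_mortality_pct: float = 1.0  # % chance an uncared-for agent dies (N>150)
    care_intensity: int = 10              # resource points transferred per care event

    # --- habitat ----------------------------------------------------------
    grid_width: int = 40
    grid_height: int = 40
    patch_max_resources: int = 10
    carrying_capacity: int = 200          # hard ceiling on reproduction
    regrowth_cutoff: int = 150            # above this, patches stop regrowing and
                                          # extrinsic mortality switches on

    # --- schedule ---------------------------------------------------------
    run_length: int = 750                 # time steps; one step = one year
    warmup_steps: int = 5                 # forage-only steps before disease seeding

    # --- life history -----------------------------------------------------
    adult_age: int = 15
    reproduction_stop_age: int = 45
    max_age: int = 60
    adult_forage_yield: int = 10          # resource points per successful forage
    child_forage_yield: int = 5
    reproduction_cost: int = 20
    reproduction_threshold: int = 20      # strict: must hold MORE than this to breed

    # --- movement & contact -----------------------------------------------
    movement_radius: float = 5.0          # Euclidean, in patches
    infection_radius: float = 5.0

    # --- immunity ---------------------------------------------------------
    innate_cost: int = 5
    acquired_first_cost: int = 10
    acquired_first_threshold: int = 10    # strict: need score > this for first use
    acquired_recall_cost: int = 1
    memory_duration: int = 5              # steps of immunological memory
    memory_maintenance_cost: int = 1      # resource points per step of memory
    strategy_inheritance_prob: float = 0.75
    strategy_use_prob: float = 0.75       # chance of deploying the prioritized arm

    # --- initialization ---------------------------------------------------
    initial_population: int = 100
    seed_infection_fraction: float = 0.5

    def replace(self, **changes: Any) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(
        cls, mapping: Mapping[str, Any], *, strict: bool = True
    ) -> "ParameterSet":
        """Build from a mapping; unknown keys raise ``KeyError``."""
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(mapping) - names)
        if unknown:
            raise KeyError(f"unknown parameter(s): {', '.join(unknown)}")
        params = cls(**dict(mapping))
        validate_params(params, strict=strict)
        return params


def validate_params(params: ParameterSet, *, strict: bool = True) -> None:
    """Raise ``ValueError`` listing every violated constraint.

    With ``strict=True`` the swept parameters must sit exactly on their
    factorial levels; with ``strict=False`` any value in range is accepted
    (useful for exploratory runs and for tests that need degenerate
    settings such as 100% disease mortality).
    """
    errors: list[str] = []
    p = params

    if strict:
        for name, levels in SWEPT_LEVELS.items():
            value = getattr(p, name)
            if value not in levels:
                errors.append(f"{name}={value!r} not in levels {levels}")

    for name in (
        "disease_mortality_pct",
        "transmissibility_pct",
        "extrinsic_mortality_pct",
    ):
        value = getattr(p, name)
        if not 0 <= value <= 100:
            errors.append(f"{name}={value!r} outside [0, 100]")
    for name in (
        "seed_infection_fraction",
        "strategy_inheritance_prob",
        "strategy_use_prob",
    ):
        value = getattr(p, name)
        if not 0 <= value <= 1:
            errors.append(f"{name}={value!r} outside [0, 1]")
    for name in (
        "care_intensity",
        "innate_cost",
        "acquired_first_cost",
        "acquired_recall_cost",
        "memory_maintenance_cost",
        "reproduction_cost",
    ):
        if getattr(p, name) < 0:
            errors.append(f"{name} must be >= 0")
    for name in ("grid_width", "grid_height", "carrying_capacity", "run_length"):
        if getattr(p, name) <= 0:
            errors.append(f"{name} must be positive")
    if p.initial_population > p.carrying_capacity:
        errors.append("initial_population exceeds carrying_capacity")
    if not 0 <= p.adult_age <= p.reproduction_stop_age <= p.max_age:
        errors.append("require 0 <= adult_age <= reproduction_stop_age <= max_age")
    if p.warmup_steps < 0 or p.memory_duration < 0:
        errors.append("warmup_steps and memory_duration must be >= 0")

    if errors:
        raise ValueError("invalid parameters: " + "; ".join(errors))
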