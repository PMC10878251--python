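"""Factorial experiment runner.

Runs the full cartesian product of the four swept parameters (144 cells at
the default levels), a fixed number of replicate simulations per cell with
documented per-run seeds, applies the halt/exclusion rules (runs that go
extinct or reach 100% prevalence before the final step are excluded from
all averages), and aggregates per-run and per-cell summaries over the final
100-step window.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .analysis import STEP_VARIABLES, compute_step_variables
from .params import SWEPT_LEVELS, ParameterSet
from .world import initialize_world

__all__ = [
    "HaltReason",
    "SweepGrid",
    "RunResult",
    "SweepResult",
    "replicate_seed",
    "run_single",
    "summarize_run",
    "run_sweep",
]

#: canonical column names for the swept parameters in all output tables
SWEPT_COLUMNS = (
    "care_intensity",
    "disease_mortality_pct",
    "transmissibility_pct",
    "extrinsic_mortality_pct",
)


class HaltReason(str, Enum):
    NONE = "none"
    EXTINCTION = "extinction"
    FULL_PREVALENCE = "full_prevalence"


@dataclass(frozen=True)
class SweepGrid:
    """Levels, replication and seeding of one factorial experiment."""

    care_intensity_levels: Sequence[int] = SWEPT_LEVELS["care_intensity"]
    disease_mortality_levels: Sequence[float] = SWEPT_LEVELS["disease_mortality_pct"]
    transmissibility_levels: Sequence[float] = SWEPT_LEVELS["transmissibility_pct"]
    extrinsic_mortality_levels: Sequence[float] = SWEPT_LEVELS[
        "extrinsic_mortality_pct"
    ]
    replicates: int = 100
    master_seed: int = 0
    summary_window: int = 100
    base_params: ParameterSet = field(default_factory=ParameterSet)

    @property
    def n_combinations(self) -> int:
        return (
            len(self.care_intensity_levels)
            * len(self.disease_mortality_levels)
            * len(self.transmissibility_levels)
            * len(self.extrinsic_mortality_levels)
        )

    def combinations(self) -> Iterable[tuple[int, ParameterSet]]:
        """Yield (combination_index, ParameterSet) in canonical order."""
        product = itertools.product(
            self.care_intensity_levels,
            self.disease_mortality_levels,
            self.transmissibility_levels,
            self.extrinsic_mortality_levels,
        )
        for c, (care, dm, tr, em) in enumerate(product):
            yield c, self.base_params.replace(
                care_intensity=care,
                disease_mortality_pct=dm,
                transmissibility_pct=tr,
                extrinsic_mortality_pct=em,
            )


def replicate_seed(master_seed: int, combination: int, replicate: int) -> int:
    """Documented per-run seed: SeedSequence of the index triple, 31 bits."""
    ss = np.random.SeedSequence((int(master_seed), int(combination), int(replicate)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


@dataclass
class RunResult:
    """One simulation run: parameters, seed, halt status and step log."""

    params: ParameterSet
    seed: int
    completed: bool
    halt_reason: HaltReason
    n_steps: int
    step_records: pd.DataFrame

    @property
    def failed(self) -> bool:
        return not self.completed


def run_single(params: ParameterSet, seed: int) -> RunResult:
    """Advance a freshly initialized world up to ``run_length`` steps.

    Halts early (and is later excluded from analysis) if the population
    dies out or if the step's infected census covers every living agent.
    """
    world = initialize_world(params, seed)
    halt = HaltReason.NONE
    for _ in range(params.run_length):
        record = world.advance_step()
        if record.n_total == 0:
            halt = HaltReason.EXTINCTION
            break
        if record.full_prevalence:
            halt = HaltReason.FULL_PREVALENCE
            break
    n_steps = len(world.step_log)
    completed = halt is HaltReason.NONE and n_steps == params.run_length
    return RunResult(
        params=params,
        seed=seed,
        completed=completed,
        halt_reason=halt,
        n_steps=n_steps,
        step_records=world.step_log_frame(),
    )


def summarize_run(run: RunResult, summary_window: int = 100) -> pd.Series:
    """Mean of each emergent variable over the final ``summary_window`` steps.

    Only completed runs are summarized; incomplete runs are excluded from
    analysis and raise ``ValueError`` here.
    """
    if not run.completed:
        raise ValueError(
            f"run (seed={run.seed}) halted early ({run.halt_reason.value}) "
            "and is excluded from analysis"
        )
    tail = run.step_records.iloc[-summary_window:]
    variables = compute_step_variables(tail)
    summary = variables.mean()
    summary["mean_population"] = float(tail["n_total"].mean())
    return summary


@dataclass
class SweepResult:
    """Aggregated output of a factorial sweep."""

    grid: SweepGrid
    summaries: pd.DataFrame      # one row per combination with >= 1 completed rep
    per_run: pd.DataFrame        # one row per completed run
    excluded: pd.DataFrame       # one row per halted run
    trajectories: pd.DataFrame | None  # per-step means across completed reps
    n_attempted: int

    @property
    def n_surviving_combinations(self) -> int:
        return int(len(self.summaries))


def run_sweep(
    grid: SweepGrid,
    keep_trajectories: bool = True,
    progress: bool = False,
) -> SweepResult:
    """Run the full factorial experiment sequentially.

    Replicate r of combination c is seeded by
    ``replicate_seed(master_seed, c, r)``, so runs are independent of
    execution order and the whole sweep is reproducible from the master
    seed alone.
    """
    run_rows: list[dict] = []
    excluded_rows: list[dict] = []
    combo_rows: list[dict] = []
    trajectory_rows: list[pd.DataFrame] = []
    n_attempted = 0
    run_length = grid.base_params.run_length

    for c, params in grid.combinations():
        swept = {
            "care_intensity": params.care_intensity,
            "disease_mortality_pct": params.disease_mortality_pct,
            "transmissibility_pct": params.transmissibility_pct,
            "extrinsic_mortality_pct": params.extrinsic_mortality_pct,
        }
        completed_summaries: list[pd.Series] = []
        traj_sum: np.ndarray | None = None
        for r in range(grid.replicates):
            seed = replicate_seed(grid.master_seed, c, r)
            result = run_single(params, seed)
            n_attempted += 1
            if not result.completed:
                excluded_rows.append(
                    {
                        "combination": c,
                        "replicate": r,
                        "seed": seed,
                        **swept,
                        "halt_reason": result.halt_reason.value,
                        "n_steps": result.n_steps,
                    }
                )
                continue
            summary = summarize_run(result, grid.summary_window)
            run_rows.append(
                {"combination": c, "replicate": r, "seed": seed, **swept,
                 **summary.to_dict()}
            )
            completed_summaries.append(summary)
            if keep_trajectories:
                values = compute_step_variables(result.step_records)
                values["n_total"] = result.step_records["n_total"].to_numpy()
                if traj_sum is None:
                    traj_sum = values.to_numpy(dtype=float)
                else:
                    traj_sum += values.to_numpy(dtype=float)
        if progress:  # pragma: no cover - cosmetic
            print(f"combination {c + 1}/{grid.n_combinations}: "
                  f"{len(completed_summaries)}/{grid.replicates} completed")
        if not completed_summaries:
            continue
        mean_summary = pd.concat(completed_summaries, axis=1).mean(axis=1)
        combo_rows.append(
            {"combination": c, **swept,
             "n_replicates_completed": len(completed_summaries),
             **mean_summary.to_dict()}
        )
        if keep_trajectories and traj_sum is not None:
            traj = pd.DataFrame(
                traj_sum / len(completed_summaries),
                columns=list(STEP_VARIABLES) + ["n_total"],
            )
            traj.insert(0, "step_index", np.arange(1, run_length + 1))
            traj.insert(0, "combination", c)
            for key, value in swept.items():
                traj[key] = value
            trajectory_rows.append(traj)

    summaries = pd.DataFrame(combo_rows)
    per_run = pd.DataFrame(run_rows)
    excluded = pd.DataFrame(
        excluded_rows,
        columns=["combination", "replicate", "seed", *SWEPT_COLUMNS,
                 "halt_reason", "n_steps"],
    )
    trajectories = (
        pd.concat(trajectory_rows, ignore_index=True)
        if keep_trajectories and trajectory_rows
        else None
    )
    return SweepResult(
        grid=grid,
        summaries=summaries,
        per_run=per_run,
        excluded=excluded,
        trajectories=trajectories,
        n_attempted=n_attempted,
    )
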