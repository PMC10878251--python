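"""Configuration files, CSV/JSON writers and trajectory plots."""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from datetime import datetime, timezone
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .params import SWEPT_LEVELS, ParameterSet, validate_params
from .sweep import SweepGrid, SweepResult

__all__ = ["load_config", "write_config", "write_outputs", "plot_trajectories"]

log = logging.getLogger("careimmune")

#: keys allowed in the optional ``sweep:`` section of a config file
_SWEEP_KEYS = {
    "replicates",
    "master_seed",
    "summary_window",
    "care_intensity_levels",
    "disease_mortality_levels",
    "transmissibility_levels",
    "extrinsic_mortality_levels",
}

_LEVEL_KEY_TO_PARAM = {
    "care_intensity_levels": "care_intensity",
    "disease_mortality_levels": "disease_mortality_pct",
    "transmissibility_levels": "transmissibility_pct",
    "extrinsic_mortality_levels": "extrinsic_mortality_pct",
}


def load_config(path: str | Path, *, strict: bool = True) -> SweepGrid:
    """Read a YAML/JSON config into a fully resolved :class:`SweepGrid`.

    Top-level keys are :class:`ParameterSet` fields (missing ones take the
    model's fixed defaults); an optional ``sweep`` section sets levels,
    replication and the master seed.  Unknown keys are rejected with their
    key path.  With ``strict`` (the default) swept parameter values and
    level lists must sit on the canonical factorial levels.
    """
    path = Path(path)
    with path.open() as handle:
        raw = yaml.safe_load(handle) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: top level must be a mapping")

    sweep_section = raw.pop("sweep", {}) or {}
    if not isinstance(sweep_section, dict):
        raise ValueError(f"{path}: 'sweep' must be a mapping")
    unknown = sorted(set(sweep_section) - _SWEEP_KEYS)
    if unknown:
        raise ValueError(
            f"{path}: unknown key(s) " + ", ".join(f"sweep.{k}" for k in unknown)
        )

    param_names = {f.name for f in dataclasses.fields(ParameterSet)}
    unknown = sorted(set(raw) - param_names)
    if unknown:
        raise ValueError(f"{path}: unknown key(s) " + ", ".join(unknown))
    params = ParameterSet(**raw)
    validate_params(params, strict=strict)

    grid_kwargs: dict[str, Any] = {"base_params": params}
    for key, value in sweep_section.items():
        if key in _LEVEL_KEY_TO_PARAM:
            levels = tuple(value)
            if strict:
                allowed = set(SWEPT_LEVELS[_LEVEL_KEY_TO_PARAM[key]])
                bad = [lv for lv in levels if lv not in allowed]
                if bad:
                    raise ValueError(
                        f"{path}: sweep.{key} values {bad} are not canonical "
                        f"levels {sorted(allowed)} (pass strict=False to allow)"
                    )
            grid_kwargs[key] = levels
        else:
            grid_kwargs[key] = value
    return SweepGrid(**grid_kwargs)


def write_config(grid: SweepGrid, path: str | Path) -> None:
    """Serialize a grid back to YAML (inverse of :func:`load_config`)."""
    payload = grid.base_params.to_dict()
    payload["sweep"] = {
        "replicates": grid.replicates,
        "master_seed": grid.master_seed,
        "summary_window": grid.summary_window,
        "care_intensity_levels": list(grid.care_intensity_levels),
        "disease_mortality_levels": list(grid.disease_mortality_levels),
        "transmissibility_levels": list(grid.transmissibility_levels),
        "extrinsic_mortality_levels": list(grid.extrinsic_mortality_levels),
    }
    with Path(path).open("w") as handle:
        yaml.safe_dump(payload, handle, sort_keys=False)


def _write_csv(frame: pd.DataFrame, path: Path) -> int:
    frame.to_csv(path, index=False, float_format="%.6f")
    return len(frame)


def write_outputs(
    result: SweepResult,
    out_dir: str | Path,
    per_step: pd.DataFrame | None = None,
) -> dict[str, int]:
    """Write sweep outputs to ``out_dir``; returns {filename: row count}.

    Emits ``summaries.csv`` (one row per surviving combination),
    ``per_run.csv``, ``excluded.csv``, ``trajectories.csv`` (when kept),
    optional ``runs.csv`` (raw per-step records) and ``meta.json`` with the
    resolved configuration, seeds and the file manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, int] = {}
    manifest["summaries.csv"] = _write_csv(result.summaries, out / "summaries.csv")
    manifest["per_run.csv"] = _write_csv(result.per_run, out / "per_run.csv")
    manifest["excluded.csv"] = _write_csv(result.excluded, out / "excluded.csv")
    if result.trajectories is not None:
        manifest["trajectories.csv"] = _write_csv(
            result.trajectories, out / "trajectories.csv"
        )
    if per_step is not None:
        manifest["runs.csv"] = _write_csv(per_step, out / "runs.csv")

    grid = result.grid
    meta = {
        "software": {"name": "careimmune", "version": __version__},
        "written_at": datetime.now(timezone.utc).isoformat(),
        "parameters": grid.base_params.to_dict(),
        "sweep": {
            "replicates": grid.replicates,
            "master_seed": grid.master_seed,
            "summary_window": grid.summary_window,
            "care_intensity_levels": list(grid.care_intensity_levels),
            "disease_mortality_levels": list(grid.disease_mortality_levels),
            "transmissibility_levels": list(grid.transmissibility_levels),
            "extrinsic_mortality_levels": list(grid.extrinsic_mortality_levels),
            "n_combinations": grid.n_combinations,
            "n_attempted_runs": result.n_attempted,
            "n_surviving_combinations": result.n_surviving_combinations,
        },
        "run_seeds": (
            result.per_run[["combination", "replicate", "seed"]].to_dict("records")
            if len(result.per_run)
            else []
        ),
        "excluded_runs": result.excluded.to_dict("records"),
        "manifest": manifest,
    }
    with (out / "meta.json").open("w") as handle:
        json.dump(meta, handle, indent=2, default=float)
    manifest["meta.json"] = 1
    return manifest


def plot_trajectories(
    trajectories: pd.DataFrame,
    out_dir: str | Path,
    outcomes: tuple[str, ...] = (
        "prevalence",
        "pct_acquired",
        "rate_of_care",
        "pct_immature",
        "reproductive_rate",
    ),
    color_by: str = "disease_mortality_pct",
    column_by: str = "care_intensity",
) -> list[Path]:
    """Small-multiple time-series plots of across-replicate mean trajectories.

    One figure per outcome: panels are the levels of ``column_by``
    (care intensity by default), lines the levels of ``color_by``,
    averaged over the remaining swept parameters.  Qualitative aid only.
    Returns the written figure paths; logs a warning and writes nothing if
    the selection is empty.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if trajectories is None or len(trajectories) == 0:
        log.warning("no trajectories to plot; skipping")
        return []
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    columns = sorted(trajectories[column_by].unique())
    colors = sorted(trajectories[color_by].unique())
    for outcome in outcomes:
        if outcome not in trajectories.columns:
            warnings.warn(f"outcome {outcome!r} missing from trajectories")
            continue
        fig, axes = plt.subplots(
            1, len(columns), figsize=(4 * len(columns), 3.2),
            sharey=True, squeeze=False,
        )
        for ax, col_level in zip(axes[0], columns):
            panel = trajectories[trajectories[column_by] == col_level]
            for level in colors:
                lines = panel[panel[color_by] == level]
                mean = lines.groupby("step_index")[outcome].mean()
                ax.plot(mean.index, mean.to_numpy(), label=f"{color_by}={level}")
            ax.set_title(f"{column_by}={col_level}")
            ax.set_xlabel("time step")
        axes[0][0].set_ylabel(outcome)
        axes[0][-1].legend(fontsize=7)
        fig.tight_layout()
        path = out / f"trajectory_{outcome}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written
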