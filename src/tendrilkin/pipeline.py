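"""End-to-end orchestration: simulate/load -> profile -> measures -> statistics.

A run writes, under its output directory:

* ``measures.csv``        — one row per plant (duration, mean velocity,
  submovement counts, endpoint variability; count columns empty for
  no-support plants, which have no grasping phase),
* ``summary.csv``         — per-condition descriptive statistics per measure,
* ``tests.csv``           — Kruskal-Wallis (+ post hoc) for duration/velocity
  across all conditions and BC-vs-AC pooled t tests for the submovement
  measures,
* ``resolved_config.yaml``— every defaulted decision materialised,
* ``run.log``             — seed, package versions, and all default choices.

Stages are separable: :func:`run_statistics` consumes a cached measures
table, so statistics can be re-run without re-simulating.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ContractError
from .groupstats import kruskal_wallis, pairwise_posthoc, student_t_from_samples, summarize_group
from .io import SupportSpec, Trajectory, read_trajectories
from .kinematics import compute_profile, mean_velocity, movement_duration
from .simulate import simulate_study
from .submovements import endpoint_variability, submovement_counts

logger = logging.getLogger("tendrilkin")

COUNT_MEASURES = ("n_velocity", "n_acceleration", "n_jerk", "n_total")
_TTEST_MEASURES = COUNT_MEASURES + ("endpoint_variability",)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    source: str = "simulate"            # "simulate" or "files"
    trajectories_path: str | None = None
    preset: str = "default"
    n_per_condition: int = 8
    seed: int = 0
    fraction: float = 0.10
    basis: str = "time"
    deadband_velocity: float = 0.0
    deadband_acceleration: float = 0.0
    deadband_jerk: float = 0.0
    estimator: str = "rms_from_centroid"
    mean_velocity_mode: str = "absolute"
    posthoc_method: str = "dunn_bonferroni"
    out_dir: str = "tendrilkin_run"

    @property
    def deadbands(self) -> tuple[float, float, float]:
        return (self.deadband_velocity, self.deadband_acceleration, self.deadband_jerk)


def measure_trajectories(
    trajectories: Sequence[Trajectory],
    supports: dict[str, SupportSpec] | Sequence[SupportSpec | None],
    *,
    fraction: float = 0.10,
    basis: str = "time",
    deadbands: tuple[float, float, float] = (0.0, 0.0, 0.0),
    estimator: str = "rms_from_centroid",
    mean_velocity_mode: str = "absolute",
) -> pd.DataFrame:
    """Per-plant measures table.

    ``supports`` is either one spec per trajectory (sequence, aligned) or a
    mapping from plant_id to spec; missing / kind="none" entries are treated
    as no-support plants, for which the submovement columns stay empty.
    """
    rows = []
    for i, traj in enumerate(trajectories):
        if isinstance(supports, dict):
            support = supports.get(traj.plant_id)
        else:
            support = supports[i]
        profile = compute_profile(traj, support)
        row = {
            "plant_id": traj.plant_id,
            "condition": traj.condition,
            "grasped": traj.grasped,
            "duration": movement_duration(traj),
            "mean_velocity": mean_velocity(profile, mean_velocity_mode),
            "endpoint_variability": endpoint_variability(
                traj, estimator=estimator, fraction=fraction, basis=basis
            ).value,
        }
        if traj.grasped and support is not None and support.kind != "none":
            counts = submovement_counts(profile, fraction, deadbands, basis=basis)
            row.update(
                n_velocity=counts.n_velocity,
                n_acceleration=counts.n_acceleration,
                n_jerk=counts.n_jerk,
                n_total=counts.n_total,
            )
        else:
            row.update({m: np.nan for m in COUNT_MEASURES})
        rows.append(row)
    return pd.DataFrame(rows).sort_values(["condition", "plant_id"]).reset_index(drop=True)


def summarize_measures(measures: pd.DataFrame) -> pd.DataFrame:
    """Per-(measure, condition) descriptive statistics table."""
    rows = []
    value_cols = ["duration", "mean_velocity", *COUNT_MEASURES, "endpoint_variability"]
    for measure in value_cols:
        for condition, group in measures.groupby("condition"):
            vals = group[measure].dropna().to_numpy()
            if len(vals) < 3:
                continue
            s = summarize_group(vals, condition)
            rows.append({"measure": measure, **dataclasses.asdict(s)})
    return pd.DataFrame(rows)


def run_statistics(
    measures: pd.DataFrame,
    *,
    posthoc_method: str = "dunn_bonferroni",
) -> pd.DataFrame:
    """The comparison battery over a per-plant measures table.

    Duration and mean velocity: Kruskal-Wallis across all available
    conditions plus pairwise post hoc when three are present. Submovement
    counts and endpoint variability: BC-vs-AC pooled Student t with Cohen's
    d, skipped (with a logged warning) unless both grasped conditions are
    present.
    """
    rows = []
    conditions = sorted(measures["condition"].unique())
    for measure in ("duration", "mean_velocity"):
        groups = [
            measures.loc[measures["condition"] == c, measure].dropna().to_numpy()
            for c in conditions
        ]
        keep = [(c, g) for c, g in zip(conditions, groups) if len(g) >= 2]
        if len(keep) < 2:
            continue
        labels = tuple(c for c, _ in keep)
        arrays = [g for _, g in keep]
        kw = kruskal_wallis(arrays, labels)
        rows.append({"measure": measure, "test": "kruskal_wallis", "groups": "|".join(labels),
                     "statistic": kw.statistic, "df": kw.df, "p": kw.p,
                     "effect_size": np.nan, "d_ci_low": np.nan, "d_ci_high": np.nan})
        if len(keep) >= 3:
            for res in pairwise_posthoc(arrays, labels, method=posthoc_method):
                rows.append({"measure": measure, "test": f"posthoc_{posthoc_method}",
                             "groups": "|".join(res.groups), "statistic": res.statistic,
                             "df": res.df, "p": res.p, "effect_size": np.nan,
                             "d_ci_low": np.nan, "d_ci_high": np.nan})
    grasped = measures[measures["grasped"] & measures["n_total"].notna()]
    have = {c for c in ("AC", "BC") if (grasped["condition"] == c).sum() >= 2}
    if have == {"AC", "BC"}:
        bc = grasped[grasped["condition"] == "BC"]
        ac = grasped[grasped["condition"] == "AC"]
        for measure in _TTEST_MEASURES:
            res = student_t_from_samples(
                bc[measure].to_numpy(), ac[measure].to_numpy(), labels=("BC", "AC")
            )
            rows.append({"measure": measure, "test": "student_t", "groups": "BC|AC",
                         "statistic": res.statistic, "df": res.df, "p": res.p,
                         "effect_size": res.effect_size,
                         "d_ci_low": res.effect_ci_low, "d_ci_high": res.effect_ci_high})
    else:
        logger.warning(
            "submovement t tests skipped: need >= 2 plants in each grasped condition, "
            "have %s", sorted(have),
        )
    return pd.DataFrame(rows)


def _load_inputs(config: RunConfig):
    if config.source == "simulate":
        trajectories, truths = simulate_study(
            n_per_condition=config.n_per_condition, seed=config.seed
        )
        supports = {gt.plant_id: gt.support for gt in truths}
        return trajectories, supports
    if config.source == "files":
        if not config.trajectories_path:
            raise ContractError("source='files' requires trajectories_path")
        trajectories = read_trajectories(config.trajectories_path)
        # file-based runs analyse supported conditions against static supports
        # declared per condition in sidecar YAML next to the trajectory file
        supports = {}
        base = Path(config.trajectories_path).parent
        from .io import read_support

        for traj in trajectories:
            sidecar = base / f"support_{traj.condition}.yaml"
            if sidecar.exists():
                supports[traj.plant_id] = read_support(sidecar)
        return trajectories, supports
    raise ContractError(f"unknown source {config.source!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run and write its report bundle; returns the artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("tendrilkin %s; numpy %s; pandas %s", __version__,
                    np.__version__, pd.__version__)
        logger.info("resolved config: %s", dataclasses.asdict(config))
        logger.info(
            "window basis=%s fraction=%.3f deadbands=%s estimator=%s velocity mode=%s",
            config.basis, config.fraction, config.deadbands, config.estimator,
            config.mean_velocity_mode,
        )
        trajectories, supports = _load_inputs(config)
        measures = measure_trajectories(
            trajectories, supports,
            fraction=config.fraction, basis=config.basis,
            deadbands=config.deadbands, estimator=config.estimator,
            mean_velocity_mode=config.mean_velocity_mode,
        )
        summary = summarize_measures(measures)
        tests = run_statistics(measures, posthoc_method=config.posthoc_method)
        measures.to_csv(out / "measures.csv", index=False)
        summary.to_csv(out / "summary.csv", index=False)
        tests.to_csv(out / "tests.csv", index=False)
        with open(out / "resolved_config.yaml", "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=False)
        logger.info("wrote %d plant measures, %d summaries, %d tests",
                    len(measures), len(summary), len(tests))
    finally:
        logger.removeHandler(handler)
        handler.close()
    return {
        "measures": measures,
        "summary": summary,
        "tests": tests,
        "out_dir": out,
        "paths": {name: out / f"{name}.csv" for name in ("measures", "summary", "tests")},
    }


__all__ = [
    "RunConfig",
    "measure_trajectories",
    "summarize_measures",
    "run_statistics",
    "run_pipeline",
]
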