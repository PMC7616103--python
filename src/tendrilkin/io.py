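"""Trajectory and support-specification I/O.

On-disk dialect
---------------
Trajectories are stored as comma-delimited UTF-8 text with a mandatory header
row and one row per (plant, sample)::

    plant_id,condition,t,x,y,z[,grasped][,grasp_index]

* ``t`` is time in **hours** since the start of tracking for that plant.
* ``x, y, z`` are tendril-tip coordinates in **millimetres**. ``y`` is the
  vertical growth axis; the horizontal plane is x-z (stimulus distances are
  measured on the XZ plane).
* ``condition`` is one of ``AC`` (artificial support), ``BC`` (biological
  support), ``CC`` (no support / control).
* ``grasped`` / ``grasp_index`` are optional and constant within a plant:
  whether the movement terminated in a grasp, and the sample index at which
  it did (defaults to the last sample when grasped).

Rows may appear in any order; parsing canonicalises by sorting on
(plant_id, t). The decimal separator is ``.``.

Support specifications are flat key-value YAML documents (``kind``,
``axis_x``, ``axis_z``, ``radius``, ``height``, optional ``motion_trace``
path pointing at a two-column x,z CSV of per-timestamp axis displacements).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ContractError, FormatError, TrajectoryValidationError

CONDITIONS = ("AC", "BC", "CC")
SUPPORT_KINDS = ("artificial", "biological", "none")

_REQUIRED_COLUMNS = ("plant_id", "condition", "t", "x", "y", "z")


@dataclass
class SupportSpec:
    """Geometry and type of the climbing target.

    The axis is vertical at horizontal position (axis_x, axis_z), radius and
    height in millimetres. ``motion_trace`` holds the per-timestamp (x, z)
    displacement of the axis from its base position (biological supports
    circumnutate themselves); its rows align with the trajectory's samples.
    """

    kind: str
    axis_x: float = 0.0
    axis_z: float = 0.0
    radius: float = 0.0
    height: float = 0.0
    motion_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in SUPPORT_KINDS:
            raise ContractError(f"unknown support kind {self.kind!r}")
        if self.kind != "none" and not self.radius > 0:
            raise ContractError("support radius must be > 0 unless kind is 'none'")
        if self.motion_trace is not None:
            self.motion_trace = np.asarray(self.motion_trace, dtype=float)
            if self.motion_trace.ndim != 2 or self.motion_trace.shape[1] != 2:
                raise ContractError("motion_trace must have shape (n, 2)")

    def axis_positions(self, n: int) -> np.ndarray:
        """(n, 2) array of axis (x, z) positions, one per trajectory sample."""
        base = np.array([self.axis_x, self.axis_z], dtype=float)
        if self.motion_trace is None:
            return np.broadcast_to(base, (n, 2)).copy()
        if len(self.motion_trace) != n:
            raise ContractError(
                f"motion_trace has {len(self.motion_trace)} rows, trajectory has {n} samples"
            )
        return base + self.motion_trace


@dataclass
class Trajectory:
    """One plant's tracked tendril-tip time series.

    ``t`` in hours (strictly increasing), ``xyz`` an (n, 3) array in mm with
    y vertical. ``grasped`` records whether the movement ended by attaching
    to the support; it is always False for the no-support condition, whose
    movement instead terminates in a drop.
    """

    plant_id: str
    condition: str
    t: np.ndarray
    xyz: np.ndarray
    grasped: bool = False
    grasp_index: int | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.condition not in CONDITIONS:
            raise TrajectoryValidationError(
                f"plant {self.plant_id!r}: unknown condition {self.condition!r}"
            )
        if self.xyz.ndim != 2 or self.xyz.shape[1] != 3:
            raise TrajectoryValidationError(
                f"plant {self.plant_id!r}: positions must have shape (n, 3)"
            )
        if len(self.t) != len(self.xyz):
            raise TrajectoryValidationError(
                f"plant {self.plant_id!r}: {len(self.t)} timestamps vs {len(self.xyz)} positions"
            )
        if len(self.t) < 4:
            raise TrajectoryValidationError(
                f"plant {self.plant_id!r}: needs >= 4 samples (jerk takes three differences), "
                f"got {len(self.t)}"
            )
        if not np.all(np.diff(self.t) > 0):
            raise TrajectoryValidationError(
                f"plant {self.plant_id!r}: timestamps are not strictly increasing"
            )
        if self.condition == "CC" and self.grasped:
            raise TrajectoryValidationError(
                f"plant {self.plant_id!r}: no-support (CC) plants cannot grasp"
            )
        if self.grasp_index is not None:
            gi = int(self.grasp_index)
            if not 0 < gi < len(self.t):
                raise TrajectoryValidationError(
                    f"plant {self.plant_id!r}: grasp_index {gi} out of range"
                )
            self.grasp_index = gi

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def end_index(self) -> int:
        """Sample index of the end of movement (grasp, or last sample)."""
        if self.grasped and self.grasp_index is not None:
            return self.grasp_index
        return len(self.t) - 1


def read_trajectories(path: str | Path, *, delimiter: str = ",") -> list[Trajectory]:
    """Parse a trajectory file into one :class:`Trajectory` per plant.

    Rows are canonicalised by sorting on (plant_id, t); duplicated or
    non-monotone timestamps within a plant raise
    :class:`TrajectoryValidationError` naming the plant. Malformed numeric
    cells are reported with their 1-based file line numbers.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=delimiter, dtype={"plant_id": str})
    except (ValueError, pd.errors.ParserError) as exc:
        raise FormatError(f"{path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    for col in ("t", "x", "y", "z"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna() | df[col].isna()
        if bad.any():
            lines = [int(i) + 2 for i in df.index[bad]]  # +2: header is line 1
            raise FormatError(f"{path}: malformed {col!r} values at line(s) {lines}")
        df[col] = coerced

    trajectories = []
    for plant_id, group in df.groupby("plant_id", sort=True):
        group = group.sort_values("t", kind="mergesort")
        tvals = group["t"].to_numpy()
        if np.any(np.diff(tvals) <= 0):
            raise TrajectoryValidationError(
                f"plant {plant_id!r}: duplicated or non-monotone timestamps"
            )
        conditions = group["condition"].unique()
        if len(conditions) != 1:
            raise TrajectoryValidationError(
                f"plant {plant_id!r}: multiple condition labels {sorted(conditions)}"
            )
        condition = str(conditions[0])
        if "grasped" in group.columns:
            grasped = bool(np.asarray(group["grasped"])[0])
        else:
            grasped = condition != "CC"
        grasp_index = None
        if "grasp_index" in group.columns:
            gi = group["grasp_index"].iloc[0]
            if pd.notna(gi):
                grasp_index = int(gi)
        trajectories.append(
            Trajectory(
                plant_id=str(plant_id),
                condition=condition,
                t=tvals,
                xyz=group[["x", "y", "z"]].to_numpy(),
                grasped=grasped,
                grasp_index=grasp_index,
            )
        )
    return trajectories


def write_trajectories(
    trajectories: Sequence[Trajectory] | Iterable[Trajectory],
    path: str | Path,
    *,
    delimiter: str = ",",
) -> Path:
    """Write trajectories in the documented dialect, rows sorted by (plant_id, t)."""
    trajectories = list(trajectories)
    if not trajectories:
        raise ContractError("cannot write an empty trajectory collection")
    frames = []
    for traj in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "plant_id": traj.plant_id,
                    "condition": traj.condition,
                    "t": traj.t,
                    "x": traj.xyz[:, 0],
                    "y": traj.xyz[:, 1],
                    "z": traj.xyz[:, 2],
                    "grasped": traj.grasped,
                    "grasp_index": traj.grasp_index if traj.grasp_index is not None else "",
                }
            )
        )
    out = pd.concat(frames, ignore_index=True).sort_values(
        ["plant_id", "t"], kind="mergesort"
    )
    path = Path(path)
    out.to_csv(path, index=False, sep=delimiter)
    return path


def read_support(path: str | Path) -> SupportSpec:
    """Read a support specification from a flat YAML key-value document."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "kind" not in doc:
        raise FormatError(f"{path}: support spec must be a mapping with a 'kind' key")
    trace = None
    trace_path = doc.pop("motion_trace", None)
    if trace_path:
        trace = pd.read_csv(path.parent / trace_path).to_numpy(dtype=float)
    return SupportSpec(
        kind=str(doc["kind"]),
        axis_x=float(doc.get("axis_x", 0.0)),
        axis_z=float(doc.get("axis_z", 0.0)),
        radius=float(doc.get("radius", 0.0)),
        height=float(doc.get("height", 0.0)),
        motion_trace=trace,
    )


def write_support(spec: SupportSpec, path: str | Path) -> Path:
    """Write a support spec as YAML; a motion trace goes to a sibling CSV."""
    path = Path(path)
    doc = {
        "kind": spec.kind,
        "axis_x": float(spec.axis_x),
        "axis_z": float(spec.axis_z),
        "radius": float(spec.radius),
        "height": float(spec.height),
    }
    if spec.motion_trace is not None:
        trace_name = path.stem + "_motion.csv"
        pd.DataFrame(spec.motion_trace, columns=["x", "z"]).to_csv(
            path.parent / trace_name, index=False
        )
        doc["motion_trace"] = trace_name
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


__all__ = [
    "CONDITIONS",
    "SUPPORT_KINDS",
    "SupportSpec",
    "Trajectory",
    "read_trajectories",
    "write_trajectories",
    "read_support",
    "write_support",
]
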