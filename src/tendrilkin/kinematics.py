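"""Discrete kinematic profiles of tendril trajectories.

The stimulus distance s_i is the Euclidean distance between the tendril tip
and the support axis on the horizontal XZ plane, minus the support radius
(so s = 0 means contact with the support surface), floored at zero. The
derivative profiles are first-order divided differences::

    v_i = (s_i - s_{i-1}) / (t_i - t_{i-1})        [mm/h]
    a_i = (v_i - v_{i-1}) / (t_i - t_{i-1})        [mm/h^2]
    j_i = (a_i - a_{i-1}) / (t_i - t_{i-1})        [mm/h^3]

Each derivative value is aligned to the *right* endpoint of its interval, so
v lives on t[1:], a on t[2:], j on t[3:]. No smoothing is applied by default;
an optional centred moving average of odd window length is available because
zero-crossing counts are noise sensitive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ContractError, UnsupportedConditionError
from .io import SupportSpec, Trajectory


@dataclass
class KinematicProfile:
    """Aligned time/distance/velocity/acceleration/jerk arrays.

    len(v) == len(s) - 1, len(a) == len(v) - 1, len(j) == len(a) - 1.
    ``condition`` and ``grasped`` are carried over from the source trajectory
    so downstream analyses can refuse measures that are undefined for
    ungrasped (no-support) movements.
    """

    t: np.ndarray
    s: np.ndarray
    v: np.ndarray
    a: np.ndarray
    j: np.ndarray
    plant_id: str | None = None
    condition: str | None = None
    grasped: bool | None = None

    def __post_init__(self) -> None:
        n = len(self.t)
        if not (len(self.s) == n and len(self.v) == n - 1 and len(self.a) == n - 2
                and len(self.j) == n - 3):
            raise ContractError("profile arrays violate the length relations")

    @property
    def n_samples(self) -> int:
        return len(self.t)


def distance_series(trajectory: Trajectory, support: SupportSpec) -> np.ndarray:
    """Per-sample distance from the tip to the support *surface* on the XZ plane.

    Vertical (y) motion never enters. A moving support (biological hosts
    circumnutate) is handled through ``support.motion_trace``, whose rows
    align with the trajectory's timestamps. Distances are floored at 0.
    """
    if support.kind == "none":
        raise UnsupportedConditionError(
            "no-support condition has no stimulus; distance series undefined"
        )
    axis = support.axis_positions(trajectory.n_samples)
    dx = trajectory.xyz[:, 0] - axis[:, 0]
    dz = trajectory.xyz[:, 2] - axis[:, 1]
    return np.maximum(np.hypot(dx, dz) - support.radius, 0.0)


def _check_series(name: str, s: np.ndarray, t: np.ndarray, min_len: int) -> None:
    if len(s) != len(t):
        raise ContractError(f"{name}: series length {len(s)} != time length {len(t)}")
    if len(s) < min_len:
        raise ContractError(f"{name}: needs at least {min_len} samples, got {len(s)}")
    dt = np.diff(t)
    if np.any(dt == 0):
        raise ContractError(f"{name}: repeated time points (zero interval)")
    if np.any(dt < 0):
        raise ContractError(f"{name}: time not strictly increasing")


def velocity(s: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Divided first differences of s against t; output aligned to t[1:]."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    _check_series("velocity", s, t, 2)
    return np.diff(s) / np.diff(t)


def acceleration(v: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Divided differences of a velocity array against its own time points.

    ``t`` must hold the times the velocity values are aligned to (i.e. the
    original t[1:]), one per velocity sample. A single-element input has no
    differences and yields an empty array.
    """
    if len(v) == 1 and len(t) == 1:
        return np.empty(0)
    return velocity(v, t)


def jerk(a: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Divided differences of an acceleration array against its time points."""
    return acceleration(a, t)


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centred moving average with edge reflection; window must be odd."""
    if window < 1 or window % 2 == 0:
        raise ContractError("smoothing window must be a positive odd integer")
    if window == 1:
        return np.asarray(x, dtype=float).copy()
    half = window // 2
    padded = np.pad(np.asarray(x, dtype=float), half, mode="reflect")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def compute_profile(
    trajectory: Trajectory,
    support: SupportSpec | None = None,
    *,
    end_index: int | None = None,
    smooth_window: int | None = None,
) -> KinematicProfile:
    """Full kinematic profile of a trajectory, truncated at the end of movement.

    For supported conditions the distance series is taken to the support
    surface. No-support (CC) plants have no stimulus: their profile uses the
    XZ-plane distance from the plant's own starting tip position, which gives
    duration and velocity-amplitude measures a well-defined reference while
    submovement analysis remains unavailable for them.
    """
    end = trajectory.end_index if end_index is None else int(end_index)
    if not 3 <= end < trajectory.n_samples:
        raise ContractError(f"end_index {end} leaves fewer than 4 samples")
    t = trajectory.t[: end + 1]
    if support is not None and support.kind != "none":
        sub = trajectory
        if end + 1 != trajectory.n_samples:
            trace = support.motion_trace
            if trace is not None:
                support = SupportSpec(
                    kind=support.kind, axis_x=support.axis_x, axis_z=support.axis_z,
                    radius=support.radius, height=support.height,
                    motion_trace=trace[: end + 1],
                )
            sub = Trajectory(
                trajectory.plant_id, trajectory.condition, t,
                trajectory.xyz[: end + 1], grasped=trajectory.grasped,
                grasp_index=None,
            )
        s = distance_series(sub, support)
    else:
        origin = trajectory.xyz[0, [0, 2]]
        dxz = trajectory.xyz[: end + 1, [0, 2]] - origin
        s = np.hypot(dxz[:, 0], dxz[:, 1])
    if smooth_window is not None:
        s = moving_average(s, smooth_window)
    v = velocity(s, t)
    a = acceleration(v, t[1:])
    j = jerk(a, t[2:])
    return KinematicProfile(
        t=t, s=s, v=v, a=a, j=j,
        plant_id=trajectory.plant_id,
        condition=trajectory.condition,
        grasped=trajectory.grasped,
    )


def movement_duration(trajectory: Trajectory, *, drop_index: int | None = None) -> float:
    """Total movement duration in hours: t[end of movement] - t[0].

    End of movement is the grasp index for grasped plants; for ungrasped
    (no-support) plants it defaults to the last tracked sample, unless an
    explicit ``drop_index`` overrides it.
    """
    if trajectory.n_samples < 2:
        raise ContractError("duration needs at least 2 samples")
    end = trajectory.end_index
    if drop_index is not None:
        if trajectory.grasped:
            raise ContractError("drop_index only applies to ungrasped trajectories")
        end = int(drop_index)
        if not 0 < end < trajectory.n_samples:
            raise ContractError(f"drop_index {end} out of range")
    return float(trajectory.t[end] - trajectory.t[0])


def mean_velocity(profile: KinematicProfile, mode: str = "absolute") -> float:
    """Amplitude of mean velocity over the whole movement.

    ``absolute`` (default) averages |v|; circumnutation makes the signed
    approach velocity oscillate around zero, so only the absolute reading
    yields the strictly positive group means this measure is reported as.
    ``signed`` averages v as-is and is kept for diagnostics.
    """
    if mode not in ("signed", "absolute"):
        raise ContractError(f"unknown mean-velocity mode {mode!r}")
    if len(profile.v) == 0:
        raise ContractError("empty velocity profile")
    v = profile.v
    return float(np.mean(np.abs(v) if mode == "absolute" else v))


__all__ = [
    "KinematicProfile",
    "distance_series",
    "velocity",
    "acceleration",
    "jerk",
    "moving_average",
    "compute_profile",
    "movement_duration",
    "mean_velocity",
]
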