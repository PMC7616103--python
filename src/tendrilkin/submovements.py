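"""Terminal-window submovement counts and endpoint variability.

Submovements are operationalised as zero-crossings of the velocity,
acceleration, and jerk profiles inside the terminal ("homing") window — by
default the last 10% of movement time, where corrective adjustments
concentrate. Profiles are differentiated over the full movement first and
windowed afterwards; a derivative value belongs to the window when the right
endpoint of its interval does.

Endpoint variability is the dispersion of the 3D tip positions across the
terminal window: root-mean-square distance from the window centroid by
default, with the arithmetic mean distance as an alternative estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ContractError, InsufficientDataError, UnsupportedConditionError
from .io import Trajectory
from .kinematics import KinematicProfile

DEFAULT_FRACTION = 0.10


@dataclass
class TerminalWindow:
    """Inclusive sample-index span of the terminal phase of a movement."""

    start_index: int
    end_index: int
    fraction: float = DEFAULT_FRACTION
    basis: str = "time"

    def __post_init__(self) -> None:
        if not self.start_index < self.end_index:
            raise ContractError("terminal window must span at least two samples")

    def n_derivative_samples(self, order: int) -> int:
        """Number of order-``order`` derivative values whose right endpoint lies inside."""
        sl = self.derivative_slice(order)
        return max(0, sl.stop - sl.start)

    def derivative_slice(self, order: int) -> slice:
        """Slice into an order-``order`` derivative array (aligned to t[order:])."""
        if order < 0:
            raise ContractError("derivative order must be >= 0")
        return slice(max(0, self.start_index - order), self.end_index - order + 1)


def window_start_index(t: np.ndarray, fraction: float, basis: str = "time") -> int:
    """First sample index inside the terminal window.

    time basis: samples with t >= t0 + (1 - fraction) * (t_end - t0), with a
    relative tolerance so grid points landing exactly on the threshold are
    included. samples basis: the last ceil(fraction * n) samples.
    """
    t = np.asarray(t, dtype=float)
    if not 0.0 < fraction < 1.0:
        raise ContractError("fraction must lie in (0, 1)")
    n = len(t)
    if basis == "time":
        span = t[-1] - t[0]
        threshold = t[0] + (1.0 - fraction) * span - 1e-9 * max(span, 1.0)
        return int(np.searchsorted(t, threshold, side="left"))
    if basis == "samples":
        return n - math.ceil(fraction * n)
    raise ContractError(f"unknown window basis {basis!r}")


def terminal_window(
    profile_or_t: KinematicProfile | np.ndarray,
    fraction: float = DEFAULT_FRACTION,
    basis: str = "time",
) -> TerminalWindow:
    """Terminal window over a profile's sample grid.

    Raises :class:`InsufficientDataError` when fewer than 3 velocity samples
    fall inside the window.
    """
    t = profile_or_t.t if isinstance(profile_or_t, KinematicProfile) else np.asarray(profile_or_t)
    start = window_start_index(t, fraction, basis)
    if start >= len(t) - 1:
        raise InsufficientDataError("terminal window degenerates to a single sample")
    window = TerminalWindow(start_index=start, end_index=len(t) - 1,
                            fraction=fraction, basis=basis)
    if window.n_derivative_samples(1) < 3:
        raise InsufficientDataError(
            f"terminal window holds {window.n_derivative_samples(1)} velocity samples; need >= 3"
        )
    return window


def count_zero_crossings(
    series: np.ndarray,
    window: TerminalWindow | tuple[int, int] | None = None,
    deadband: float = 0.0,
    *,
    derivative_order: int = 0,
) -> int:
    """Number of sign changes in ``series`` (optionally restricted to a window).

    Values with |x| <= deadband are snapped to zero first. A run of zeros
    counts as at most one crossing, and only when the flanking signs differ —
    this keeps counts stable under duplicated samples. ``window`` may be a
    (start, stop) pair of indices into ``series`` itself, or a
    :class:`TerminalWindow` on the sample grid together with the series'
    ``derivative_order`` (1 = velocity, 2 = acceleration, 3 = jerk).
    """
    if deadband < 0:
        raise ContractError("deadband must be >= 0")
    series = np.asarray(series, dtype=float)
    if window is None:
        sl = slice(0, len(series))
    elif isinstance(window, TerminalWindow):
        sl = window.derivative_slice(derivative_order)
    else:
        start, stop = window
        sl = slice(int(start), int(stop))
    if sl.start < 0 or sl.stop > len(series) or sl.start > sl.stop:
        raise ContractError(f"window {sl} outside series of length {len(series)}")
    x = series[sl]
    signs = np.sign(x)
    signs[np.abs(x) <= deadband] = 0.0
    nonzero = signs[signs != 0]
    if len(nonzero) < 2:
        return 0
    return int(np.count_nonzero(nonzero[1:] * nonzero[:-1] < 0))


@dataclass
class SubmovementCounts:
    """Zero-crossing counts of v/a/j inside the terminal window, plus total."""

    n_velocity: int
    n_acceleration: int
    n_jerk: int
    window: TerminalWindow
    deadbands: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @property
    def n_total(self) -> int:
        return self.n_velocity + self.n_acceleration + self.n_jerk


def submovement_counts(
    profile: KinematicProfile,
    fraction: float = DEFAULT_FRACTION,
    deadbands: tuple[float, float, float] = (0.0, 0.0, 0.0),
    *,
    basis: str = "time",
    window: TerminalWindow | None = None,
) -> SubmovementCounts:
    """Count velocity/acceleration/jerk submovements in the terminal window.

    Defined only for grasped movements: the no-support condition has no
    grasping phase and raises :class:`UnsupportedConditionError`.
    """
    if profile.condition == "CC" or profile.grasped is False:
        raise UnsupportedConditionError(
            "submovement analysis requires a grasping phase; "
            "unavailable for ungrasped / no-support movements"
        )
    if window is None:
        window = terminal_window(profile, fraction, basis)
    # Numerical zero floor: divided differences of a distance series of scale
    # |s| carry rounding error ~eps*|s|/dt per order, so signs of derivative
    # values below that magnitude are meaningless (an exactly constant-speed
    # approach would otherwise show spurious acceleration crossings). The
    # floor scales with the data, preserving positive-scale invariance of the
    # counts; any user deadband larger than it takes precedence.
    min_dt = float(np.min(np.diff(profile.t)))
    floor_v = 1e-10 * float(np.max(np.abs(profile.s), initial=0.0)) / min_dt
    floor_a = 2.0 * floor_v / min_dt
    floor_j = 2.0 * floor_a / min_dt
    eff = (
        max(float(deadbands[0]), floor_v),
        max(float(deadbands[1]), floor_a),
        max(float(deadbands[2]), floor_j),
    )
    return SubmovementCounts(
        n_velocity=count_zero_crossings(profile.v, window, eff[0], derivative_order=1),
        n_acceleration=count_zero_crossings(profile.a, window, eff[1], derivative_order=2),
        n_jerk=count_zero_crossings(profile.j, window, eff[2], derivative_order=3),
        window=window,
        deadbands=eff,
    )


@dataclass
class EndpointVariability:
    """Dispersion (mm) of terminal-window tip positions around their centroid."""

    value: float
    estimator: str
    window: TerminalWindow


def endpoint_variability(
    trajectory: Trajectory,
    window: TerminalWindow | None = None,
    estimator: str = "rms_from_centroid",
    *,
    fraction: float = DEFAULT_FRACTION,
    basis: str = "time",
) -> EndpointVariability:
    """Endpoint variability over the terminal window of one movement.

    ``rms_from_centroid`` (default): sqrt(mean squared 3D distance from the
    window centroid). ``mean_dist_from_centroid``: mean of those distances.
    Both are invariant to rigid translation and rotation of the trajectory.
    """
    if estimator not in ("rms_from_centroid", "mean_dist_from_centroid"):
        raise ContractError(f"unknown estimator {estimator!r}")
    end = trajectory.end_index
    if window is None:
        window = terminal_window(trajectory.t[: end + 1], fraction, basis)
    if window.end_index >= trajectory.n_samples:
        raise ContractError("window outside trajectory bounds")
    pts = trajectory.xyz[window.start_index : window.end_index + 1]
    if len(pts) < 2:
        raise InsufficientDataError("endpoint variability needs >= 2 window samples")
    centroid = pts.mean(axis=0)
    d = np.linalg.norm(pts - centroid, axis=1)
    value = float(np.sqrt(np.mean(d**2)) if estimator == "rms_from_centroid" else np.mean(d))
    return EndpointVariability(value=value, estimator=estimator, window=window)


__all__ = [
    "DEFAULT_FRACTION",
    "TerminalWindow",
    "window_start_index",
    "terminal_window",
    "count_zero_crossings",
    "SubmovementCounts",
    "submovement_counts",
    "EndpointVariability",
    "endpoint_variability",
]
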