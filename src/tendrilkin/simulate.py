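"""Synthetic circumnutation trajectories with controllable ground truth.

The generator produces tendril-tip time series with the statistical
structure the analysis pipeline assumes, in three phases:

1. **Exploration** — the tip oscillates on an ellipse (configurable radii
   and period) around a centre that rises at ``vertical_rate``.
2. **Approach** (supported conditions only) — the oscillation centre is
   pulled toward the support surface, the centre-to-surface gap decaying
   exponentially to ``homing_start_distance`` by the onset of homing, while
   the oscillation amplitude tapers.
3. **Homing** — the final ``fraction`` (default 10%) of movement time. The
   signed distance-to-surface follows a deterministic schedule of k + 1
   alternating monotone runs, so its first difference (the velocity
   profile) reverses sign exactly k times before the tendril settles on
   the support: k is the injected velocity-submovement count. Valley
   levels decay linearly to zero; within each run the step magnitudes grow
   geometrically (``velocity_tilt``) so acceleration and jerk are genuinely
   nonzero floats with deterministic sign patterns rather than rounding
   noise. Acceleration/jerk crossing counts arise consequently and are
   brute-force counted on the noiseless series as ground truth.

The no-support condition skips the approach and ends with a monotone drop
(no grasp). Isotropic Gaussian jitter can be added to the homing samples
(endpoint dispersion) and observation noise to every coordinate. Output is
bit-reproducible given (seed, plant index, condition): each plant draws
from its own ``numpy.random.default_rng`` stream keyed on that triple.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import ContractError
from .io import SupportSpec, Trajectory
from .kinematics import KinematicProfile
from .submovements import submovement_counts, window_start_index

_CONDITION_CODE = {"AC": 1, "BC": 2, "CC": 3}


@dataclass
class SimulationConfig:
    """All knobs of the generator; nothing is hard-coded in the phases.

    Units: hours for times, millimetres for lengths. ``duration`` and
    ``n_injected_submovements`` are per-condition means; the matching ``_sd``
    fields give between-plant variation (0 = every plant identical, which is
    what exact-recovery checks use).
    """

    condition: str
    n_plants: int = 8
    duration: float = 100.0
    duration_sd: float = 0.0
    dt: float = 0.03
    circumnutation_period: float = 1.4
    ellipse_radii: tuple[float, float] = (35.0, 25.0)
    vertical_rate: float = 2.0
    support: SupportSpec | None = None
    approach_gain: float = 4.0          # e-folds of gap decay completed by homing onset
    homing_start_distance: float = 40.0
    fraction: float = 0.10              # homing (terminal-window) fraction of movement time
    n_injected_submovements: float = 8.0
    submovement_sd: float = 0.0
    bounce_fraction: float = 0.3        # upward rebound as a fraction of the preceding drop
    velocity_tilt: float = 0.08         # within-run geometric growth of step magnitudes
    amplitude_taper: float = 0.15       # oscillation amplitude left at homing onset
    terminal_jitter_sd: float = 0.0
    observation_noise_sd: float = 0.0
    support_motion_amplitude: float = 0.0
    support_motion_period: float = 1.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.condition not in _CONDITION_CODE:
            raise ContractError(f"unknown condition {self.condition!r}")
        if self.dt <= 0:
            raise ContractError("dt must be > 0")
        if self.duration / self.dt < 40:
            raise ContractError("duration/dt must give at least 40 samples")
        if self.n_injected_submovements < 0 or self.submovement_sd < 0:
            raise ContractError("submovement count parameters must be >= 0")
        if not 0 < self.fraction < 1:
            raise ContractError("fraction must lie in (0, 1)")
        if self.condition == "CC":
            if self.support is not None and self.support.kind != "none":
                raise ContractError("no-support condition cannot carry a support")
        elif self.support is None:
            raise ContractError(f"condition {self.condition} requires a support spec")


@dataclass
class GroundTruth:
    """Per-plant generative truth for pipeline validation.

    ``true_n_velocity`` is exact by construction (zero-noise pipelines must
    recover it); acceleration/jerk counts are brute-force zero-crossing
    counts on the noiseless profile. ``support`` carries the plant's own
    support spec (biological supports have per-plant motion traces).
    """

    plant_id: str
    condition: str
    true_duration: float
    grasped: bool
    true_n_velocity: int | None = None
    true_n_acceleration: int | None = None
    true_n_jerk: int | None = None
    endpoint_centroid: np.ndarray | None = None
    jitter_sd: float = 0.0
    support: SupportSpec | None = None

    @property
    def true_n_total(self) -> int | None:
        if self.true_n_velocity is None:
            return None
        return self.true_n_velocity + self.true_n_acceleration + self.true_n_jerk


def _homing_schedule(
    s0: float, m: int, k: int, bounce: float, tilt: float
) -> np.ndarray:
    """Signed-distance schedule: m + 1 values from s0 to ~0 with exactly k
    first-difference sign reversals.

    The k + 1 monotone runs alternate direction starting downward. Valley
    levels decay linearly to 0; each rebound recovers ``bounce`` of the
    preceding drop (the final rebound, when k is odd, is capped small so the
    movement still ends essentially on the surface). Within a run the step
    magnitudes grow by factor (1 + tilt) per sample, keeping acceleration
    and jerk bounded away from zero.
    """
    if not 0 <= k <= m - 1:
        raise ContractError(f"cannot fit {k} reversals into {m} steps")
    if s0 <= 0:
        raise ContractError("homing must start at positive distance")
    n_runs = k + 1
    n_down = (n_runs + 1) // 2
    valleys = [s0 * (n_down - 1 - i) / n_down for i in range(n_down)]
    levels = [s0]
    for i in range(n_down):
        levels.append(valleys[i])
        is_last_run = len(levels) - 1 == n_runs
        if not is_last_run:
            prev_above = levels[-2]
            b = bounce if len(levels) < n_runs else min(bounce, 0.08)
            levels.append(valleys[i] + b * (prev_above - valleys[i]))
    levels = np.asarray(levels[: n_runs + 1])
    # distribute the m steps over runs, each run getting at least one
    base, rem = divmod(m, n_runs)
    lengths = np.full(n_runs, base, dtype=int)
    lengths[:rem] += 1
    sched = np.empty(m + 1)
    sched[0] = s0
    pos = 0
    for run in range(n_runs):
        ell = lengths[run]
        amp = levels[run + 1] - levels[run]
        # cap the compound within-run growth (~e^3) so the smallest step of a
        # long run stays far above floating-point resolution of the distance
        g = min(tilt, 3.0 / ell)
        w = (1.0 + g) ** np.arange(ell)
        steps = amp * w / w.sum()
        sched[pos + 1 : pos + 1 + ell] = levels[run] + np.cumsum(steps)
        pos += ell
    sched[-1] = levels[-1]  # land exactly on the final level
    if np.any(sched < -1e-9):
        raise ContractError("homing schedule dipped below the support surface")
    return sched


def _plant_rng(config: SimulationConfig, plant_index: int) -> np.random.Generator:
    return np.random.default_rng(
        [int(config.seed), int(plant_index), _CONDITION_CODE[config.condition]]
    )


def simulate_plant(
    config: SimulationConfig, plant_index: int
) -> tuple[Trajectory, GroundTruth]:
    """Simulate one plant; deterministic given (config.seed, plant_index)."""
    rng = _plant_rng(config, plant_index)
    cond = config.condition
    plant_id = f"{cond}{plant_index:03d}"

    duration = config.duration + config.duration_sd * rng.standard_normal()
    duration = max(duration, 41 * config.dt, 0.25 * config.duration)
    n = int(round(duration / config.dt)) + 1
    t = np.arange(n) * config.dt
    h0 = window_start_index(t, config.fraction)
    m = n - h0
    phase0 = rng.uniform(0.0, 2.0 * math.pi)
    r1, r2 = config.ellipse_radii
    omega = 2.0 * math.pi / config.circumnutation_period

    xyz = np.empty((n, 3))
    xyz[:, 1] = config.vertical_rate * t

    if cond == "CC":
        osc_x = r1 * np.cos(omega * t + phase0)
        osc_z = r2 * np.sin(omega * t + phase0)
        xyz[:, 0] = osc_x
        xyz[:, 2] = osc_z
        # terminal drop: the tip falls below its starting height, frozen in XZ
        y_onset = xyz[h0 - 1, 1]
        drop = np.linspace(0.0, 1.3 * y_onset + 10.0, m)
        xyz[h0:, 0] = xyz[h0 - 1, 0]
        xyz[h0:, 2] = xyz[h0 - 1, 2]
        xyz[h0:, 1] = y_onset - drop
        support = SupportSpec(kind="none")
        truth = GroundTruth(
            plant_id=plant_id, condition=cond, true_duration=float(t[-1] - t[0]),
            grasped=False, jitter_sd=config.terminal_jitter_sd, support=support,
        )
        if config.terminal_jitter_sd > 0:
            xyz[h0:] += rng.normal(0.0, config.terminal_jitter_sd, (m, 3))
        if config.observation_noise_sd > 0:
            xyz += rng.normal(0.0, config.observation_noise_sd, (n, 3))
        return (
            Trajectory(plant_id, cond, t, xyz, grasped=False),
            truth,
        )

    # --- supported conditions (AC / BC) ---
    base_support = config.support
    if config.support_motion_amplitude > 0:
        phase_s = rng.uniform(0.0, 2.0 * math.pi)
        omega_s = 2.0 * math.pi / config.support_motion_period
        trace = config.support_motion_amplitude * np.column_stack(
            [
                np.cos(omega_s * t + phase_s) - math.cos(phase_s),
                np.sin(omega_s * t + phase_s) - math.sin(phase_s),
            ]
        )
    else:
        trace = None
    support = SupportSpec(
        kind=base_support.kind, axis_x=base_support.axis_x, axis_z=base_support.axis_z,
        radius=base_support.radius, height=base_support.height, motion_trace=trace,
    )
    axis = support.axis_positions(n)

    # approach: centre-to-surface gap decays to the homing start distance
    base_axis = np.array([base_support.axis_x, base_support.axis_z])
    gap0 = float(np.linalg.norm(base_axis)) - support.radius
    if gap0 <= config.homing_start_distance:
        raise ContractError("support too close: approach gap smaller than homing start")
    t_onset = t[h0] if h0 > 0 else t[-1]
    gap = config.homing_start_distance + (gap0 - config.homing_start_distance) * np.exp(
        -config.approach_gain * t / t_onset
    )
    u_home = -base_axis / np.linalg.norm(base_axis)  # from axis toward the plant base
    center = axis + u_home[None, :] * (support.radius + gap)[:, None]

    taper = np.ones(n)
    ramp = t >= 0.5 * t_onset
    taper[ramp] = 1.0 + (config.amplitude_taper - 1.0) * (
        (t[ramp] - 0.5 * t_onset) / (0.5 * t_onset)
    )
    taper = np.clip(taper, config.amplitude_taper, 1.0)
    xyz[:, 0] = center[:, 0] + r1 * np.cos(omega * t + phase0) * taper
    xyz[:, 2] = center[:, 1] + r2 * np.sin(omega * t + phase0) * taper

    # homing: replace the terminal segment with the injected-count schedule
    tip_prev = xyz[h0 - 1, [0, 2]]
    rel = tip_prev - axis[h0 - 1]
    s_prev = max(float(np.linalg.norm(rel)) - support.radius, 1.0)
    u_h = rel / np.linalg.norm(rel)

    if config.submovement_sd > 0:
        k = int(round(config.n_injected_submovements
                      + config.submovement_sd * rng.standard_normal()))
    else:
        k = int(round(config.n_injected_submovements))
    k = int(np.clip(k, 0, m - 1))
    sched = _homing_schedule(
        s_prev, m, k, config.bounce_fraction, config.velocity_tilt
    )
    radial = (support.radius + sched[1:])[:, None] * u_h[None, :]
    xyz[h0:, 0] = axis[h0:, 0] + radial[:, 0]
    xyz[h0:, 2] = axis[h0:, 1] + radial[:, 1]
    # vertical growth slows once the tendril is working the support surface
    xyz[h0:, 1] = xyz[h0 - 1, 1] + 0.5 * config.vertical_rate * (t[h0:] - t[h0 - 1])

    # noiseless ground-truth counts, brute-forced exactly as the pipeline counts
    s_clean = np.maximum(
        np.hypot(xyz[:, 0] - axis[:, 0], xyz[:, 2] - axis[:, 1]) - support.radius, 0.0
    )
    v_clean = np.diff(s_clean) / np.diff(t)
    a_clean = np.diff(v_clean) / np.diff(t[1:])
    j_clean = np.diff(a_clean) / np.diff(t[2:])
    clean_profile = KinematicProfile(
        t=t, s=s_clean, v=v_clean, a=a_clean, j=j_clean,
        plant_id=plant_id, condition=cond, grasped=True,
    )
    clean_counts = submovement_counts(clean_profile, config.fraction)
    truth = GroundTruth(
        plant_id=plant_id, condition=cond, true_duration=float(t[-1] - t[0]),
        grasped=True,
        true_n_velocity=clean_counts.n_velocity,
        true_n_acceleration=clean_counts.n_acceleration,
        true_n_jerk=clean_counts.n_jerk,
        endpoint_centroid=xyz[h0:].mean(axis=0).copy(),
        jitter_sd=config.terminal_jitter_sd,
        support=support,
    )
    assert truth.true_n_velocity == k, "schedule failed to realise the injected count"

    if config.terminal_jitter_sd > 0:
        xyz[h0:] += rng.normal(0.0, config.terminal_jitter_sd, (m, 3))
    if config.observation_noise_sd > 0:
        xyz += rng.normal(0.0, config.observation_noise_sd, (n, 3))
    traj = Trajectory(plant_id, cond, t, xyz, grasped=True, grasp_index=n - 1)
    return traj, truth


def simulate_condition(config: SimulationConfig) -> tuple[list[Trajectory], list[GroundTruth]]:
    """Simulate config.n_plants plants of one condition."""
    pairs = [simulate_plant(config, i) for i in range(config.n_plants)]
    return [p[0] for p in pairs], [p[1] for p in pairs]


def study_preset(condition: str, seed: int = 0, **overrides) -> SimulationConfig:
    """Default study presets.

    The artificial-support condition is faster (shorter period), shorter in
    duration, and packs more terminal reversals with a wider, more scattered
    homing cloud; the biological-support condition is slower and smoother
    with a moving host stem; the control has no support and ends in a drop.
    Support geometry: a 600 mm tall, 12 mm diameter pole 120 mm from the
    plant; the host stem is thinner and sways a few millimetres.

    Presets default to noise-free coordinates: discrete acceleration and
    jerk magnify per-sample noise by 1/dt^2 and 1/dt^3, so raw zero-crossing
    counts (deadband 0, the source analysis) are only structured on
    low-noise tracks. Condition-dependent endpoint dispersion comes from the
    homing geometry (a wider homing start spreads the terminal cloud);
    ``terminal_jitter_sd`` / ``observation_noise_sd`` remain available to
    stress-test noise sensitivity.
    """
    if condition == "AC":
        cfg = dict(
            condition="AC", duration=81.0, duration_sd=15.0,
            circumnutation_period=1.1, ellipse_radii=(35.0, 25.0),
            homing_start_distance=60.0,
            n_injected_submovements=67.125, submovement_sd=20.490,
            support=SupportSpec(kind="artificial", axis_x=120.0, axis_z=0.0,
                                radius=6.0, height=600.0),
        )
    elif condition == "BC":
        cfg = dict(
            condition="BC", duration=111.0, duration_sd=20.0,
            circumnutation_period=1.6, ellipse_radii=(30.0, 22.0),
            homing_start_distance=20.0,
            n_injected_submovements=48.0, submovement_sd=13.148,
            support=SupportSpec(kind="biological", axis_x=120.0, axis_z=0.0,
                                radius=2.5, height=400.0),
            support_motion_amplitude=4.0, support_motion_period=1.8,
        )
    elif condition == "CC":
        cfg = dict(
            condition="CC", duration=63.0, duration_sd=12.0,
            circumnutation_period=1.3, ellipse_radii=(32.0, 24.0),
            support=None,
        )
    else:
        raise ContractError(f"unknown condition {condition!r}")
    cfg.update(overrides)
    return SimulationConfig(seed=seed, **cfg)


def simulate_study(
    ac_config: SimulationConfig | None = None,
    bc_config: SimulationConfig | None = None,
    cc_config: SimulationConfig | None = None,
    n_per_condition: int | None = None,
    seed: int | None = None,
) -> tuple[list[Trajectory], list[GroundTruth]]:
    """Simulate a full study (all three conditions, n plants each).

    Omitted configs fall back to the presets. ``seed`` / ``n_per_condition``
    override the per-config values when given.
    """
    configs = []
    for cond, cfg in (("AC", ac_config), ("BC", bc_config), ("CC", cc_config)):
        cfg = cfg if cfg is not None else study_preset(cond, seed=seed or 0)
        if seed is not None:
            cfg = replace(cfg, seed=seed)
        if n_per_condition is not None:
            cfg = replace(cfg, n_plants=n_per_condition)
        configs.append(cfg)
    trajectories: list[Trajectory] = []
    truths: list[GroundTruth] = []
    for cfg in configs:
        trajs, gts = simulate_condition(cfg)
        trajectories.extend(trajs)
        truths.extend(gts)
    return trajectories, truths


def configured_total_effect_size(c1: SimulationConfig, c2: SimulationConfig) -> float:
    """Standardized mean difference of total submovement counts implied by two configs.

    Total counts are an affine function of the injected velocity count
    (~3k - 1 up to window-boundary terms), so the standardized difference of
    totals equals that of the injected counts:
    (mu1 - mu2) / sqrt((sd1^2 + sd2^2) / 2).
    """
    sp = math.sqrt((c1.submovement_sd**2 + c2.submovement_sd**2) / 2.0)
    if sp == 0:
        raise ContractError("effect size undefined for zero submovement variance")
    return (c1.n_injected_submovements - c2.n_injected_submovements) / sp


__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_plant",
    "simulate_condition",
    "simulate_study",
    "study_preset",
    "configured_total_effect_size",
]
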