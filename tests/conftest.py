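import dataclasses

import numpy as np
import pytest

import tendrilkin as tk


@pytest.fixture
def simple_trajectory():
    """Straight-line approach toward a pole at x=100, uniform 1 h sampling."""
    t = np.arange(11.0)
    x = 10.0 * t  # tip marches from 0 to 100
    xyz = np.column_stack([x, 5.0 * t, np.zeros_like(t)])
    return tk.Trajectory("p1", "AC", t, xyz, grasped=True)


@pytest.fixture
def pole():
    return tk.SupportSpec(kind="artificial", axis_x=120.0, axis_z=0.0,
                          radius=6.0, height=600.0)


@pytest.fixture
def clean_config():
    """Noise-free, fixed-duration BC config: every generated quantity exact."""
    return tk.study_preset(
        "BC", seed=0, duration_sd=0.0, submovement_sd=0.0,
        observation_noise_sd=0.0, terminal_jitter_sd=0.0,
    )


def make_trajectory(t, s_from_support, support, condition="AC", grasped=True, y=None):
    """Place a tip on the XZ ray from the support axis toward the origin at
    the requested surface distances; handy for building exact fixtures."""
    t = np.asarray(t, float)
    s = np.asarray(s_from_support, float)
    axis = np.array([support.axis_x, support.axis_z])
    u = -axis / np.linalg.norm(axis)
    xz = axis + u[None, :] * (support.radius + s)[:, None]
    yv = np.zeros_like(t) if y is None else np.asarray(y, float)
    xyz = np.column_stack([xz[:, 0], yv, xz[:, 1]])
    return tk.Trajectory("fx", condition, t, xyz, grasped=grasped)


@pytest.fixture
def trajectory_factory(pole):
    def factory(t, s, **kwargs):
        return make_trajectory(t, s, pole, **kwargs), pole
    return factory
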