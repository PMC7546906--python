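import math

import numpy as np
import pytest

from cortexflow.piv import FlowField, FlowSeries
from cortexflow.simulate import SimConfig


@pytest.fixture
def noiseless_config():
    """Small noiseless acquisition for exact-recovery tests."""

    def make(**overrides):
        kw = dict(
            width_px=192,
            height_px=128,
            n_frames=2,
            shot_noise=False,
            read_noise_sd=0.0,
            seed=1234,
        )
        kw.update(overrides)
        return SimConfig(**kw)

    return make


def make_field(vx, vy=None, spacing_um=2.0, units="um_min"):
    """Hand-built FlowField on a regular grid with the given um spacing."""
    vx = np.asarray(vx, dtype=float)
    vy = np.zeros_like(vx) if vy is None else np.asarray(vy, dtype=float)
    ny, nx = vx.shape
    # pixel size 1 um so x_um = x_px + 1
    return FlowField(
        x_px=np.arange(nx) * spacing_um + spacing_um - 1.0,
        y_px=np.arange(ny) * spacing_um + spacing_um - 1.0,
        vx=vx,
        vy=vy,
        valid=np.ones_like(vx, dtype=bool),
        units=units,
        pixel_size_um=1.0,
    )


def make_series(fields, dt_s=5.0):
    return FlowSeries(list(fields), frame_interval_s=dt_s)


def frame_shift_um(px_per_frame, config):
    """Velocity in um/min giving the requested px/frame displacement."""
    return px_per_frame * config.pixel_size_um * 60.0 / config.frame_interval_s


def analytic_recovery(tau_half_s, t_s, floor=0.4, plateau=1.0, pre_frames=5):
    """Closed-form double-normalized FRAP curve on the given time base."""
    t_s = np.asarray(t_s, dtype=float)
    n = np.ones_like(t_s)
    b = pre_frames
    t_rec = t_s[b:] - t_s[b]
    n[b:] = floor + (plateau - floor) * (1.0 - np.exp(-t_rec * math.log(2.0) / tau_half_s))
    return n, b
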