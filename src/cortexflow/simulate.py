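"""Synthetic cortical time-lapse movies with known ground truth.

Real cortical movies of the one-cell embryo (punctate actomyosin reporters
advected by anterior-directed flows, photobleaching experiments, equatorial
filament bands) are emulated here so that every analysis stage — particle
image velocimetry, compression rates, FRAP fitting, orientation scoring —
can be validated against a known answer.

Three generators are provided:

``simulate_cortex_movie``
    Gaussian-spot particles advected by a prescribed flow field, with
    first-order molecular turnover (whole-particle exchange at rate
    ``koff``) and camera noise.
``simulate_frap_experiment``
    A photobleaching experiment: a rectangular region drops in intensity at
    the bleach frame and recovers as a single exponential with a programmed
    half-time, on top of slow acquisition bleaching of the whole field.
``simulate_filament_band``
    Line-segment textures whose dominant orientation follows a programmed
    angle schedule, for validating orientation histograms.

All randomness flows through one seeded ``numpy`` generator per call, so a
fixed configuration and seed reproduce the output bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np

from .imagestack import ImageSequence

__all__ = [
    "SimConfig",
    "FlowModel",
    "GroundTruth",
    "simulate_cortex_movie",
    "simulate_frap_experiment",
    "simulate_filament_band",
]

#: Pixel calibration of the reference acquisition: a 192-px-wide region of
#: interest spans 34.1 um of cortex.
DEFAULT_PIXEL_SIZE_UM = 34.1 / 192.0
#: Cortical stacks are acquired every 5 s.
DEFAULT_FRAME_INTERVAL_S = 5.0


@dataclass
class SimConfig:
    """Acquisition geometry, optics and noise of a simulated movie.

    Defaults mirror a spinning-disk cortical acquisition: ~0.178 um pixels,
    one frame every 5 s, diffraction-limited spots of sigma 1.3 px.
    ``particle_density`` is in particles per square micrometre.  Setting
    ``shot_noise=False`` and ``read_noise_sd=0`` yields a noiseless movie.
    """

    width_px: int = 256
    height_px: int = 160
    n_frames: int = 40
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    particle_density: float = 1.5
    psf_sigma_px: float = 1.3
    photon_scale: float = 150.0
    bg_photons: float = 10.0
    read_noise_sd: float = 2.0
    shot_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.width_px, self.height_px, self.n_frames) <= 0:
            raise ValueError("width_px, height_px and n_frames must be positive")
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("calibration must be positive")
        if self.particle_density <= 0:
            raise ValueError("particle_density must be positive")
        if self.psf_sigma_px <= 0:
            raise ValueError("psf_sigma_px must be positive")
        if self.read_noise_sd < 0:
            raise ValueError("read_noise_sd must be non-negative")

    @property
    def width_um(self) -> float:
        return self.width_px * self.pixel_size_um

    @property
    def height_um(self) -> float:
        return self.height_px * self.pixel_size_um


@dataclass
class FlowModel:
    """A prescribed cortical velocity field ``(x_um, y_um, t_s) -> (Vx, Vy)``.

    Kinds
    -----
    ``uniform``
        Spatially and temporally constant ``(vmax_um_min, vy_um_min)``.
        Zero spatial gradient by construction.
    ``control_like``
        Anterior-directed flow (negative Vx) whose magnitude ramps up
        across the equator: near zero at the anterior pole, ``-vmax`` in
        the posterior half, with a temporal ramp of ``ramp_time_s``.  This
        reproduces the control phenotype in which flow speed is highest in
        the posterior half and the velocity gradient — hence compression —
        is concentrated at the equatorial band.
    ``flat_erratic``
        Weak flow with no coherent direction: a sum of seeded sinusoids of
        short spatial wavelength in x, y and t, peak magnitude ``vmax``.
        Emulates motor-dead-myosin cortices.
    ``bidirectional``
        Both halves flow toward the equator (anterior side positive Vx,
        posterior side negative), as during ring constriction.

    ``vmax_um_min`` is the peak speed in um/min; positions are in um with
    x = 0 at the anterior edge of the field.
    """

    kind: str = "control_like"
    vmax_um_min: float = 4.5
    vy_um_min: float = 0.0
    equator_um: float = 17.0
    ramp_um: float = 4.0
    ramp_time_s: float = 40.0
    noise_wavelength_um: float = 5.0
    noise_period_s: float = 30.0
    seed: int = 0

    _phases: np.ndarray = field(init=False, repr=False)

    _KINDS = ("uniform", "control_like", "flat_erratic", "bidirectional")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"unknown flow kind {self.kind!r}; choose from {self._KINDS}")
        rng = np.random.default_rng(self.seed)
        # random phases for the erratic model's sinusoid bank (fixed at
        # construction so the velocity function is deterministic)
        self._phases = rng.uniform(0.0, 2.0 * np.pi, size=(2, 4, 3))

    def velocity(
        self, x_um: np.ndarray, y_um: np.ndarray, t_s: float
    ) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate the field at positions (um) and time (s); returns um/min."""
        x = np.asarray(x_um, dtype=float)
        y = np.asarray(y_um, dtype=float)
        if self.kind == "uniform":
            vx = np.full_like(x, self.vmax_um_min)
            vy = np.full_like(x, self.vy_um_min)
            return vx, vy
        if self.kind == "control_like":
            ramp_t = min(1.0, t_s / self.ramp_time_s) if self.ramp_time_s > 0 else 1.0
            profile = 1.0 / (1.0 + np.exp(-(x - self.equator_um) / self.ramp_um))
            vx = -self.vmax_um_min * ramp_t * profile
            return vx, np.zeros_like(x)
        if self.kind == "bidirectional":
            vx = -self.vmax_um_min * np.tanh((x - self.equator_um) / self.ramp_um)
            return vx, np.zeros_like(x)
        # flat_erratic: bank of incommensurate sinusoids, seeded phases
        lam = self.noise_wavelength_um
        per = self.noise_period_s
        freqs = np.array([1.0, 1.37, 1.93, 2.51])
        out = []
        for c in range(2):
            v = np.zeros_like(x)
            for k, f in enumerate(freqs):
                ph = self._phases[c, k]
                v = v + np.sin(
                    2 * np.pi * (f * x / lam + ph[0])
                    + 2 * np.pi * (f * y / lam + ph[1])
                    + 2 * np.pi * (f * t_s / per + ph[2])
                )
            out.append(v / len(freqs) * self.vmax_um_min)
        return out[0], out[1]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "vmax_um_min": self.vmax_um_min,
            "vy_um_min": self.vy_um_min,
            "equator_um": self.equator_um,
            "ramp_um": self.ramp_um,
            "ramp_time_s": self.ramp_time_s,
            "noise_wavelength_um": self.noise_wavelength_um,
            "noise_period_s": self.noise_period_s,
            "seed": self.seed,
        }


@dataclass
class GroundTruth:
    """The simulator's programmed truth, for recovery tests.

    ``velocity_fn`` evaluates the true flow at any simulated position and
    time; ``angle_program`` gives the true filament angle in degrees.
    ``to_json`` serialises the scalar parameters (callables are described
    by their generating parameters in ``params``).
    """

    velocity_fn: Callable | None = None
    koff_true_s: float = 0.0
    tau_half_true_s: float | None = None
    angle_program: Callable | None = None
    params: dict = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "koff_true_s": self.koff_true_s,
            "tau_half_true_s": self.tau_half_true_s,
            "seed": self.seed,
            "params": self.params,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


# --------------------------------------------------------------------------
# rendering helpers
# --------------------------------------------------------------------------

def _render_gaussians(
    x_px: np.ndarray,
    y_px: np.ndarray,
    amplitudes: np.ndarray | float,
    shape: tuple[int, int],
    sigma: float,
) -> np.ndarray:
    """Scatter 2-D Gaussian spots at subpixel positions onto a frame.

    The domain is toroidal: spots wrap around the frame edges, matching
    the periodic advection of particle positions.  Rendering is therefore
    exactly translation-equivariant — shifting every position by an
    integer number of pixels rolls the rendered image by the same amount.
    """
    h, w = shape
    r = int(math.ceil(4.0 * sigma))
    x_px = np.mod(np.asarray(x_px, dtype=float), w)
    y_px = np.mod(np.asarray(y_px, dtype=float), h)
    amp = np.broadcast_to(np.asarray(amplitudes, dtype=float), x_px.shape)
    if x_px.size == 0:
        return np.zeros(shape)
    x0 = np.floor(x_px).astype(int)
    y0 = np.floor(y_px).astype(int)
    fx = x_px - x0
    fy = y_px - y0
    off = np.arange(-r, r + 1)
    gx = np.exp(-((off[None, :] - fx[:, None]) ** 2) / (2.0 * sigma**2))
    gy = np.exp(-((off[None, :] - fy[:, None]) ** 2) / (2.0 * sigma**2))
    stamps = amp[:, None, None] * gy[:, :, None] * gx[:, None, :]
    pad = r + 1
    canvas = np.zeros((h + 2 * pad, w + 2 * pad))
    rows = (y0[:, None] + off)[:, :, None] + pad
    cols = (x0[:, None] + off)[:, None, :] + pad
    np.add.at(canvas, (np.broadcast_to(rows, stamps.shape), np.broadcast_to(cols, stamps.shape)), stamps)
    # fold the padded margins back periodically
    row_idx = (np.arange(h + 2 * pad) - pad) % h
    col_idx = (np.arange(w + 2 * pad) - pad) % w
    tmp = np.zeros((h, w + 2 * pad))
    np.add.at(tmp, row_idx, canvas)
    frame = np.zeros((h, w))
    np.add.at(frame.T, col_idx, tmp.T)
    return frame


def _apply_camera(frame: np.ndarray, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Shot noise (Poisson) then additive Gaussian read noise, clipped at 0."""
    img = frame + config.bg_photons
    if config.shot_noise:
        img = rng.poisson(np.clip(img, 0, None)).astype(float)
    if config.read_noise_sd > 0:
        img = img + rng.normal(0.0, config.read_noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


# --------------------------------------------------------------------------
# particle movie
# --------------------------------------------------------------------------

def simulate_cortex_movie(
    config: SimConfig,
    flow: FlowModel,
    koff: float = 0.0,
) -> tuple[ImageSequence, GroundTruth]:
    """Render a particle movie advected by ``flow`` with turnover rate ``koff``.

    Particles are seeded uniformly at ``config.particle_density`` per um^2
    and advected each frame by the flow evaluated at their position
    (forward Euler over one frame interval), wrapping periodically at the
    field edges.  Turnover is whole-particle exchange: each particle is
    removed with probability ``1 - exp(-koff * dt)`` per frame and a
    Poisson-distributed number of fresh particles appears at uniform
    random positions, keeping the mean density stationary.

    Returns the movie and a :class:`GroundTruth` whose ``velocity_fn`` is
    the programmed field.
    """
    if koff < 0:
        raise ValueError("koff must be non-negative")
    rng = np.random.default_rng(config.seed)
    w_um, h_um = config.width_um, config.height_um
    n_target = config.particle_density * w_um * h_um
    n0 = int(round(n_target))
    xs = rng.uniform(0.0, w_um, size=n0)
    ys = rng.uniform(0.0, h_um, size=n0)

    dt_min = config.frame_interval_s / 60.0
    survival = math.exp(-koff * config.frame_interval_s)

    frames = np.empty((config.n_frames, config.height_px, config.width_px))
    for f in range(config.n_frames):
        t = f * config.frame_interval_s
        img = _render_gaussians(
            xs / config.pixel_size_um,
            ys / config.pixel_size_um,
            config.photon_scale,
            (config.height_px, config.width_px),
            config.psf_sigma_px,
        )
        frames[f] = _apply_camera(img, config, rng)
        if f == config.n_frames - 1:
            break
        vx, vy = flow.velocity(xs, ys, t)
        if not (np.all(np.isfinite(vx)) and np.all(np.isfinite(vy))):
            raise ValueError(
                f"flow model {flow.kind!r} returned non-finite velocity at t={t} s"
            )
        xs = np.mod(xs + vx * dt_min, w_um)
        ys = np.mod(ys + vy * dt_min, h_um)
        if koff > 0:
            alive = rng.random(xs.size) < survival
            xs, ys = xs[alive], ys[alive]
            n_new = rng.poisson(n_target * (1.0 - survival))
            xs = np.concatenate([xs, rng.uniform(0.0, w_um, size=n_new)])
            ys = np.concatenate([ys, rng.uniform(0.0, h_um, size=n_new)])

    movie = ImageSequence(
        frames,
        pixel_size_um=config.pixel_size_um,
        frame_interval_s=config.frame_interval_s,
        channel="synthetic-cortex",
    )
    truth = GroundTruth(
        velocity_fn=flow.velocity,
        koff_true_s=koff,
        params={"flow": flow.to_dict(), "koff_s": koff},
        seed=config.seed,
    )
    return movie, truth


# --------------------------------------------------------------------------
# FRAP experiment
# --------------------------------------------------------------------------

#: ROI geometries used in the reference photobleaching protocol, px (w, h).
FRAP_ROI_SHAPES = {
    "posterior_cortex": (5, 5),
    "posterior_cytoplasm": (5, 5),
    "ingressing_furrow": (5, 15),
    "division_plane": (15, 200),
}


def simulate_frap_experiment(
    config: SimConfig,
    tau_half_true_s: float,
    bleach_frame: int,
    bleach_roi: tuple[int, int, int, int],
    plateau_fraction: float = 1.0,
    bleach_depth: float = 0.6,
    acq_bleach_tau_s: float = 500.0,
) -> tuple[ImageSequence, GroundTruth]:
    """Simulate a photobleaching movie with exponential recovery.

    The field is a uniform fluorescent "embryo" patch (central 80% of the
    frame) of mean intensity ``photon_scale`` on a camera background of
    ``bg_photons``.  At ``bleach_frame`` the intensity inside
    ``bleach_roi`` (x, y, width, height in px) drops by ``bleach_depth``
    and then recovers as::

        I(t) = floor + A * (1 - exp(-t * ln 2 / tau_half))

    with ``floor = 1 - bleach_depth`` and plateau
    ``floor + plateau_fraction * bleach_depth`` (relative units).  The
    whole field additionally decays with time constant ``acq_bleach_tau_s``
    to exercise acquisition-bleaching correction downstream.

    ``movie.meta['rois']`` records the bleach, embryo and background ROIs
    and ``movie.meta['bleach_frame']`` the bleach index.
    """
    if not 0 < bleach_frame < config.n_frames:
        raise ValueError("bleach_frame must lie strictly inside the movie")
    if not 0.0 <= plateau_fraction <= 1.0:
        raise ValueError("plateau_fraction must be in [0, 1]")
    if not 0.0 < bleach_depth <= 1.0:
        raise ValueError("bleach_depth must be in (0, 1]")
    bx, by, bw, bh = bleach_roi
    h, w = config.height_px, config.width_px
    # embryo occupies the central 80% of the frame
    ex0, ey0 = int(0.1 * w), int(0.1 * h)
    ex1, ey1 = w - ex0, h - ey0
    if not (ex0 <= bx and bx + bw <= ex1 and ey0 <= by and by + bh <= ey1):
        raise ValueError("bleach_roi must lie inside the embryo region")

    rng = np.random.default_rng(config.seed)
    floor = 1.0 - bleach_depth
    amp = plateau_fraction * bleach_depth
    rate = math.log(2.0) / tau_half_true_s

    frames = np.empty((config.n_frames, h, w))
    for f in range(config.n_frames):
        t = f * config.frame_interval_s
        field_img = np.zeros((h, w))
        acq = math.exp(-t / acq_bleach_tau_s) if acq_bleach_tau_s > 0 else 1.0
        field_img[ey0:ey1, ex0:ex1] = config.photon_scale * acq
        if f >= bleach_frame:
            t_rec = (f - bleach_frame) * config.frame_interval_s
            rel = floor + amp * (1.0 - math.exp(-t_rec * rate))
            field_img[by : by + bh, bx : bx + bw] *= rel
        frames[f] = _apply_camera(field_img, config, rng)

    movie = ImageSequence(
        frames,
        pixel_size_um=config.pixel_size_um,
        frame_interval_s=config.frame_interval_s,
        channel="synthetic-frap",
        meta={
            "rois": {
                "bleach": [bx, by, bw, bh],
                "embryo": [ex0, ey0, ex1 - ex0, ey1 - ey0],
                "background": [0, 0, ex0, ey0],
            },
            "bleach_frame": bleach_frame,
        },
    )
    truth = GroundTruth(
        tau_half_true_s=tau_half_true_s,
        koff_true_s=rate,
        params={
            "tau_half_s": tau_half_true_s,
            "bleach_frame": bleach_frame,
            "bleach_depth": bleach_depth,
            "plateau_fraction": plateau_fraction,
            "acq_bleach_tau_s": acq_bleach_tau_s,
        },
        seed=config.seed,
    )
    return movie, truth


# --------------------------------------------------------------------------
# filament band
# --------------------------------------------------------------------------

def simulate_filament_band(
    config: SimConfig,
    angle_program: Callable[[float], float],
    dispersion_deg: float = 0.0,
    n_segments: int = 80,
    segment_len_um: float = 4.0,
) -> tuple[ImageSequence, GroundTruth]:
    """Render frames of line segments around a programmed orientation.

    ``angle_program(t_s)`` gives the true dominant angle in degrees
    (counter-clockwise from the x-axis; 90 deg = perpendicular to the long
    axis).  Individual segment orientations are drawn from a von Mises
    distribution on doubled angles around the program value, with angular
    spread ``dispersion_deg`` (0 = perfectly parallel segments).
    """
    if dispersion_deg < 0:
        raise ValueError("dispersion_deg must be non-negative")
    rng = np.random.default_rng(config.seed)
    h, w = config.height_px, config.width_px
    seg_len_px = segment_len_um / config.pixel_size_um

    angles_true = np.empty(config.n_frames)
    frames = np.empty((config.n_frames, h, w))
    for f in range(config.n_frames):
        t = f * config.frame_interval_s
        alpha = float(angle_program(t))
        angles_true[f] = alpha
        cx = rng.uniform(0, w, size=n_segments)
        cy = rng.uniform(0, h, size=n_segments)
        if dispersion_deg > 0:
            sigma2 = 2.0 * math.radians(dispersion_deg)  # spread on doubled angles
            kappa = 1.0 / sigma2**2
            th2 = rng.vonmises(2.0 * math.radians(alpha), kappa, size=n_segments)
            seg_angles = th2 / 2.0
        else:
            seg_angles = np.full(n_segments, math.radians(alpha))
        # sample points along each segment and stamp Gaussians
        n_pts = max(3, int(seg_len_px * 2))
        s = np.linspace(-0.5, 0.5, n_pts)
        px = (cx[:, None] + s[None, :] * seg_len_px * np.cos(seg_angles)[:, None]).ravel()
        # image y grows downward; drawing with -sin keeps angles CCW from x-axis
        py = (cy[:, None] - s[None, :] * seg_len_px * np.sin(seg_angles)[:, None]).ravel()
        img = _render_gaussians(
            px, py, config.photon_scale / n_pts * 4.0, (h, w), config.psf_sigma_px
        )
        frames[f] = _apply_camera(img, config, rng)

    movie = ImageSequence(
        frames,
        pixel_size_um=config.pixel_size_um,
        frame_interval_s=config.frame_interval_s,
        channel="synthetic-filaments",
    )
    truth = GroundTruth(
        angle_program=angle_program,
        params={
            "dispersion_deg": dispersion_deg,
            "angles_true_deg": angles_true.tolist(),
            "n_segments": n_segments,
            "segment_len_um": segment_len_um,
        },
        seed=config.seed,
    )
    return movie, truth
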