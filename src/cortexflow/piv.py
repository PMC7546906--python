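"""Two-pass iterative particle image velocimetry (PIV).

Velocity fields are estimated from consecutive frame pairs by FFT-based
normalized cross-correlation of interrogation windows: a first pass with
large windows (default 64 px) captures the bulk displacement, and a second
pass with smaller windows (default 32 px) refines it, with each pass-2
search window offset by the rounded pass-1 displacement interpolated to the
finer grid.  Consecutive windows overlap by 50%.  Displacements are
localized to sub-pixel precision with a three-point Gaussian fit and
screened with a normalized median test.

Sign convention: x is the anterior-posterior axis, y the dorsal-ventral
axis; negative Vx means posterior-to-anterior flow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .imagestack import ImageSequence

__all__ = [
    "PivParams",
    "FlowField",
    "FlowSeries",
    "correlate_window",
    "subpixel_peak",
    "validate_vectors",
    "run_piv",
    "to_physical",
    "to_pixels",
]


class FlatPatchError(ValueError):
    """Raised when a correlation window has zero intensity variance."""


class BorderPeakError(ValueError):
    """Raised when the correlation peak lies on the map border."""


@dataclass
class PivParams:
    """Interrogation parameters for the two-pass PIV engine.

    ``roi`` is ``(x0, y0, width, height)`` in frame pixels; when ``None``
    a 192 x 128 px region centered on the frame is used, the standard
    cortical region of interest.  Window sides must be powers of two with
    the second pass no larger than the first.
    """

    window_pass1_px: int = 64
    window_pass2_px: int = 32
    overlap_fraction: float = 0.5
    roi: tuple[int, int, int, int] | None = None
    validation_threshold: float = 2.0

    def __post_init__(self) -> None:
        for w in (self.window_pass1_px, self.window_pass2_px):
            if w < 4 or (w & (w - 1)) != 0:
                raise ValueError(f"window size {w} must be a power of two >= 4")
        if self.window_pass2_px > self.window_pass1_px:
            raise ValueError("second-pass window must not exceed first-pass window")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")

    def resolve_roi(self, frame_shape: tuple[int, int]) -> tuple[int, int, int, int]:
        h, w = frame_shape
        if self.roi is None:
            rw, rh = min(192, w), min(128, h)
            return ((w - rw) // 2, (h - rh) // 2, rw, rh)
        x0, y0, rw, rh = self.roi
        if x0 < 0 or y0 < 0 or x0 + rw > w or y0 + rh > h:
            raise ValueError(f"ROI {self.roi} does not fit inside frame {frame_shape}")
        return x0, y0, rw, rh


@dataclass
class FlowField:
    """A regular grid of velocity vectors for one frame pair.

    ``x_px``/``y_px`` are anchor positions (window centers) in 0-based ROI
    coordinates; ``vx``/``vy`` are ``(ny, nx)`` velocity components in the
    units named by ``units`` (``"px_frame"`` straight from correlation,
    ``"um_min"`` after calibration).  ``valid`` flags vectors that passed
    correlation and outlier screening.
    """

    x_px: np.ndarray
    y_px: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    valid: np.ndarray
    units: str = "px_frame"
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def x_um(self) -> np.ndarray:
        """Anchor positions along A-P in um (1-based pixel convention)."""
        if self.pixel_size_um is None:
            raise ValueError("field is not calibrated")
        return (np.asarray(self.x_px) + 1.0) * self.pixel_size_um

    @property
    def y_um(self) -> np.ndarray:
        if self.pixel_size_um is None:
            raise ValueError("field is not calibrated")
        return (np.asarray(self.y_px) + 1.0) * self.pixel_size_um


@dataclass
class FlowSeries:
    """Ordered FlowFields, one per consecutive frame pair."""

    fields: list[FlowField]
    frame_interval_s: float
    timestamps_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.timestamps_s is None:
            self.timestamps_s = np.arange(len(self.fields)) * self.frame_interval_s
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if len(self.timestamps_s) != len(self.fields):
            raise ValueError("one timestamp per frame pair required")

    def __len__(self) -> int:
        return len(self.fields)

    def __getitem__(self, i: int) -> FlowField:
        return self.fields[i]

    def aligned(self, event_time_s: float) -> "FlowSeries":
        """Shift timestamps so the given event time becomes t = 0."""
        return FlowSeries(
            self.fields, self.frame_interval_s, self.timestamps_s - event_time_s
        )


# --------------------------------------------------------------------------
# correlation primitives
# --------------------------------------------------------------------------

def correlate_window(template: np.ndarray, search: np.ndarray) -> np.ndarray:
    """Normalized FFT cross-correlation of two equally sized patches.

    Returns a centered correlation map of the same shape: the peak at
    offset ``(dy, dx)`` from the map center means the pattern of
    ``template`` appears in ``search`` displaced by ``(dy, dx)`` pixels.
    Values are normalized so perfect correlation gives 1 at the peak.

    Raises
    ------
    FlatPatchError
        If either patch has zero intensity variance (uniform background).
    """
    a = np.asarray(template, dtype=float)
    b = np.asarray(search, dtype=float)
    if a.shape != b.shape:
        raise ValueError("patches must have identical shape")
    a = a - a.mean()
    b = b - b.mean()
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        raise FlatPatchError("zero-variance interrogation window")
    c = np.fft.irfft2(np.conj(np.fft.rfft2(a)) * np.fft.rfft2(b), s=a.shape)
    c /= sa * sb * a.size
    c = np.fft.fftshift(c)
    # correct the displacement bias of windowed FFT correlation: divide by
    # the triangular overlap weighting, floored at 0.5 to avoid blowing up
    # noise at extreme lags
    ny, nx = c.shape
    wy = np.maximum(1.0 - np.abs(np.arange(ny) - ny // 2) / ny, 0.5)
    wx = np.maximum(1.0 - np.abs(np.arange(nx) - nx // 2) / nx, 0.5)
    return c / np.outer(wy, wx)


def subpixel_peak(corr: np.ndarray) -> tuple[float, float]:
    """Sub-pixel displacement ``(dx, dy)`` from a centered correlation map.

    The integer peak (first in row-major order on ties) is refined along
    each axis with a three-point Gaussian fit; if any of the three samples
    is non-positive the fit falls back to a parabola.

    Raises
    ------
    BorderPeakError
        If the integer peak lies on the map border, where no three-point
        neighborhood exists.
    """
    corr = np.asarray(corr, dtype=float)
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    ny, nx = corr.shape
    if iy == 0 or iy == ny - 1 or ix == 0 or ix == nx - 1:
        raise BorderPeakError("correlation peak on map border")

    def refine(cm: float, c0: float, cp: float) -> float:
        if cm > 0 and c0 > 0 and cp > 0:
            denom = math.log(cm) + math.log(cp) - 2.0 * math.log(c0)
            if denom < 0:
                return 0.5 * (math.log(cm) - math.log(cp)) / denom
        denom = cm + cp - 2.0 * c0
        if denom < 0:
            return 0.5 * (cm - cp) / denom
        return 0.0

    dx = (ix - nx // 2) + refine(corr[iy, ix - 1], corr[iy, ix], corr[iy, ix + 1])
    dy = (iy - ny // 2) + refine(corr[iy - 1, ix], corr[iy, ix], corr[iy + 1, ix])
    return dx, dy


# --------------------------------------------------------------------------
# vector validation
# --------------------------------------------------------------------------

def validate_vectors(fld: FlowField, threshold: float = 2.0, eps: float = 0.1) -> FlowField:
    """Normalized median test on 3x3 neighborhoods (Westerweel-Scarano).

    Each component is compared against the median of its valid neighbors,
    normalized by the median absolute residual plus a regularization
    ``eps`` (in the field's velocity units).  Vectors exceeding
    ``threshold`` on either component are replaced by the neighborhood
    median and flagged invalid; with fewer than three valid neighbors the
    vector is flagged but left unreplaced.
    """
    ny, nx = fld.vx.shape
    if fld.vx.size == 0:
        raise ValueError("empty flow field")
    vx, vy = fld.vx.copy(), fld.vy.copy()
    valid = fld.valid.copy()
    out_valid = valid.copy()
    for j in range(ny):
        for i in range(nx):
            if not valid[j, i]:
                continue
            ys = slice(max(0, j - 1), min(ny, j + 2))
            xs = slice(max(0, i - 1), min(nx, i + 2))
            mask = valid[ys, xs].copy()
            mask[j - max(0, j - 1), i - max(0, i - 1)] = False
            nb_vx = fld.vx[ys, xs][mask]
            nb_vy = fld.vy[ys, xs][mask]
            if nb_vx.size < 3:
                out_valid[j, i] = False
                continue
            bad = False
            for comp, nb in ((fld.vx[j, i], nb_vx), (fld.vy[j, i], nb_vy)):
                med = np.median(nb)
                resid = np.median(np.abs(nb - med))
                if abs(comp - med) / (resid + eps) > threshold:
                    bad = True
            if bad:
                vx[j, i] = np.median(nb_vx)
                vy[j, i] = np.median(nb_vy)
                out_valid[j, i] = False
    return replace(fld, vx=vx, vy=vy, valid=out_valid)


# --------------------------------------------------------------------------
# unit conversion
# --------------------------------------------------------------------------

def to_physical(fld: FlowField, pixel_size_um: float, frame_interval_s: float) -> FlowField:
    """Convert a px/frame field to um/min: ``v * pixel_size * 60 / dt``."""
    if pixel_size_um <= 0 or frame_interval_s <= 0:
        raise ValueError("calibration must be positive")
    if fld.units != "px_frame":
        raise ValueError(f"expected px_frame field, got {fld.units}")
    scale = pixel_size_um * 60.0 / frame_interval_s
    return replace(
        fld,
        vx=fld.vx * scale,
        vy=fld.vy * scale,
        units="um_min",
        pixel_size_um=pixel_size_um,
    )


def to_pixels(fld: FlowField, pixel_size_um: float, frame_interval_s: float) -> FlowField:
    """Inverse of :func:`to_physical`."""
    if pixel_size_um <= 0 or frame_interval_s <= 0:
        raise ValueError("calibration must be positive")
    if fld.units != "um_min":
        raise ValueError(f"expected um_min field, got {fld.units}")
    scale = pixel_size_um * 60.0 / frame_interval_s
    return replace(
        fld, vx=fld.vx / scale, vy=fld.vy / scale, units="px_frame", pixel_size_um=None
    )


# --------------------------------------------------------------------------
# two-pass engine
# --------------------------------------------------------------------------

def _grid_1d(extent: int, window: int, step: int) -> np.ndarray:
    """Top-left offsets of windows fitting entirely inside ``extent``."""
    n = (extent - window) // step + 1
    return np.arange(max(n, 0)) * step


def _pair_displacements(
    f1: np.ndarray,
    f2: np.ndarray,
    roi: tuple[int, int, int, int],
    window: int,
    step: int,
    guess: tuple[np.ndarray, np.ndarray] | None = None,
) -> FlowField:
    """Single-pass displacements on a regular window grid.

    ``guess`` optionally supplies integer pre-shifts (vx, vy arrays on the
    same grid) applied to the search window before correlation.
    """
    x0, y0, rw, rh = roi
    gx = _grid_1d(rw, window, step)
    gy = _grid_1d(rh, window, step)
    nx, ny = len(gx), len(gy)
    h, w = f1.shape
    vx = np.zeros((ny, nx))
    vy = np.zeros((ny, nx))
    valid = np.zeros((ny, nx), dtype=bool)
    for j, oy in enumerate(gy):
        for i, ox in enumerate(gx):
            ty, tx = y0 + oy, x0 + ox
            tpl = f1[ty : ty + window, tx : tx + window]
            if guess is not None:
                sx = int(round(guess[0][j, i]))
                sy = int(round(guess[1][j, i]))
            else:
                sx = sy = 0
            # clamp the offset search window to the frame, never pad
            sy = int(np.clip(ty + sy, 0, h - window)) - ty
            sx = int(np.clip(tx + sx, 0, w - window)) - tx
            srch = f2[ty + sy : ty + sy + window, tx + sx : tx + sx + window]
            try:
                cmap = correlate_window(tpl, srch)
                ddx, ddy = subpixel_peak(cmap)
            except (FlatPatchError, BorderPeakError):
                continue
            vx[j, i] = sx + ddx
            vy[j, i] = sy + ddy
            valid[j, i] = True
    # window-center anchors in ROI coordinates (0-based)
    cx = gx + (window - 1) / 2.0
    cy = gy + (window - 1) / 2.0
    return FlowField(x_px=cx, y_px=cy, vx=vx, vy=vy, valid=valid)


def _interp_to_grid(src: FlowField, x_new: np.ndarray, y_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear interpolation (linear extrapolation at edges) of a field."""
    vx = src.vx.copy()
    vy = src.vy.copy()
    if not src.valid.all() and src.valid.any():
        vx[~src.valid] = np.median(src.vx[src.valid])
        vy[~src.valid] = np.median(src.vy[src.valid])
    out = []
    yy, xx = np.meshgrid(y_new, x_new, indexing="ij")
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1)
    for comp in (vx, vy):
        if comp.shape[0] < 2 or comp.shape[1] < 2:
            out.append(np.full((len(y_new), len(x_new)), comp.mean()))
            continue
        itp = RegularGridInterpolator(
            (src.y_px, src.x_px), comp, bounds_error=False, fill_value=None
        )
        out.append(itp(pts).reshape(len(y_new), len(x_new)))
    return out[0], out[1]


def run_piv(movie: ImageSequence, params: PivParams | None = None) -> FlowSeries:
    """Two-pass PIV over all consecutive frame pairs of a movie.

    Pass 1 estimates displacements on the coarse window grid and validates
    them; pass 2 repeats on the fine grid with search windows offset by the
    rounded pass-1 prediction.  The returned series is calibrated to um/min
    with timestamps at the first frame of each pair.
    """
    params = params or PivParams()
    if movie.n_frames < 2:
        raise ValueError("PIV needs at least two frames")
    roi = params.resolve_roi(movie.shape)
    step1 = max(1, int(params.window_pass1_px * (1.0 - params.overlap_fraction)))
    step2 = max(1, int(params.window_pass2_px * (1.0 - params.overlap_fraction)))

    fields = []
    any_allinvalid = False
    for k in range(movie.n_frames - 1):
        f1, f2 = movie.frames[k], movie.frames[k + 1]
        pass1 = _pair_displacements(f1, f2, roi, params.window_pass1_px, step1)
        if pass1.valid.any():
            pass1 = validate_vectors(pass1, params.validation_threshold)
        # fine grid
        x0, y0, rw, rh = roi
        gx2 = _grid_1d(rw, params.window_pass2_px, step2)
        gy2 = _grid_1d(rh, params.window_pass2_px, step2)
        cx2 = gx2 + (params.window_pass2_px - 1) / 2.0
        cy2 = gy2 + (params.window_pass2_px - 1) / 2.0
        if pass1.valid.any():
            gvx, gvy = _interp_to_grid(pass1, cx2, cy2)
            guess = (gvx, gvy)
        else:
            guess = None
        pass2 = _pair_displacements(
            f1, f2, roi, params.window_pass2_px, step2, guess=guess
        )
        if pass2.valid.any():
            pass2 = validate_vectors(pass2, params.validation_threshold)
        else:
            any_allinvalid = True
        fields.append(to_physical(pass2, movie.pixel_size_um, movie.frame_interval_s))
    if any_allinvalid:
        warnings.warn("at least one frame pair produced no valid vectors", stacklevel=2)
    return FlowSeries(fields, frame_interval_s=movie.frame_interval_s)
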