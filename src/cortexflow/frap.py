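"""FRAP (fluorescence recovery after photobleaching) analysis.

Workflow mirrors the easyFRAP convention: extract mean-intensity traces
from three ROIs (bleached region, whole embryo, camera background),
correct for acquisition photobleaching with the simple ratio method,
apply double normalization so the pre-bleach level is 1, fit a single
exponential to the recovery, and extrapolate the dissociation rate

    k_off = ln(2) / tau_half

from the fitted half-time of recovery.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import curve_fit

from .imagestack import ImageSequence

__all__ = [
    "RoiTraces",
    "NormalizedRecovery",
    "FrapFit",
    "extract_traces",
    "bleach_correct",
    "double_normalize",
    "fit_recovery",
    "dissociation_rate",
]


@dataclass
class RoiTraces:
    """Mean-intensity time courses of the three FRAP ROIs.

    ``roi1`` is the bleached region, ``roi2`` the whole embryo (corrects
    for acquisition bleaching), ``roi3`` the camera background.
    """

    t_s: np.ndarray
    roi1: np.ndarray
    roi2: np.ndarray
    roi3: np.ndarray
    bleach_frame: int

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.roi1 = np.asarray(self.roi1, dtype=float)
        self.roi2 = np.asarray(self.roi2, dtype=float)
        self.roi3 = np.asarray(self.roi3, dtype=float)
        n = len(self.t_s)
        if not (len(self.roi1) == len(self.roi2) == len(self.roi3) == n):
            raise ValueError("all traces must have equal length")
        if not 0 < self.bleach_frame < n:
            raise ValueError("bleach_frame must lie strictly inside the series")

    @property
    def pre_slice(self) -> slice:
        return slice(0, self.bleach_frame)


@dataclass
class NormalizedRecovery:
    """Double-normalized recovery curve (pre-bleach mean = 1)."""

    t_s: np.ndarray
    intensity: np.ndarray
    bleach_frame: int


@dataclass
class FrapFit:
    """Single-exponential recovery fit ``N(t) = N0 + A (1 - exp(-t/tau))``.

    ``tau_half_s = tau_s * ln 2`` and ``koff_s = ln 2 / tau_half_s``.
    ``mobile_fraction`` is ``(plateau - floor) / (1 - floor)``; it is an
    optional diagnostic, not needed for the turnover rate.
    ``identifiable`` is False when the curve shows no recovery (amplitude
    indistinguishable from zero), in which case the time constants are NaN.
    """

    tau_s: float
    tau_half_s: float
    koff_s: float
    plateau: float
    amplitude: float
    floor: float
    residual_norm: float
    mobile_fraction: float
    identifiable: bool = True


def _roi_mean(frames: np.ndarray, roi: tuple[int, int, int, int]) -> np.ndarray:
    x0, y0, w, h = roi
    return frames[:, y0 : y0 + h, x0 : x0 + w].mean(axis=(1, 2))


def extract_traces(
    movie: ImageSequence,
    bleach_roi: tuple[int, int, int, int] | None = None,
    embryo_roi: tuple[int, int, int, int] | None = None,
    background_roi: tuple[int, int, int, int] | None = None,
    bleach_frame: int | None = None,
) -> RoiTraces:
    """Mean-intensity traces for the three FRAP ROIs of a movie.

    ROI rectangles are ``(x0, y0, width, height)`` in px; any omitted ROI
    or the bleach frame is taken from ``movie.meta`` (as written by the
    FRAP simulator).
    """
    meta_rois = movie.meta.get("rois", {})
    bleach_roi = bleach_roi or tuple(meta_rois.get("bleach", ()))
    embryo_roi = embryo_roi or tuple(meta_rois.get("embryo", ()))
    background_roi = background_roi or tuple(meta_rois.get("background", ()))
    if bleach_frame is None:
        bleach_frame = movie.meta.get("bleach_frame")
    if not (bleach_roi and embryo_roi and background_roi) or bleach_frame is None:
        raise ValueError("ROIs and bleach frame must be given or present in movie.meta")
    return RoiTraces(
        t_s=movie.times_s,
        roi1=_roi_mean(movie.frames, bleach_roi),
        roi2=_roi_mean(movie.frames, embryo_roi),
        roi3=_roi_mean(movie.frames, background_roi),
        bleach_frame=int(bleach_frame),
    )


def bleach_correct(traces: RoiTraces) -> RoiTraces:
    """Simple-ratio correction for acquisition photobleaching.

    After background subtraction, every trace is multiplied per frame by
    ``mean_pre(roi2) / roi2(t)``, pinning the whole-embryo signal at its
    pre-bleach level.  The returned background trace is zero (already
    subtracted).
    """
    r1 = traces.roi1 - traces.roi3
    r2 = traces.roi2 - traces.roi3
    if np.any(r2 <= 0):
        bad = int(np.flatnonzero(r2 <= 0)[0])
        raise ValueError(
            f"whole-embryo trace non-positive after background subtraction at frame {bad}"
        )
    ratio = r2[traces.pre_slice].mean() / r2
    return replace(
        traces,
        roi1=r1 * ratio,
        roi2=r2 * ratio,
        roi3=np.zeros_like(traces.roi3),
    )


def double_normalize(traces: RoiTraces) -> NormalizedRecovery:
    """Double normalization of the bleached-ROI trace.

    ``N(t) = (roi1(t) - bg)/(roi2(t) - bg) * (<roi2>_pre - bg)/(<roi1>_pre - bg)``

    which makes the pre-bleach mean exactly 1 and removes residual
    whole-sample intensity drift.  Requires at least 3 pre-bleach frames.
    """
    if traces.bleach_frame < 3:
        raise ValueError("double normalization needs >= 3 pre-bleach frames")
    r1 = traces.roi1 - traces.roi3
    r2 = traces.roi2 - traces.roi3
    pre = traces.pre_slice
    if np.any(r2 == 0) or r1[pre].mean() == 0:
        raise ValueError("zero denominator in double normalization")
    n = (r1 / r2) * (r2[pre].mean() / r1[pre].mean())
    # exact unit pre-bleach mean (ratio-of-means vs mean-of-ratios residual)
    n = n / n[pre].mean()
    return NormalizedRecovery(
        t_s=traces.t_s, intensity=n, bleach_frame=traces.bleach_frame
    )


def fit_recovery(curve: NormalizedRecovery, min_amplitude: float = 1e-3) -> FrapFit:
    """Nonlinear least-squares fit of the post-bleach recovery.

    The bleach frame itself is excluded (partially exposed) and time zero
    is the first post-bleach frame.  Initial values come from a
    log-linearized estimate; the fit model is
    ``N(t) = N0 + A (1 - exp(-t/tau))``.

    Raises ``RuntimeError`` on non-convergence and ``ValueError`` if the
    fitted time constant is not positive.
    """
    b = curve.bleach_frame
    t = curve.t_s[b + 1 :] - curve.t_s[b + 1]
    y = curve.intensity[b + 1 :]
    if len(t) < 5:
        raise ValueError("need at least 5 post-bleach points")
    if np.any(y < 0):
        raise ValueError("recovery intensities must be non-negative")

    n0 = float(y[0])
    plateau0 = float(np.mean(y[-3:]))
    amp0 = plateau0 - n0
    if abs(amp0) < min_amplitude and float(np.std(y)) < min_amplitude:
        return FrapFit(
            tau_s=math.nan,
            tau_half_s=math.nan,
            koff_s=math.nan,
            plateau=plateau0,
            amplitude=0.0,
            floor=n0,
            residual_norm=float(np.linalg.norm(y - np.mean(y))),
            mobile_fraction=0.0,
            identifiable=False,
        )

    # log-linearized initial guess for tau
    resid = plateau0 * 1.02 - y
    ok = resid > 0
    if ok.sum() >= 2:
        slope = np.polyfit(t[ok], np.log(resid[ok]), 1)[0]
        tau0 = -1.0 / slope if slope < 0 else (t[-1] - t[0]) / 3.0
    else:
        tau0 = (t[-1] - t[0]) / 3.0
    tau0 = float(np.clip(tau0, 1e-3, 10.0 * (t[-1] + 1.0)))

    def model(tt, n0_, a_, tau_):
        return n0_ + a_ * (1.0 - np.exp(-tt / tau_))

    try:
        popt, _ = curve_fit(
            model,
            t,
            y,
            p0=[n0, max(amp0, min_amplitude), tau0],
            bounds=([-np.inf, 0.0, 1e-6], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy message passthrough
        raise RuntimeError(f"recovery fit did not converge: {exc}") from exc
    n0f, ampf, tauf = map(float, popt)
    if tauf <= 0:
        raise ValueError(f"fitted time constant non-positive ({tauf})")
    resid_norm = float(np.linalg.norm(model(t, *popt) - y))
    plateau = n0f + ampf
    mobile = (plateau - n0f) / (1.0 - n0f) if n0f < 1.0 else math.nan
    tau_half = tauf * math.log(2.0)
    return FrapFit(
        tau_s=tauf,
        tau_half_s=tau_half,
        koff_s=dissociation_rate(tau_half),
        plateau=plateau,
        amplitude=ampf,
        floor=n0f,
        residual_norm=resid_norm,
        mobile_fraction=mobile,
        identifiable=True,
    )


def dissociation_rate(tau_half_s: float) -> float:
    """Turnover rate from the recovery half-time: ``k_off = ln(2)/tau_half``.

    This is the standard half-life relation with the natural logarithm;
    tau_half = ln 2 s gives exactly 1.0 1/s.
    """
    if tau_half_s <= 0:
        raise ValueError("tau_half must be positive")
    return math.log(2.0) / tau_half_s
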