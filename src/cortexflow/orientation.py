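"""F-actin bundle alignment by the local gradient orientation method.

Per-pixel intensity gradients (5x5 derivative-of-Gaussian kernels) define
local structure orientations — the gradient direction rotated by 90 deg —
which are accumulated into a gradient-energy-weighted histogram over
(-90, 90] deg.  The dominant angle alpha of an ROI is the center of a
Gaussian fitted around the histogram peak, and bundle alignment is scored
as the deviation from vertical, |90 - alpha| folded into [0, 90]: 0 deg
means bundles perpendicular to the embryo's long axis, as in a properly
assembling contractile ring.

Angles are measured counter-clockwise from the image x-axis (the A-P
axis), with the y-axis taken to point up, so alpha = 90 deg denotes
vertical structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import correlate1d
from scipy.optimize import curve_fit

from .imagestack import ImageSequence

__all__ = [
    "OrientationHistogram",
    "orientation_histogram",
    "dominant_angle",
    "deviation_from_vertical",
    "orientation_trace",
]

_BIN_WIDTH_DEG = 2.0


@dataclass
class OrientationHistogram:
    """Gradient-energy-weighted orientation histogram over (-90, 90]."""

    bin_centers_deg: np.ndarray
    weights: np.ndarray
    roi: tuple[int, int, int, int]
    empty: bool = False

    def circular_mean_deg(self) -> float:
        """Weighted circular mean on doubled angles (period 180 deg)."""
        th2 = np.radians(2.0 * self.bin_centers_deg)
        s = float(np.sum(self.weights * np.sin(th2)))
        c = float(np.sum(self.weights * np.cos(th2)))
        a = math.degrees(math.atan2(s, c)) / 2.0
        return _wrap_orientation(a)


def _wrap_orientation(a: float) -> float:
    """Wrap an angle into (-90, 90]."""
    a = (a + 90.0) % 180.0 - 90.0
    if a == -90.0:
        a = 90.0
    return a


def _dog_kernels(sigma: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """5-tap Gaussian and derivative-of-Gaussian kernels."""
    k = np.arange(-2, 3, dtype=float)
    g = np.exp(-(k**2) / (2.0 * sigma**2))
    g /= g.sum()
    dg = -k / sigma**2 * np.exp(-(k**2) / (2.0 * sigma**2))
    # normalize so the response to a unit ramp is 1
    dg /= np.sum(dg * k)
    return g, dg


def orientation_histogram(
    image: np.ndarray,
    roi: tuple[int, int, int, int] | None = None,
    bin_width_deg: float = _BIN_WIDTH_DEG,
    grad_sigma: float = 1.0,
) -> OrientationHistogram:
    """Orientation histogram of an ROI (default 30 x 70 px, centered).

    Gradients are computed with separable 5x5 derivative-of-Gaussian
    kernels; each interior pixel votes for its structure orientation
    (gradient direction + 90 deg, mapped to (-90, 90]) with weight equal
    to its squared gradient magnitude.  A 2-px ROI border band is
    excluded.  A flat ROI yields an empty histogram flagged ``empty``.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    if roi is None:
        rw, rh = min(30, w), min(70, h)
        roi = ((w - rw) // 2, (h - rh) // 2, rw, rh)
    x0, y0, rw, rh = roi
    if x0 < 0 or y0 < 0 or x0 + rw > w or y0 + rh > h:
        raise ValueError(f"ROI {roi} outside image {(h, w)}")
    patch = img[y0 : y0 + rh, x0 : x0 + rw]

    g, dg = _dog_kernels(grad_sigma)
    gx = correlate1d(correlate1d(patch, dg, axis=1), g, axis=0)
    gy_img = correlate1d(correlate1d(patch, dg, axis=0), g, axis=1)
    gy = -gy_img  # array rows grow downward; flip so y points up

    b = 2  # border band affected by the 5-tap kernels
    gx, gy = gx[b:-b, b:-b], gy[b:-b, b:-b]
    energy = gx**2 + gy**2

    edges = np.arange(-90.0, 90.0 + bin_width_deg, bin_width_deg)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if not np.any(energy > 0):
        return OrientationHistogram(centers, np.zeros(len(centers)), roi, empty=True)

    theta = np.degrees(np.arctan2(gy, gx))  # gradient direction
    alpha = np.vectorize(_wrap_orientation)(theta + 90.0)  # structure orientation
    weights, _ = np.histogram(alpha.ravel(), bins=edges, weights=energy.ravel())
    return OrientationHistogram(centers, weights, roi)


def dominant_angle(
    hist: OrientationHistogram, fit_halfwidth_deg: float = 15.0
) -> float:
    """Dominant orientation of a histogram, in degrees.

    A Gaussian is fitted to the bins within +/-``fit_halfwidth_deg`` of the
    highest peak (circularly, period 180 deg; ties resolve to the lower
    angle); the fitted center is the dominant angle.  If the fit fails the
    weighted circular mean of doubled angles is returned instead.
    """
    if hist.empty or not np.any(hist.weights > 0):
        raise ValueError("empty orientation histogram")
    centers = hist.bin_centers_deg
    weights = hist.weights
    peak = centers[int(np.argmax(weights))]
    # signed circular offset from the peak, period 180
    delta = (centers - peak + 90.0) % 180.0 - 90.0
    sel = np.abs(delta) <= fit_halfwidth_deg

    def gauss(d, a, mu, s, c):
        return a * np.exp(-((d - mu) ** 2) / (2.0 * s**2)) + c

    try:
        popt, _ = curve_fit(
            gauss,
            delta[sel],
            weights[sel],
            p0=[float(weights.max()), 0.0, 5.0, 0.0],
            bounds=(
                [0.0, -fit_halfwidth_deg, 0.5, -np.inf],
                [np.inf, fit_halfwidth_deg, 90.0, np.inf],
            ),
            maxfev=5000,
        )
        return _wrap_orientation(peak + float(popt[1]))
    except RuntimeError:
        return hist.circular_mean_deg()


def deviation_from_vertical(alpha_deg: float) -> float:
    """Deviation of an orientation from vertical, folded into [0, 90] deg.

    ``|90 - alpha|``, with values beyond 90 folded back (``d -> 180 - d``):
    alpha = 90 gives 0 (perfectly aligned band), alpha = -80 gives 10.
    """
    d = abs(90.0 - float(alpha_deg)) % 180.0
    return 180.0 - d if d > 90.0 else d


def orientation_trace(
    movie: ImageSequence,
    roi: tuple[int, int, int, int] | None = None,
    align_event_s: float = 0.0,
) -> pd.DataFrame:
    """Per-frame dominant angle and deviation from vertical of an ROI.

    Returns a DataFrame with columns ``t_s`` (relative to
    ``align_event_s``, e.g. anaphase onset), ``alpha_deg`` and
    ``deviation_deg``; flat frames yield NaN, never zero.
    """
    rows = []
    for k in range(movie.n_frames):
        t = movie.times_s[k] - align_event_s
        hist = orientation_histogram(movie.frames[k], roi)
        if hist.empty:
            rows.append({"t_s": t, "alpha_deg": np.nan, "deviation_deg": np.nan})
            continue
        alpha = dominant_angle(hist)
        rows.append(
            {"t_s": t, "alpha_deg": alpha, "deviation_deg": deviation_from_vertical(alpha)}
        )
    return pd.DataFrame(rows)
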