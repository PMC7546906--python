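"""Derived cortical-flow statistics.

Turns PIV velocity series into the quantities used to characterise
cytokinetic flows: per-region velocity time courses, longitudinal
(anterior-posterior) velocity profiles, compression rates by flow
(the negated spatial derivative of the longitudinal profile, positive where
flow converges), cosine-similarity coherence as a function of vector
distance, and kymographs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imagestack import ImageSequence
from .piv import FlowSeries

__all__ = [
    "RegionSpec",
    "APProfile",
    "CompressionProfile",
    "CosineCurve",
    "Kymograph",
    "ANTERIOR_CORTEX",
    "POSTERIOR_CORTEX",
    "pixel_to_position",
    "region_velocity_series",
    "ap_profile",
    "compression_rate",
    "compression_profile",
    "cosine_similarity",
    "cosine_vs_distance",
    "build_kymograph",
]

#: Standard region-of-interest calibration: 192 px span 34.1 um.
ROI_PX = 192
ROI_UM = 34.1


def pixel_to_position(index_1based: int, roi_px: int = ROI_PX, roi_um: float = ROI_UM) -> float:
    """Map a 1-based A-P pixel index to its position in um (1 decimal).

    With the standard calibration, pixel 108 maps to 19.2 um, pixel 109 to
    19.4 um and pixel 192 to 34.1 um — the anterior/posterior sub-region
    bounds.
    """
    if not 1 <= index_1based <= roi_px:
        raise ValueError(f"pixel index {index_1based} outside 1..{roi_px}")
    return round(index_1based * roi_um / roi_px, 1)


@dataclass(frozen=True)
class RegionSpec:
    """A named A-P pixel span (1-based, inclusive) within the standard ROI."""

    name: str
    px_span: tuple[int, int]
    roi_px: int = ROI_PX
    roi_um: float = ROI_UM

    def __post_init__(self) -> None:
        lo, hi = self.px_span
        if not 1 <= lo <= hi <= self.roi_px:
            raise ValueError(f"span {self.px_span} outside 1..{self.roi_px}")

    @property
    def um_span(self) -> tuple[float, float]:
        lo, hi = self.px_span
        return (
            pixel_to_position(lo, self.roi_px, self.roi_um),
            pixel_to_position(hi, self.roi_px, self.roi_um),
        )

    def contains_um(self, x_um: np.ndarray) -> np.ndarray:
        lo, hi = self.px_span
        # half-open pixel bins so adjacent regions tile the ROI exactly
        return (x_um > (lo - 1) * self.roi_um / self.roi_px) & (
            x_um <= hi * self.roi_um / self.roi_px + 1e-9
        )


#: The two standard halves of the cortical ROI.
ANTERIOR_CORTEX = RegionSpec("anterior_cortex", (1, 108))
POSTERIOR_CORTEX = RegionSpec("posterior_cortex", (109, 192))


@dataclass
class APProfile:
    """Mean longitudinal velocity per A-P grid column, over a time window."""

    positions_um: np.ndarray
    mean_vx_um_min: np.ndarray
    sem_um_min: np.ndarray
    window_start_s: float
    window_len_s: float
    n_samples: np.ndarray | None = None


@dataclass
class CompressionProfile:
    """Compression rate by flow per position and time bin.

    ``rates_s`` has shape ``(n_bins, n_positions)`` in 1/s; positive values
    mark converging flow.  ``equatorial_mean_s`` is the per-bin mean over
    the equatorial band (15-25 um by default).
    """

    positions_um: np.ndarray
    bin_starts_s: np.ndarray
    rates_s: np.ndarray
    equatorial_mean_s: np.ndarray
    equator_band_um: tuple[float, float] = (15.0, 25.0)


@dataclass
class CosineCurve:
    """Mean pairwise cosine similarity binned by inter-vector distance."""

    distance_um: np.ndarray
    mean_cosine: np.ndarray
    n_pairs: np.ndarray
    n_zero_excluded: int = 0


@dataclass
class Kymograph:
    """Space-time image: strip position (rows) by frame (columns)."""

    data: np.ndarray
    strip: tuple[int, int, int, int]
    pixel_size_um: float
    frame_interval_s: float


# --------------------------------------------------------------------------
# region time series
# --------------------------------------------------------------------------

def _single_series_region_means(
    series: FlowSeries, regions: list[RegionSpec]
) -> pd.DataFrame:
    rows = []
    for t, fld in zip(series.timestamps_s, series.fields):
        x_um = fld.x_um
        for reg in regions:
            in_reg = reg.contains_um(x_um)
            sel = fld.valid & in_reg[None, :]
            rows.append(
                {
                    "t_s": t,
                    "region": reg.name,
                    "vx_um_min": fld.vx[sel].mean() if sel.any() else np.nan,
                    "vy_um_min": fld.vy[sel].mean() if sel.any() else np.nan,
                    "n_vectors": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)


def region_velocity_series(
    series: FlowSeries | list[FlowSeries],
    regions: list[RegionSpec] | None = None,
    align_event_s: float = 0.0,
) -> pd.DataFrame:
    """Mean Vx and Vy per region per time point, pooled across embryos.

    Within each embryo the mean is over all valid vectors whose anchor
    falls in the region; with several embryos, embryo means are averaged
    and the SEM is across embryos.  Time points with no vectors in a
    region yield NaN, never zero.  Timestamps are shifted so
    ``align_event_s`` (e.g. shallow deformation) becomes t = 0.
    """
    regions = regions or [ANTERIOR_CORTEX, POSTERIOR_CORTEX]
    many = series if isinstance(series, list) else [series]
    per_embryo = [
        _single_series_region_means(s.aligned(align_event_s), regions) for s in many
    ]
    for e, df in enumerate(per_embryo):
        df["embryo"] = e
    pooled = pd.concat(per_embryo, ignore_index=True)
    out = (
        pooled.groupby(["t_s", "region"])
        .agg(
            vx_um_min=("vx_um_min", "mean"),
            vy_um_min=("vy_um_min", "mean"),
            vx_sem=("vx_um_min", "sem"),
            vy_sem=("vy_um_min", "sem"),
            n_embryos=("embryo", "nunique"),
        )
        .reset_index()
    )
    return out


# --------------------------------------------------------------------------
# longitudinal profiles and compression
# --------------------------------------------------------------------------

def ap_profile(
    series: FlowSeries, window_start_s: float, window_len_s: float = 50.0
) -> APProfile:
    """Average Vx per A-P grid column over a time window.

    All vectors along the dorsal-ventral axis sharing an x-coordinate are
    pooled, together with all frames whose timestamp falls in
    ``[window_start_s, window_start_s + window_len_s)``; the standard
    window is the 50 s of persistent unidirectional flow starting at
    shallow deformation.
    """
    t = series.timestamps_s
    in_win = (t >= window_start_s) & (t < window_start_s + window_len_s)
    if not in_win.any():
        raise ValueError("time window contains no frame pairs")
    ref = series.fields[int(np.flatnonzero(in_win)[0])]
    nx = ref.vx.shape[1]
    sums = np.zeros(nx)
    sqs = np.zeros(nx)
    counts = np.zeros(nx, dtype=int)
    for k in np.flatnonzero(in_win):
        fld = series.fields[k]
        vx = np.where(fld.valid, fld.vx, np.nan)
        sums += np.nansum(vx, axis=0)
        sqs += np.nansum(vx**2, axis=0)
        counts += np.sum(fld.valid, axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(
            counts > 1, (sqs - counts * mean**2) / np.maximum(counts - 1, 1), np.nan
        )
        sem = np.sqrt(np.clip(var, 0, None) / np.maximum(counts, 1))
    return APProfile(
        positions_um=ref.x_um,
        mean_vx_um_min=mean,
        sem_um_min=sem,
        window_start_s=window_start_s,
        window_len_s=window_len_s,
        n_samples=counts,
    )


def compression_rate(positions_um: np.ndarray, vx_um_min: np.ndarray) -> np.ndarray:
    """Compression rate by flow: ``-dVx/dx`` in 1/s from a Vx profile.

    Velocities enter in um/min and are converted to um/s so the rate is in
    1/s.  Central differences are used at interior positions and one-sided
    differences at the ends; positive values mark converging flow.
    """
    x = np.asarray(positions_um, dtype=float)
    v = np.asarray(vx_um_min, dtype=float) / 60.0
    if x.size < 3:
        raise ValueError("at least 3 positions required for a spatial derivative")
    if np.any(np.diff(x) <= 0):
        raise ValueError("positions must be strictly increasing")
    return -np.gradient(v, x)


def compression_profile(
    series: FlowSeries,
    bin_starts_s: np.ndarray | None = None,
    bin_len_s: float = 10.0,
    equator_band_um: tuple[float, float] = (15.0, 25.0),
) -> CompressionProfile:
    """Compression rate per A-P position in consecutive time bins.

    Default binning follows the standard protocol: 10-s intervals from
    25 s to 95 s after anaphase onset (timestamps must already be relative
    to anaphase onset).  Also reports the per-bin mean over the equatorial
    band, where compression is expected to be uniform.
    """
    if bin_starts_s is None:
        bin_starts_s = np.arange(25.0, 95.0, bin_len_s)
    bin_starts_s = np.asarray(bin_starts_s, dtype=float)
    rates = []
    eq_means = []
    positions = None
    for t0 in bin_starts_s:
        prof = ap_profile(series, t0, bin_len_s)
        positions = prof.positions_um
        r = compression_rate(prof.positions_um, prof.mean_vx_um_min)
        rates.append(r)
        band = (positions >= equator_band_um[0]) & (positions <= equator_band_um[1])
        eq_means.append(np.nanmean(r[band]) if band.any() else np.nan)
    return CompressionProfile(
        positions_um=positions,
        bin_starts_s=bin_starts_s,
        rates_s=np.asarray(rates),
        equatorial_mean_s=np.asarray(eq_means),
        equator_band_um=equator_band_um,
    )


# --------------------------------------------------------------------------
# flow coherence
# --------------------------------------------------------------------------

def cosine_similarity(v: np.ndarray, w: np.ndarray) -> float:
    """Cosine similarity ``v.w / (|v||w|)``: 1 parallel, -1 antiparallel.

    Undefined for a zero vector, which raises ``ValueError`` (callers
    exclude such pairs and tally them).
    """
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0.0 or nw == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(v, w) / (nv * nw))


def cosine_vs_distance(
    series: FlowSeries,
    window: tuple[float, float] | None = None,
    bin_width_um: float | None = None,
) -> CosineCurve:
    """Mean pairwise cosine similarity versus inter-vector distance.

    For every frame in the window, all pairs of valid nonzero vectors are
    binned by the Euclidean distance between their anchors (default bin
    width: the post-refinement grid spacing) and the cosine similarity is
    averaged within each bin over pairs and frames.  The zero-distance
    self-pair bin is excluded; zero vectors are excluded and tallied.
    """
    t = series.timestamps_s
    if window is None:
        mask = np.ones(len(t), dtype=bool)
    else:
        mask = (t >= window[0]) & (t < window[1])
    if not mask.any():
        raise ValueError("time window contains no frame pairs")
    ref = series.fields[int(np.flatnonzero(mask)[0])]
    if bin_width_um is None:
        xs = ref.x_um
        bin_width_um = float(xs[1] - xs[0]) if len(xs) > 1 else 1.0

    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    n_zero = 0
    for k in np.flatnonzero(mask):
        fld = series.fields[k]
        xx, yy = np.meshgrid(fld.x_um, fld.y_um)
        sel = fld.valid.ravel()
        vx = fld.vx.ravel()[sel]
        vy = fld.vy.ravel()[sel]
        px = xx.ravel()[sel]
        py = yy.ravel()[sel]
        norms = np.hypot(vx, vy)
        nz = norms > 0
        n_zero += int((~nz).sum())
        vx, vy, px, py, norms = vx[nz], vy[nz], px[nz], py[nz], norms[nz]
        m = len(vx)
        if m < 2:
            continue
        ux, uy = vx / norms, vy / norms
        cosm = np.outer(ux, ux) + np.outer(uy, uy)
        dist = np.hypot(px[:, None] - px[None, :], py[:, None] - py[None, :])
        iu = np.triu_indices(m, k=1)
        bins = np.maximum(1, np.rint(dist[iu] / bin_width_um).astype(int))
        for b, c in zip(bins, np.clip(cosm[iu], -1.0, 1.0)):
            sums[b] = sums.get(b, 0.0) + c
            counts[b] = counts.get(b, 0) + 1
    ks = np.array(sorted(counts))
    return CosineCurve(
        distance_um=ks * bin_width_um,
        mean_cosine=np.array([sums[k] / counts[k] for k in ks]),
        n_pairs=np.array([counts[k] for k in ks]),
        n_zero_excluded=n_zero,
    )


# --------------------------------------------------------------------------
# kymograph
# --------------------------------------------------------------------------

def build_kymograph(
    movie: ImageSequence, strip: tuple[int, int, int, int] | None = None
) -> Kymograph:
    """Space-time montage of a strip, one column per frame.

    ``strip`` is ``(x0, y0, length, thickness)`` in px, the long axis along
    x (the A-P axis); by default a 150 x 5 px strip centered on the frame.
    Each frame's strip is averaged across its short axis to one column.
    """
    h, w = movie.shape
    if strip is None:
        length, thick = min(150, w), 5
        strip = ((w - length) // 2, (h - thick) // 2, length, thick)
    x0, y0, length, thick = strip
    if x0 < 0 or y0 < 0 or x0 + length > w or y0 + thick > h:
        raise ValueError(f"strip {strip} does not fit inside frame {(h, w)}")
    data = movie.frames[:, y0 : y0 + thick, x0 : x0 + length].mean(axis=1).T
    return Kymograph(
        data=data,
        strip=strip,
        pixel_size_um=movie.pixel_size_um,
        frame_interval_s=movie.frame_interval_s,
    )
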