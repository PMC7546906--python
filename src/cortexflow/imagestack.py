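"""Calibrated time-lapse image stacks.

The analysis pipeline operates on single-channel 2-D time-lapse movies with
known spatial calibration (micrometres per pixel) and temporal calibration
(seconds per frame).  Movies are carried in memory as an
:class:`ImageSequence` and on disk as a multi-page TIFF with a JSON sidecar
holding the calibration metadata.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageSequence"]


@dataclass
class ImageSequence:
    """A single-channel time-lapse movie with physical calibration.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, height, width)``; intensities must be
        non-negative (photon counts or camera units).
    pixel_size_um
        Lateral size of one pixel in micrometres.
    frame_interval_s
        Time between consecutive frames in seconds.
    channel
        Free-form channel label (e.g. ``"LifeAct::GFP"``).
    """

    frames: np.ndarray
    pixel_size_um: float
    frame_interval_s: float
    channel: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (n_frames, height, width); got shape {self.frames.shape}"
            )
        if self.pixel_size_um <= 0 or self.frame_interval_s <= 0:
            raise ValueError("pixel_size_um and frame_interval_s must be positive")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Frame shape as ``(height, width)``."""
        return self.frames.shape[1:]

    @property
    def times_s(self) -> np.ndarray:
        """Acquisition time of each frame, first frame at t = 0."""
        return np.arange(self.n_frames) * self.frame_interval_s

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i):
        return self.frames[i]

    # ------------------------------------------------------------------ I/O
    def save(self, path: str | Path) -> None:
        """Write frames as a multi-page TIFF plus a ``.json`` calibration sidecar."""
        path = Path(path)
        tifffile.imwrite(path, self.frames.astype(np.float32), photometric="minisblack")
        sidecar = {
            "pixel_size_um": self.pixel_size_um,
            "frame_interval_s": self.frame_interval_s,
            "channel": self.channel,
            "n_frames": self.n_frames,
            "height_px": self.shape[0],
            "width_px": self.shape[1],
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ImageSequence":
        """Read a TIFF written by :meth:`save` (sidecar JSON required)."""
        path = Path(path)
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        sidecar_path = path.with_suffix(path.suffix + ".json")
        if not sidecar_path.exists():
            raise FileNotFoundError(
                f"calibration sidecar {sidecar_path} not found; "
                "pixel size and frame interval are required"
            )
        meta = json.loads(sidecar_path.read_text())
        return cls(
            frames=np.asarray(frames, dtype=float),
            pixel_size_um=float(meta["pixel_size_um"]),
            frame_interval_s=float(meta["frame_interval_s"]),
            channel=meta.get("channel", ""),
        )

    def max_project(self) -> "ImageSequence":
        """Identity pass-through for single-plane movies.

        Real acquisitions are maximum-intensity projections of cortical
        z-stacks; simulated movies are generated in-plane, so projection
        reduces to a no-op kept for pipeline symmetry.
        """
        return self
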