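"""Shared containers for calibrated image sequences.

Coordinate convention used throughout the package: 0-based pixel indices,
origin at the center of pixel (0, 0), ``x`` is the column index and ``y``
the row index. Positions are in pixels unless a function documents μm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageStack:
    """Timed, calibrated single-channel frame sequence.

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
        Frame sequence, one 2-D intensity array per time point.
    pixel_size : float
        Lateral calibration in μm/pixel.
    frame_interval : float
        Frame-to-frame time interval in seconds.
    channel_label : str
        Free-text channel name (e.g. ``"paxillin"``, ``"GFP"``).
    """

    frames: np.ndarray
    pixel_size: float
    frame_interval: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim == 2:
            self.frames = self.frames[None]
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) array")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, i: int) -> np.ndarray:
        return self.frames[i]

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) of a single frame."""
        return self.frames.shape[1:]

    def times(self) -> np.ndarray:
        """Frame acquisition times in seconds, starting at 0."""
        return np.arange(len(self)) * self.frame_interval

    def to_tiff(self, path) -> None:
        """Write as a multi-page 16-bit unsigned TIFF (values clipped)."""
        data = np.clip(np.round(self.frames), 0, 65535).astype(np.uint16)
        tifffile.imwrite(path, data, metadata={
            "pixel_size_um": self.pixel_size,
            "frame_interval_s": self.frame_interval,
            "channel": self.channel_label,
        })

    @classmethod
    def from_tiff(cls, path, pixel_size: float, frame_interval: float,
                  channel_label: str = "") -> "ImageStack":
        try:
            frames = tifffile.imread(path)
        except Exception as exc:  # corrupt or non-TIFF input
            raise IOError(f"cannot read TIFF file {path!r}: {exc}") from exc
        return cls(np.asarray(frames, dtype=float), pixel_size,
                   frame_interval, channel_label)
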