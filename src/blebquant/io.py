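"""Movie container and TIFF/JSON input-output.

Movies are stacks of single-channel frames — either integer *label* frames
(background 0, one positive integer id per cell) or real-valued *intensity*
frames — together with the physical pixel spacing (µm/px) and the frame
interval (s).  On disk a movie is a multi-page 16-bit TIFF next to a JSON
sidecar (``<name>.tif.json``) holding the spacing, interval and timestamps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["MovieStack", "write_movie", "read_movie"]


@dataclass
class MovieStack:
    """An ordered stack of 2-D frames with physical calibration.

    Parameters
    ----------
    frames
        Array of shape ``(T, H, W)``.  Integer dtype marks a label movie,
        floating dtype an intensity movie.
    pixel_spacing_um
        Physical size of one pixel, in µm.
    frame_interval_s
        Nominal time between frames, in s.
    timestamps_s
        Per-frame acquisition times.  Defaults to ``k * frame_interval_s``.
        Must be strictly increasing.
    """

    frames: np.ndarray
    pixel_spacing_um: float
    frame_interval_s: float
    timestamps_s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (T, H, W)")
        if self.pixel_spacing_um <= 0:
            raise ValueError("pixel_spacing_um must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")
        if self.timestamps_s is None:
            self.timestamps_s = np.arange(self.n_frames) * float(self.frame_interval_s)
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        if self.timestamps_s.shape != (self.n_frames,):
            raise ValueError("timestamps_s must have one entry per frame")
        if self.n_frames > 1 and not np.all(np.diff(self.timestamps_s) > 0):
            raise ValueError("timestamps_s must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]  # type: ignore[return-value]

    @property
    def is_label(self) -> bool:
        return np.issubdtype(self.frames.dtype, np.integer)

    def duration_s(self) -> float:
        return float(self.timestamps_s[-1] - self.timestamps_s[0])


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def write_movie(movie: MovieStack, path: str | Path) -> Path:
    """Write a movie as multi-page 16-bit TIFF plus a JSON metadata sidecar.

    Intensity frames are rounded and clipped to the uint16 range; label
    frames must already fit in uint16.
    """
    path = Path(path)
    frames = movie.frames
    if movie.is_label:
        if frames.min() < 0 or frames.max() > np.iinfo(np.uint16).max:
            raise ValueError("label ids must fit in uint16")
        data = frames.astype(np.uint16)
    else:
        data = np.clip(np.round(frames), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(path, data)
    meta = {
        "pixel_spacing_um": float(movie.pixel_spacing_um),
        "frame_interval_s": float(movie.frame_interval_s),
        "timestamps_s": [float(t) for t in movie.timestamps_s],
        "kind": "label" if movie.is_label else "intensity",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_movie(path: str | Path) -> MovieStack:
    """Read a movie written by :func:`write_movie` (TIFF + JSON sidecar)."""
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(_sidecar_path(path).read_text())
    if meta.get("kind") == "intensity":
        frames = frames.astype(np.float32)
    else:
        frames = frames.astype(np.int32)
    return MovieStack(
        frames=frames,
        pixel_spacing_um=meta["pixel_spacing_um"],
        frame_interval_s=meta["frame_interval_s"],
        timestamps_s=np.asarray(meta["timestamps_s"], dtype=float),
    )
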