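"""Classical intensity-based segmentation, registration and resampling.

The segmenter replaces a learned model with a standard recipe: Gaussian
smoothing, optional large-kernel background subtraction, automatic global
(Otsu) threshold, distance-transform maxima as seeds, and seeded watershed.
Registration is translation-only against the first frame via phase
cross-correlation; resampling picks the frame nearest each target timestamp
(masks are not interpolable without a shape model).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage import measure
from skimage.feature import peak_local_max
from skimage.filters import gaussian, threshold_otsu
from skimage.registration import phase_cross_correlation
from skimage.segmentation import relabel_sequential, watershed

from .io import MovieStack

__all__ = ["segment_frame", "segment_movie", "register_movie", "resample_movie"]

log = logging.getLogger(__name__)


def segment_frame(
    image: np.ndarray,
    *,
    pixel_spacing_um: float,
    min_object_px: int = 100,
    smoothing_um: float = 0.1,
    background_sigma_um: float | None = None,
    seed_min_distance_px: int = 10,
) -> np.ndarray:
    """Segment one intensity frame into labelled cells.

    Pipeline: Gaussian smoothing (``smoothing_um``) → optional background
    subtraction (Gaussian estimate with ``background_sigma_um``) → Otsu
    threshold → Euclidean distance transform → local maxima (separated by at
    least ``seed_min_distance_px``) as watershed seeds → seeded watershed on
    the inverted distance map → objects smaller than ``min_object_px``
    discarded.  Objects are 8-connected.

    An empty or constant image yields an all-zero label frame (not an error).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("segment_frame expects a single-channel 2-D frame")
    if smoothing_um > 0:
        img = gaussian(img, sigma=smoothing_um / pixel_spacing_um, preserve_range=True)
    if background_sigma_um:
        img = img - gaussian(
            img, sigma=background_sigma_um / pixel_spacing_um, preserve_range=True
        )
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32)

    binary = img > threshold_otsu(img)
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)

    components = measure.label(binary, connectivity=2)
    dist = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(
        dist,
        min_distance=seed_min_distance_px,
        labels=components,
        exclude_border=False,
    )
    markers = np.zeros(img.shape, dtype=np.int32)
    if peaks.size:
        markers[tuple(peaks.T)] = np.arange(1, peaks.shape[0] + 1)
    else:  # tiny objects without clear distance maxima: one seed per component
        markers = components
    labels = watershed(-dist, markers=markers, mask=binary, connectivity=2)

    if min_object_px > 0:
        counts = np.bincount(labels.ravel())
        small = np.flatnonzero(counts < min_object_px)
        labels[np.isin(labels, small)] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def segment_movie(movie: MovieStack, **kwargs) -> MovieStack:
    """Apply :func:`segment_frame` to every frame of an intensity movie."""
    frames = np.stack(
        [
            segment_frame(f, pixel_spacing_um=movie.pixel_spacing_um, **kwargs)
            for f in movie.frames
        ]
    )
    return MovieStack(
        frames=frames,
        pixel_spacing_um=movie.pixel_spacing_um,
        frame_interval_s=movie.frame_interval_s,
        timestamps_s=movie.timestamps_s.copy(),
    )


def register_movie(movie: MovieStack) -> tuple[MovieStack, np.ndarray]:
    """Register all frames to the first frame (translation only).

    Integer-pixel shifts are estimated by phase cross-correlation and applied
    with constant (zero) padding at the edges.  Degenerate frames (no
    correlation signal, e.g. constant images) get a zero shift and a log
    message.  Returns the registered movie and the per-frame ``(row, col)``
    shifts that were applied.
    """
    ref = np.asarray(movie.frames[0], dtype=float)
    shifts = np.zeros((movie.n_frames, 2), dtype=int)
    out = movie.frames.copy()
    for k in range(1, movie.n_frames):
        frame = np.asarray(movie.frames[k], dtype=float)
        if np.ptp(frame) == 0 or np.ptp(ref) == 0:
            log.warning("frame %d: degenerate correlation, using zero shift", k)
            continue
        shift, _, _ = phase_cross_correlation(ref, frame, upsample_factor=1)
        shift = np.round(shift).astype(int)
        shifts[k] = shift
        if np.any(shift):
            out[k] = ndi.shift(movie.frames[k], shift, order=0, mode="constant", cval=0)
    registered = MovieStack(
        frames=out,
        pixel_spacing_um=movie.pixel_spacing_um,
        frame_interval_s=movie.frame_interval_s,
        timestamps_s=movie.timestamps_s.copy(),
    )
    return registered, shifts


def resample_movie(movie: MovieStack, target_interval_s: float = 20.0) -> MovieStack:
    """Resample to a fixed cadence by keeping the frame nearest each target time.

    Target timestamps start at t = 0 and step by ``target_interval_s`` up to
    the last acquired timestamp.  The native interval must not exceed the
    target (no interpolation is attempted); ties pick the earlier frame.
    """
    ts = movie.timestamps_s
    native = np.median(np.diff(ts)) if movie.n_frames > 1 else movie.frame_interval_s
    if native > target_interval_s + 1e-9:
        raise ValueError(
            f"native interval {native:g}s exceeds target {target_interval_s:g}s; "
            "cannot resample without interpolation"
        )
    targets = np.arange(0.0, ts[-1] + 1e-9, target_interval_s)
    idx = np.abs(ts[None, :] - targets[:, None]).argmin(axis=1)
    return MovieStack(
        frames=movie.frames[idx],
        pixel_spacing_um=movie.pixel_spacing_um,
        frame_interval_s=target_interval_s,
        timestamps_s=targets,
    )
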