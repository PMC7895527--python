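"""End-to-end conveniences tying the stages together.

These helpers run the canonical orderings used throughout: register →
resample to the 20-s analysis cadence → track → truncate to the analysis
window → QC filter → per-cell blebbing activity.  They are thin compositions
of the public stage functions and exist so the CLI, the acceptance script
and user notebooks share one code path.
"""

from __future__ import annotations

import numpy as np

from .blebbing import BlebbingResult, blebbing_activity
from .io import MovieStack
from .segmentation import register_movie, resample_movie, segment_movie
from .tracking import (
    CellTrack,
    QCParams,
    QCReport,
    filter_tracks,
    link_tracks,
    tracks_from_labels,
    truncate_track,
)

__all__ = ["prepare_tracks", "activity_pipeline", "segment_and_track"]


def prepare_tracks(
    labels: MovieStack,
    qc: QCParams = QCParams(),
    *,
    linker: str = "labels",
    max_link_dist_px: float = 10.0,
    truncate: bool = True,
    register: bool = False,
) -> list[CellTrack]:
    """Resample a label movie to the QC cadence and build truncated tracks.

    ``linker='labels'`` trusts frame-consistent ids (simulator movies);
    ``linker='greedy'`` runs nearest-centroid linking (segmented movies).
    """
    if register:
        labels, _ = register_movie(labels)
    resampled = resample_movie(labels, qc.resample_interval_s)
    if linker == "labels":
        tracks = tracks_from_labels(resampled)
    elif linker == "greedy":
        tracks = link_tracks(resampled, max_link_dist_px=max_link_dist_px)
    else:
        raise ValueError("linker must be 'labels' or 'greedy'")
    if truncate:
        tracks = [truncate_track(t, qc.analysis_window_s) for t in tracks]
    return tracks


def activity_pipeline(
    labels: MovieStack,
    qc: QCParams = QCParams(),
    *,
    linker: str = "labels",
    apply_qc: bool = True,
    register: bool = False,
) -> tuple[dict[int, BlebbingResult], list[CellTrack], QCReport | None]:
    """Per-cell blebbing activity from a label movie.

    Returns ``(results by cell id, analysed tracks, QC report)``; the report
    is ``None`` when ``apply_qc`` is off (e.g. on noise-free simulator masks
    where the exclusion filters are not needed).
    """
    tracks = prepare_tracks(labels, qc, linker=linker, register=register)
    report: QCReport | None = None
    if apply_qc:
        tracks, report = filter_tracks(tracks, qc)
    tracks = [t for t in tracks if len(t) >= 2]
    results = {t.cell_id: blebbing_activity(t, qc) for t in tracks}
    return results, tracks, report


def segment_and_track(
    intensity: MovieStack,
    qc: QCParams = QCParams(),
    *,
    max_link_dist_px: float = 10.0,
    register: bool = True,
    **segment_kwargs,
) -> list[CellTrack]:
    """Segment an intensity movie and return QC-ready (unfiltered) tracks."""
    if register:
        intensity, _ = register_movie(intensity)
    resampled = resample_movie(intensity, qc.resample_interval_s)
    labels = segment_movie(resampled, **segment_kwargs)
    tracks = link_tracks(labels, max_link_dist_px=max_link_dist_px)
    return [truncate_track(t, qc.analysis_window_s) for t in tracks]


def activities_array(results: dict[int, BlebbingResult]) -> np.ndarray:
    """Activity values of a result mapping, ordered by cell id."""
    return np.array([results[k].activity for k in sorted(results)])
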