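"""Cell tracks, greedy frame-to-frame linking, and QC exclusion filters.

A :class:`CellTrack` holds one cell's time-ordered masks and shape
descriptors.  Linking is greedy nearest-centroid bipartite matching between
consecutive frames.  The QC filter removes tracks that are too short or that
at any analysed time point have a small area, a large step displacement, a
large area change, or a low circularity; tracks are expected to be resampled
to the analysis cadence (20 s) and truncated to the analysis window (240 s)
before filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage import measure

from .io import MovieStack
from .morphometrics import ShapeDescriptor, shape_descriptors

__all__ = [
    "QCParams",
    "CellTrack",
    "QCReport",
    "link_tracks",
    "tracks_from_labels",
    "truncate_track",
    "filter_tracks",
]

log = logging.getLogger(__name__)

#: QC exclusion reasons, in reporting order
QC_REASONS = ("duration", "area", "displacement", "area_change", "circularity")


@dataclass(frozen=True)
class QCParams:
    """Track-level quality-control thresholds.

    Defaults reproduce the published exclusion rules at 0.1625 µm/px: area
    < 500 px, step displacement > 5 px, step area change > 10 %, circularity
    < 0.7, tracks shorter than 200 s; only the first 240 s are analysed at
    one frame per 20 s.
    """

    min_area_px: int = 500
    max_step_disp_px: float = 5.0
    max_area_change_frac: float = 0.10
    min_circularity: float = 0.7
    min_track_duration_s: float = 200.0
    analysis_window_s: float = 240.0
    resample_interval_s: float = 20.0

    def __post_init__(self) -> None:
        for name in (
            "min_area_px",
            "max_step_disp_px",
            "max_area_change_frac",
            "min_circularity",
            "min_track_duration_s",
            "analysis_window_s",
            "resample_interval_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.analysis_window_s < self.min_track_duration_s:
            raise ValueError("analysis window must cover the minimum track duration")


@dataclass
class CellTrack:
    """One cell's time-ordered masks and descriptors."""

    cell_id: int
    times_s: np.ndarray
    masks: list[np.ndarray]
    descriptors: list[ShapeDescriptor]
    pixel_spacing_um: float
    condition: str | None = None
    replicate: str | None = None

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        if not (len(self.masks) == len(self.descriptors) == self.times_s.size):
            raise ValueError("times, masks and descriptors must have equal length")
        if self.times_s.size == 0:
            raise ValueError("track is empty")
        if self.times_s.size > 1 and not np.all(np.diff(self.times_s) > 0):
            raise ValueError("track times must be strictly increasing")
        for m in self.masks:
            if not m.any():
                raise ValueError("track contains an empty mask")

    def __len__(self) -> int:
        return self.times_s.size

    @property
    def samples(self) -> list[tuple[float, np.ndarray, ShapeDescriptor]]:
        return list(zip(self.times_s.tolist(), self.masks, self.descriptors))

    @property
    def duration_s(self) -> float:
        return float(self.times_s[-1] - self.times_s[0])

    @property
    def areas_px(self) -> np.ndarray:
        return np.array([d.projected_area_px for d in self.descriptors], dtype=float)

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([d.area_um2 for d in self.descriptors])

    @property
    def centroids_um(self) -> np.ndarray:
        return np.array([d.centroid_um for d in self.descriptors])

    @property
    def centroids_px(self) -> np.ndarray:
        return self.centroids_um / self.pixel_spacing_um

    @property
    def aspect_ratios(self) -> np.ndarray:
        return np.array([d.aspect_ratio for d in self.descriptors])

    @property
    def circularities(self) -> np.ndarray:
        return np.array([d.circularity for d in self.descriptors])


def _largest_component(mask: np.ndarray, context: str) -> np.ndarray:
    labeled, n = measure.label(mask, connectivity=2, return_num=True)
    if n <= 1:
        return mask
    log.warning("%s: multi-component region, keeping largest component", context)
    counts = np.bincount(labeled.ravel())
    counts[0] = 0
    return labeled == counts.argmax()


def _track_from_entries(
    movie: MovieStack,
    cell_id: int,
    entries: list[tuple[int, int]],
) -> CellTrack:
    times, masks, descs = [], [], []
    for frame_idx, label in entries:
        mask = np.asarray(movie.frames[frame_idx] == label)
        mask = _largest_component(mask, f"frame {frame_idx} label {label}")
        times.append(float(movie.timestamps_s[frame_idx]))
        masks.append(mask)
        descs.append(shape_descriptors(mask, movie.pixel_spacing_um))
    return CellTrack(
        cell_id=cell_id,
        times_s=np.asarray(times),
        masks=masks,
        descriptors=descs,
        pixel_spacing_um=movie.pixel_spacing_um,
    )


def link_tracks(labels: MovieStack, max_link_dist_px: float = 10.0) -> list[CellTrack]:
    """Greedy nearest-centroid linking of labelled regions across frames.

    Each region links to at most one track; a link requires centroid distance
    ≤ ``max_link_dist_px``, candidate pairs are taken in order of increasing
    distance (ties broken by smaller region label), and unmatched regions
    start new tracks.  Tracks end when a cell goes unmatched for one frame.
    """
    if not labels.is_label:
        raise ValueError("link_tracks expects a label movie")
    per_frame: list[list[tuple[int, np.ndarray]]] = []
    for frame in labels.frames:
        regions = [
            (int(p.label), np.asarray(p.centroid)) for p in measure.regionprops(frame)
        ]
        per_frame.append(regions)

    next_track_id = 1
    finished: list[tuple[int, list[tuple[int, int]]]] = []
    # active: track_id -> (last centroid, entries)
    active: dict[int, tuple[np.ndarray, list[tuple[int, int]]]] = {}
    for frame_idx, regions in enumerate(per_frame):
        candidates = []
        for track_id, (centroid, _) in active.items():
            for label, rc in regions:
                d = float(np.hypot(*(rc - centroid)))
                if d <= max_link_dist_px:
                    candidates.append((d, label, track_id))
        candidates.sort()
        used_labels: set[int] = set()
        matched: dict[int, tuple[int, np.ndarray]] = {}
        for d, label, track_id in candidates:
            if track_id in matched or label in used_labels:
                continue
            rc = next(c for lab, c in regions if lab == label)
            matched[track_id] = (label, rc)
            used_labels.add(label)
        new_active: dict[int, tuple[np.ndarray, list[tuple[int, int]]]] = {}
        for track_id, (centroid, entries) in active.items():
            if track_id in matched:
                label, rc = matched[track_id]
                entries.append((frame_idx, label))
                new_active[track_id] = (rc, entries)
            else:
                finished.append((track_id, entries))
        for label, rc in regions:
            if label not in used_labels:
                new_active[next_track_id] = (rc, [(frame_idx, label)])
                next_track_id += 1
        active = new_active
    finished.extend((tid, entries) for tid, (_, entries) in active.items())
    finished.sort()
    return [_track_from_entries(labels, tid, entries) for tid, entries in finished]


def tracks_from_labels(movie: MovieStack) -> list[CellTrack]:
    """Extract tracks assuming label ids are already consistent across frames.

    This is the ground-truth route for simulator movies, where cell ``i``
    carries label ``i`` in every frame it appears in.
    """
    if not movie.is_label:
        raise ValueError("tracks_from_labels expects a label movie")
    ids = np.unique(movie.frames)
    tracks = []
    for cell_id in ids[ids > 0]:
        entries = [
            (k, int(cell_id))
            for k in range(movie.n_frames)
            if (movie.frames[k] == cell_id).any()
        ]
        if entries:
            tracks.append(_track_from_entries(movie, int(cell_id), entries))
    return tracks


def truncate_track(track: CellTrack, window_s: float) -> CellTrack:
    """Keep only samples with timestamps within the first ``window_s`` seconds."""
    keep = track.times_s <= window_s + 1e-9
    if not keep.any():
        raise ValueError("truncation window removes every sample")
    return CellTrack(
        cell_id=track.cell_id,
        times_s=track.times_s[keep],
        masks=[m for m, k in zip(track.masks, keep) if k],
        descriptors=[d for d, k in zip(track.descriptors, keep) if k],
        pixel_spacing_um=track.pixel_spacing_um,
        condition=track.condition,
        replicate=track.replicate,
    )


@dataclass
class QCReport:
    """Per-reason exclusion bookkeeping from :func:`filter_tracks`."""

    n_input: int
    n_kept: int
    excluded_counts: dict[str, int] = field(default_factory=dict)
    reasons_by_track: dict[int, list[str]] = field(default_factory=dict)


def _check_resampled(track: CellTrack, qc: QCParams) -> None:
    if len(track) > 1:
        diffs = np.diff(track.times_s)
        if not np.allclose(diffs, qc.resample_interval_s, atol=1e-6):
            raise ValueError(
                f"track {track.cell_id} is not resampled to "
                f"{qc.resample_interval_s:g}s cadence"
            )


def track_qc_reasons(track: CellTrack, qc: QCParams) -> list[str]:
    """List of exclusion reasons a track violates (empty = compliant)."""
    _check_resampled(track, qc)
    reasons = []
    if track.duration_s < qc.min_track_duration_s:
        reasons.append("duration")
    if np.any(track.areas_px < qc.min_area_px):
        reasons.append("area")
    if len(track) > 1:
        steps = np.linalg.norm(np.diff(track.centroids_px, axis=0), axis=1)
        if np.any(steps > qc.max_step_disp_px):
            reasons.append("displacement")
        areas = track.areas_px
        rel_change = np.abs(np.diff(areas)) / areas[:-1]
        if np.any(rel_change > qc.max_area_change_frac):
            reasons.append("area_change")
    if np.any(track.circularities < qc.min_circularity):
        reasons.append("circularity")
    return reasons


def filter_tracks(
    tracks: list[CellTrack], qc: QCParams = QCParams()
) -> tuple[list[CellTrack], QCReport]:
    """Apply the QC exclusion rules; returns kept tracks and a report.

    A track is removed iff its duration is below ``min_track_duration_s`` OR
    any analysed time point violates the area / displacement / area-change /
    circularity thresholds.  Tracks must already be resampled to
    ``resample_interval_s`` (and truncated to the analysis window by the
    caller); an unresampled track raises.
    """
    kept: list[CellTrack] = []
    report = QCReport(
        n_input=len(tracks), n_kept=0, excluded_counts={r: 0 for r in QC_REASONS}
    )
    for track in tracks:
        reasons = track_qc_reasons(track, qc)
        if reasons:
            report.reasons_by_track[track.cell_id] = reasons
            for r in reasons:
                report.excluded_counts[r] += 1
        else:
            kept.append(track)
    report.n_kept = len(kept)
    return kept, report
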