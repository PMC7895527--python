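"""Escape-assay geometry and morphodynamics.

Quantifies escape from a circular confinement zone: unsigned distances from
the cell front / centroid / rear to the boundary circle, front- and
whole-cell crossing times, the angle between crawling steps and the shortest
escape path, windowed speed and directional persistence, and event-aligned
aggregation of aspect ratio and projected area across escaping cells.

Distance conventions: the front (rear) distance is the minimal (maximal)
unsigned distance ``| ||p − c|| − R |`` over all cell pixel centres; escape
state uses the signed side (``||p − c|| > R`` = outside, unconfined).  The
front crossing time is the first frame with any pixel outside; completion is
the first frame with every pixel outside (whole-cell crossing) — both are
reported because published escape counts do not state which criterion was
used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tracking import CellTrack

__all__ = [
    "ConfinementBoundary",
    "EscapeRecord",
    "MotilityRecord",
    "boundary_distances",
    "detect_escape",
    "escape_angle_series",
    "speed_and_persistence",
    "align_to_event",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfinementBoundary:
    """Circular confinement border; the confined side is the interior."""

    center_um: tuple[float, float]  # (row, col) µm
    radius_um: float

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("boundary radius must be positive")


def _pixel_coords_um(mask: np.ndarray, spacing_um: float) -> np.ndarray:
    rows, cols = np.nonzero(mask)
    return np.column_stack([rows, cols]).astype(float) * spacing_um


def boundary_distances(
    mask: np.ndarray, boundary: ConfinementBoundary, spacing_um: float
) -> tuple[float, float, float]:
    """Front, centroid and rear unsigned distances to the boundary circle.

    For each cell pixel centre ``p``: ``d(p) = | ||p − c|| − R |``.  Front is
    the minimum over pixels, rear the maximum, and the centroid distance is
    the same quantity evaluated at the pixel-centre mean.
    """
    pts = _pixel_coords_um(np.asarray(mask, bool), spacing_um)
    if pts.shape[0] == 0:
        raise ValueError("mask is empty")
    c = np.asarray(boundary.center_um)
    radial = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
    d = np.abs(radial - boundary.radius_um)
    centroid = pts.mean(axis=0)
    centroid_d = abs(float(np.hypot(*(centroid - c))) - boundary.radius_um)
    return float(d.min()), centroid_d, float(d.max())


@dataclass
class EscapeRecord:
    """Per-frame escape geometry and the detected crossing times of one cell."""

    times_s: np.ndarray
    front_dist_um: np.ndarray
    centroid_dist_um: np.ndarray
    rear_dist_um: np.ndarray
    aspect_ratio: np.ndarray
    projected_area_um2: np.ndarray
    escaped: bool
    t_front_s: float | None
    t_complete_s: float | None
    initial_front_dist_um: float
    angles_deg: np.ndarray  # per step; NaN where skipped

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "front_dist_um": self.front_dist_um,
                "centroid_dist_um": self.centroid_dist_um,
                "rear_dist_um": self.rear_dist_um,
                "aspect_ratio": self.aspect_ratio,
                "projected_area_um2": self.projected_area_um2,
            }
        )


def detect_escape(track: CellTrack, boundary: ConfinementBoundary) -> EscapeRecord:
    """Escape detection and boundary-distance series for one track.

    ``t_front`` is the first time any cell pixel centre lies outside the
    circle, ``t_complete`` the first time all pixels do; ``escaped`` means
    completion happened within the movie.  The initial centroid must lie
    inside the boundary (otherwise the cell is not confined and a
    ``ValueError`` is raised).
    """
    spacing = track.pixel_spacing_um
    c = np.asarray(boundary.center_um)
    first_centroid = track.centroids_um[0]
    if np.hypot(*(first_centroid - c)) > boundary.radius_um:
        raise ValueError("initial centroid lies outside the boundary (not confined)")

    n = len(track)
    front = np.empty(n)
    cent = np.empty(n)
    rear = np.empty(n)
    t_front = t_complete = None
    for i, mask in enumerate(track.masks):
        front[i], cent[i], rear[i] = boundary_distances(mask, boundary, spacing)
        pts = _pixel_coords_um(mask, spacing)
        radial = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
        outside = radial > boundary.radius_um
        if t_front is None and outside.any():
            t_front = float(track.times_s[i])
        if t_complete is None and outside.all():
            t_complete = float(track.times_s[i])
    return EscapeRecord(
        times_s=track.times_s.copy(),
        front_dist_um=front,
        centroid_dist_um=cent,
        rear_dist_um=rear,
        aspect_ratio=track.aspect_ratios,
        projected_area_um2=track.areas_um2,
        escaped=t_complete is not None,
        t_front_s=t_front,
        t_complete_s=t_complete,
        initial_front_dist_um=float(front[0]),
        angles_deg=escape_angle_series(track, boundary),
    )


def escape_angle_series(
    track: CellTrack,
    boundary: ConfinementBoundary,
    min_step_px: float = 0.5,
) -> np.ndarray:
    """Angle between each crawling step and the shortest escape path, degrees.

    Per consecutive-sample step the angle in [0°, 180°] between the centroid
    displacement and the outward radial direction at the step start (centroid
    → nearest boundary point).  Steps are skipped (NaN) when the displacement
    is below ``min_step_px`` pixels, when the starting centroid sits exactly
    at the circle centre (radial direction undefined, logged), or when the
    centroid has already left the confinement zone (the shortest escape path
    is only defined inside).
    """
    if len(track) < 2:
        raise ValueError("need at least two samples for an angle series")
    c = np.asarray(boundary.center_um)
    centroids = track.centroids_um
    angles = np.full(len(track) - 1, np.nan)
    min_step_um = min_step_px * track.pixel_spacing_um
    for i in range(len(track) - 1):
        p = centroids[i]
        disp = centroids[i + 1] - p
        if np.hypot(*disp) < min_step_um:
            continue
        radial = p - c
        r = float(np.hypot(*radial))
        if r < 1e-9:
            log.warning("step %d: centroid at circle centre; skipping angle", i)
            continue
        if r > boundary.radius_um:
            continue  # already outside: no confined escape path
        cosang = float(np.dot(disp, radial) / (np.hypot(*disp) * r))
        angles[i] = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return angles


@dataclass
class MotilityRecord:
    """Sliding-window speed and directional persistence of one track."""

    times_s: np.ndarray  # window start times
    speed_um_min: np.ndarray
    persistence: np.ndarray  # NaN where displacement is zero
    definition: str  # 'paper_literal' (total/Euclidean, ≥1) or 'conventional'

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times_s,
                "speed_um_min": self.speed_um_min,
                "persistence": self.persistence,
            }
        )


def speed_and_persistence(
    track: CellTrack,
    window_s: float = 120.0,
    definition: str = "paper_literal",
) -> MotilityRecord:
    """Windowed speed (µm/min) and directional persistence.

    Windows of ``window_s`` slide by one resampled frame.  Speed is the total
    path length in the window divided by the window duration.  Persistence is
    the ratio of total path to Euclidean (net) displacement under the
    ``paper_literal`` definition (≥ 1 for any non-straight path), or its
    reciprocal (∈ [0, 1]) under ``conventional``.  Windows with zero net
    displacement have undefined persistence and are reported as NaN.
    """
    if definition not in ("paper_literal", "conventional"):
        raise ValueError("definition must be 'paper_literal' or 'conventional'")
    if len(track) < 2:
        raise ValueError("track too short")
    dts = np.diff(track.times_s)
    if not np.allclose(dts, dts[0], atol=1e-6):
        raise ValueError("track must be uniformly sampled")
    dt = float(dts[0])
    n_per = int(round(window_s / dt))
    if n_per < 1 or len(track) < n_per + 1:
        raise ValueError("track shorter than the analysis window")
    pts = track.centroids_um
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    n_windows = len(track) - n_per
    speed = np.empty(n_windows)
    pers = np.full(n_windows, np.nan)
    for i in range(n_windows):
        path = float(steps[i : i + n_per].sum())
        net = float(np.hypot(*(pts[i + n_per] - pts[i])))
        speed[i] = path / (n_per * dt / 60.0)
        if net > 0:
            ratio = path / net
            pers[i] = ratio if definition == "paper_literal" else 1.0 / ratio
        else:
            log.debug("window %d: zero net displacement, persistence undefined", i)
    return MotilityRecord(
        times_s=track.times_s[:n_windows].copy(),
        speed_um_min=speed,
        persistence=pers,
        definition=definition,
    )


def align_to_event(
    tracks: list[CellTrack],
    event_times_s: list[float],
    bin_s: float | None = None,
) -> pd.DataFrame:
    """Event-aligned mean ± SD of aspect ratio and projected area.

    Each track's timestamps are re-zeroed at its event time (e.g. escape
    completion), snapped to bins of width ``bin_s`` (default: the sampling
    interval of the first track), and aggregated across cells per bin.
    Returns a DataFrame with columns ``time_s``, ``aspect_ratio_mean/sd``,
    ``area_um2_mean/sd`` and ``n_cells``; empty input yields an empty frame.
    SD is the population standard deviation (0 for a single track).
    """
    if len(tracks) != len(event_times_s):
        raise ValueError("one event time per track required")
    if not tracks:
        return pd.DataFrame(
            columns=[
                "time_s",
                "aspect_ratio_mean",
                "aspect_ratio_sd",
                "area_um2_mean",
                "area_um2_sd",
                "n_cells",
            ]
        )
    if bin_s is None:
        bin_s = float(np.median(np.diff(tracks[0].times_s)))
    rows = []
    for track, t0 in zip(tracks, event_times_s):
        rel = track.times_s - t0
        bins = np.round(rel / bin_s) * bin_s
        for b, ar, area in zip(bins, track.aspect_ratios, track.areas_um2):
            rows.append((float(b), float(ar), float(area)))
    df = pd.DataFrame(rows, columns=["time_s", "aspect_ratio", "area_um2"])
    grouped = df.groupby("time_s")
    out = pd.DataFrame(
        {
            "aspect_ratio_mean": grouped["aspect_ratio"].mean(),
            "aspect_ratio_sd": grouped["aspect_ratio"].std(ddof=0),
            "area_um2_mean": grouped["area_um2"].mean(),
            "area_um2_sd": grouped["area_um2"].std(ddof=0),
            "n_cells": grouped["aspect_ratio"].size(),
        }
    ).reset_index()
    return out
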