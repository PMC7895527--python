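"""Simulated study cohorts with fixed conditions.

These functions pin the simulated experimental designs used to validate the
pipeline end to end: a rate sweep for protrusion-count recovery and activity
monotonicity, a rendered-and-segmented phenotype benchmark with threshold
calibration, an escape cohort with programmed radial escapes, and cortex
fluorescence recovery.  Tests, the CLI and the reproduction script all call
these so the conditions are defined once.

Shared conditions: body radius 2.5 µm, pixel spacing 0.1625 µm/px, bleb
maximum radius 0.9 µm with fast (20 s) expansion and slow (150 s)
retraction, analysis cadence 20 s.  Blebbing cohorts are stationary
(confined cells typically bleb in place without net locomotion); the escape
cohort crawls at the measured 0.3 µm/min.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .blebbing import (
    blebbing_activity,
    calibrate_activity_threshold,
    count_bleb_nucleations,
)
from .escape import ConfinementBoundary, EscapeRecord, detect_escape
from .linescan import cortical_cytoplasmic_ratio
from .segmentation import segment_movie
from .simulate import (
    GroundTruth,
    SimParams,
    render_intensity_movie,
    simulate_blebbing_movie,
    simulate_escape_movie,
)
from .tracking import CellTrack, link_tracks, tracks_from_labels

__all__ = [
    "derive_seeds",
    "rate_sweep",
    "RateSweepResult",
    "measured_activities_cohort",
    "calibrate_threshold_simulated",
    "phenotype_benchmark",
    "escape_cohort",
    "EscapeCohort",
    "cortex_ratio_recovery",
]


def derive_seeds(seed: int, n: int) -> np.ndarray:
    """``n`` independent 31-bit child seeds derived from ``seed``."""
    return (
        np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64) % (2**31)
    ).astype(np.int64)


# ---------------------------------------------------------------------------
# rate sweep: nucleation recovery and activity monotonicity
# ---------------------------------------------------------------------------


@dataclass
class RateSweepResult:
    """Per-rate recovery of bleb nucleations and blebbing activity."""

    rate_per_min: float
    activities: np.ndarray  # per cell
    detected_nucleations: int  # summed over cells
    true_nucleations: int


def _single_cell_params(rate: float, duration_s: float, seed: int) -> SimParams:
    # stationary blebbing: confined cells typically extend blebs in all
    # directions without net locomotion
    return SimParams(
        image_size_px=(192, 192),
        frame_interval_s=5.0,
        duration_s=duration_s,
        n_cells=1,
        bleb_rate_per_min=rate,
        migration_speed_um_min=0.0,
        seed=int(seed),
    )


def rate_sweep(
    rates: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0),
    n_cells: int = 20,
    seed: int = 0,
    duration_s: float = 600.0,
    min_protrusion_px: int = 10,
) -> list[RateSweepResult]:
    """Simulate ``n_cells`` independent cells at each bleb rate.

    Each cell runs in its own movie (cells are independent in the model) for
    ``duration_s`` at a native 5-s interval.  Blebbing activity is measured
    on the 20-s resampled track, per the analysis procedure; nucleation
    counting runs at the native cadence, where closely spaced blebs are
    better separated in time.  Both are measured on the simulator's own
    label masks — this isolates the statistics from segmentation error; the
    phenotype benchmark covers the rendered-and-segmented route.
    """
    from .segmentation import resample_movie

    seeds = derive_seeds(seed, len(rates) * n_cells).reshape(len(rates), n_cells)
    out = []
    for r_idx, rate in enumerate(rates):
        activities = np.empty(n_cells)
        detected = 0
        truth_count = 0
        for c in range(n_cells):
            movie, truth = simulate_blebbing_movie(
                _single_cell_params(rate, duration_s, seeds[r_idx, c])
            )
            native_track = tracks_from_labels(movie)[0]
            resampled_track = tracks_from_labels(resample_movie(movie, 20.0))[0]
            activities[c] = blebbing_activity(resampled_track).activity
            detected += count_bleb_nucleations(native_track, min_protrusion_px)
            truth_count += len(truth.bleb_events)
        out.append(
            RateSweepResult(
                rate_per_min=rate,
                activities=activities,
                detected_nucleations=detected,
                true_nucleations=truth_count,
            )
        )
    return out


# ---------------------------------------------------------------------------
# phenotype benchmark: rendered + segmented activity and threshold calibration
# ---------------------------------------------------------------------------


def measured_activities_cohort(
    n_cells: int,
    bleb_rate_per_min: float,
    seed: int,
    *,
    cells_per_movie: int = 5,
    noise_sd: float = 0.05,
    duration_s: float = 240.0,
) -> np.ndarray:
    """Blebbing activities measured through the full imaging pipeline.

    Cells are simulated in batches, rendered as cortex-fluorescence movies
    with Gaussian noise, segmented with the watershed segmenter, linked, and
    measured.  Only full-length tracks enter the result (segmentation very
    occasionally drops a frame of a cell); the first ``n_cells`` activities
    are returned.
    """
    n_movies = math.ceil(n_cells * 1.2 / cells_per_movie) + 1
    seeds = derive_seeds(seed, 2 * n_movies).reshape(n_movies, 2)
    activities: list[float] = []
    for m in range(n_movies):
        if len(activities) >= n_cells:
            break
        params = SimParams(
            image_size_px=(256, 256),
            frame_interval_s=20.0,
            duration_s=duration_s,
            n_cells=cells_per_movie,
            bleb_rate_per_min=bleb_rate_per_min,
            migration_speed_um_min=0.0,
            seed=int(seeds[m, 0]),
        )
        labels_true, _ = simulate_blebbing_movie(params)
        intensity = render_intensity_movie(
            labels_true, "cortex_fluor", noise_sd=noise_sd, seed=int(seeds[m, 1])
        )
        labels = segment_movie(
            intensity, min_object_px=100, seed_min_distance_px=20
        )
        tracks = link_tracks(labels, max_link_dist_px=10.0)
        for track in tracks:
            if len(track) == labels.n_frames:
                activities.append(blebbing_activity(track).activity)
    return np.asarray(activities[:n_cells])


def calibrate_threshold_simulated(
    n_cells: int = 150, seed: int = 0, quantile: float = 0.99, **cohort_kwargs
) -> tuple[float, np.ndarray]:
    """Amoeboid-call threshold from a simulated non-blebbing population.

    The threshold is the ``quantile`` (default 99th percentile) of measured
    activities of non-blebbing cells pushed through rendering and
    segmentation, i.e. the pipeline's noise floor.  Estimating a 99th
    percentile needs well over a hundred cells, hence the default cohort.
    """
    activities = measured_activities_cohort(n_cells, 0.0, seed, **cohort_kwargs)
    return calibrate_activity_threshold(activities, quantile), activities


def phenotype_benchmark(
    n_per_class: int = 50,
    rate_per_min: float = 1.0,
    seed: int = 0,
) -> dict:
    """Classification accuracy of the amoeboid/flagellate call.

    Calibrates the activity threshold on an independent simulated
    non-blebbing cohort, then classifies ``n_per_class`` fresh non-blebbing
    and ``n_per_class`` blebbing cells measured through the full
    render-segment-track pipeline.  Returns threshold, per-class activities
    and overall accuracy against the programmed phenotypes.
    """
    cal_seed, neg_seed, pos_seed = derive_seeds(seed, 3)
    threshold, _ = calibrate_threshold_simulated(seed=int(cal_seed))
    neg = measured_activities_cohort(n_per_class, 0.0, int(neg_seed))
    pos = measured_activities_cohort(n_per_class, rate_per_min, int(pos_seed))
    correct = int((neg < threshold).sum() + (pos >= threshold).sum())
    total = neg.size + pos.size
    return {
        "threshold": float(threshold),
        "activities_flagellate": neg,
        "activities_amoeboid": pos,
        "accuracy": correct / total,
        "n_total": total,
    }


# ---------------------------------------------------------------------------
# escape cohort
# ---------------------------------------------------------------------------


@dataclass
class EscapeCohort:
    """Programmed escape cohort plus blebbing non-escaping controls."""

    escape_tracks: list[CellTrack]
    escape_records: list[EscapeRecord]
    escape_truths: list[GroundTruth]
    nonescape_tracks: list[CellTrack]
    nonescape_records: list[EscapeRecord]
    boundary: ConfinementBoundary


def _escape_params(seed: int) -> SimParams:
    return SimParams(
        image_size_px=(320, 320),
        frame_interval_s=10.0,
        duration_s=1800.0,
        n_cells=1,
        bleb_rate_per_min=1.0,
        migration_speed_um_min=0.3,
        seed=int(seed),
    )


def escape_cohort(
    n_escaping: int = 8,
    n_nonescaping: int = 8,
    seed: int = 0,
    start_dist_um: float = 3.0,
) -> EscapeCohort:
    """Simulate escaping cells and confined blebbing non-escapers.

    Escapers start ``start_dist_um`` inside a 12-µm confinement circle, bleb
    in place for 2 min, then crawl radially outward at 0.3 µm/min,
    elongating to aspect ratio 2 while crossing.  Non-escapers bleb near the
    circle centre and never reach the border.  Tracks are resampled to the
    20-s cadence before analysis.
    """
    from .segmentation import resample_movie

    seeds = derive_seeds(seed, n_escaping + n_nonescaping)
    spacing = 0.1625
    center_um = ((320 - 1) / 2 * spacing, (320 - 1) / 2 * spacing)
    boundary = ConfinementBoundary(center_um=center_um, radius_um=12.0)

    escape_tracks, escape_records, escape_truths = [], [], []
    for i in range(n_escaping):
        params = _escape_params(seeds[i])
        movie, truth = simulate_escape_movie(params, boundary, start_dist_um)
        track = tracks_from_labels(resample_movie(movie, 20.0))[0]
        escape_tracks.append(track)
        escape_records.append(detect_escape(track, boundary))
        escape_truths.append(truth)

    nonescape_tracks, nonescape_records = [], []
    for i in range(n_nonescaping):
        params = SimParams(
            image_size_px=(320, 320),
            frame_interval_s=10.0,
            duration_s=1800.0,
            n_cells=1,
            bleb_rate_per_min=1.0,
            migration_speed_um_min=0.0,  # confined blebbing without locomotion
            seed=int(seeds[n_escaping + i]),
        )
        movie, _ = simulate_blebbing_movie(params)
        track = tracks_from_labels(resample_movie(movie, 20.0))[0]
        # analysis circle around the cell (slightly off-centre so the radial
        # direction is defined everywhere); the cell starts well inside
        c = track.centroids_um[0]
        circle = ConfinementBoundary(
            center_um=(float(c[0]) + 1.0, float(c[1])), radius_um=12.0
        )
        nonescape_records.append(detect_escape(track, circle))
        nonescape_tracks.append(track)
    return EscapeCohort(
        escape_tracks=escape_tracks,
        escape_records=escape_records,
        escape_truths=escape_truths,
        nonescape_tracks=nonescape_tracks,
        nonescape_records=nonescape_records,
        boundary=boundary,
    )


def boundary_around(track: CellTrack, radius_um: float) -> ConfinementBoundary:
    """Confinement circle centred on a track's initial centroid."""
    c = track.centroids_um[0]
    return ConfinementBoundary(center_um=(float(c[0]), float(c[1])), radius_um=radius_um)


# ---------------------------------------------------------------------------
# fluorescence recovery
# ---------------------------------------------------------------------------


def cortex_ratio_recovery(
    true_ratio: float = 2.0,
    noise_sd: float = 0.05,
    cortex_width_um: float = 0.5,
    seed: int = 0,
) -> float:
    """Measured cortical/cytoplasmic ratio of a rendered static cell."""
    params = SimParams(
        image_size_px=(128, 128),
        frame_interval_s=20.0,
        duration_s=40.0,
        n_cells=1,
        bleb_rate_per_min=0.0,
        migration_speed_um_min=0.0,
        seed=int(seed),
    )
    movie, _ = simulate_blebbing_movie(params)
    intensity = render_intensity_movie(
        movie,
        "cortex_fluor",
        cortex_width_um=cortex_width_um,
        cortex_to_cytoplasm_ratio=true_ratio,
        noise_sd=noise_sd,
        seed=int(seed),
    )
    mask = movie.frames[0] > 0
    result = cortical_cytoplasmic_ratio(
        intensity.frames[0], mask, cortex_width_um, movie.pixel_spacing_um
    )
    return result.ratio
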