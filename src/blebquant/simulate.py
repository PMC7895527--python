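"""Synthetic movie generator with full ground truth.

Generates label and intensity movies of roughly round cells (body radius a
few µm) that stochastically nucleate blebs, crawl with slow persistent
motion, and — in the escape variant — cross a circular confinement boundary
while transiently elongating.  Every stochastic event is logged so each
downstream analysis stage can be tested against known truth without any
external data.

Model summary
-------------
* A cell is a disc of radius ``body_radius_um`` plus the union of its
  currently active bleb discs.  A bleb is a disc anchored at a fixed angle on
  the body boundary whose radius grows linearly to ``bleb_max_radius_um``
  over ``bleb_expand_s`` and then shrinks linearly to zero over
  ``bleb_retract_s``.  Bleb nucleation is a Poisson process per cell
  (``bleb_rate_per_min``) with anchor angles uniform on [0, 2π).
* Cell motion is a persistent random walk at constant speed
  ``migration_speed_um_min`` with heading diffusion set by
  ``persistence_time_s``; walls reflect.
* Shapes are rasterised by pixel-centre membership on the pixel grid
  (the centre of pixel ``(i, j)`` is at ``(i, j) * spacing``).
* Randomness: one :class:`numpy.random.SeedSequence` is built from ``seed``
  and spawned into ``n_cells + 1`` child streams — child 0 places the cells,
  child ``i + 1`` drives cell ``i`` (bleb schedule, anchors, heading noise).
  Identical seeds give bit-identical movies and logs, and cell ``i``'s
  realisation does not change when ``n_cells`` grows.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .escape import ConfinementBoundary
from .io import MovieStack

__all__ = [
    "SimParams",
    "BlebEvent",
    "GroundTruth",
    "simulate_blebbing_movie",
    "simulate_escape_movie",
    "render_intensity_movie",
]


@dataclass
class SimParams:
    """Parameters of the synthetic movie generator.

    Defaults follow the measured scales of the confined-choanoflagellate
    system: pixel spacing 0.1625 µm/px, body radius 2.5 µm, migration speed
    0.3 µm/min, and a bleb lifetime of a few minutes (fast seconds-scale
    expansion, slower retraction).
    """

    image_size_px: tuple[int, int] = (256, 256)
    pixel_spacing_um: float = 0.1625
    frame_interval_s: float = 5.0
    duration_s: float = 240.0
    n_cells: int = 1
    body_radius_um: float = 2.5
    #: scalar rate shared by all cells, or one rate per cell (min⁻¹)
    bleb_rate_per_min: float | Sequence[float] = 1.0
    bleb_max_radius_um: float = 0.9
    bleb_expand_s: float = 20.0
    bleb_retract_s: float = 150.0
    migration_speed_um_min: float = 0.3
    persistence_time_s: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.image_size_px) != 2 or min(self.image_size_px) < 8:
            raise ValueError("image_size_px must be a pair of side lengths >= 8")
        for name in (
            "pixel_spacing_um",
            "frame_interval_s",
            "duration_s",
            "body_radius_um",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in (
            "bleb_max_radius_um",
            "bleb_expand_s",
            "bleb_retract_s",
            "migration_speed_um_min",
            "persistence_time_s",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if np.any(self.cell_rates() < 0):
            raise ValueError("bleb_rate_per_min must be non-negative")
        if min(self.image_size_px) <= 2 * self.margin_px() + 4:
            raise ValueError(
                "image too small: cells (body + largest bleb) could leave the frame"
            )

    def cell_rates(self) -> np.ndarray:
        """Per-cell bleb nucleation rates, min⁻¹ (length ``n_cells``)."""
        rates = np.atleast_1d(np.asarray(self.bleb_rate_per_min, dtype=float))
        if rates.size == 1:
            rates = np.full(self.n_cells, rates[0])
        if rates.size != self.n_cells:
            raise ValueError("bleb_rate_per_min must be scalar or length n_cells")
        return rates

    def margin_px(self) -> int:
        """Wall margin keeping body + fully grown bleb inside the frame."""
        reach = self.body_radius_um + self.bleb_max_radius_um
        return int(np.ceil(reach / self.pixel_spacing_um)) + 2

    def frame_times(self) -> np.ndarray:
        return np.arange(0.0, self.duration_s + 1e-9, self.frame_interval_s)


@dataclass(frozen=True)
class BlebEvent:
    """One logged bleb nucleation."""

    cell_id: int
    t_s: float
    angle_rad: float
    max_area_um2: float  # π · bleb_max_radius²


@dataclass
class GroundTruth:
    """Simulator event log used as oracle by the recovery tests."""

    times_s: np.ndarray
    #: per-cell programmed centroid series, µm, shape (T, 2) as (row, col)
    true_tracks: dict[int, np.ndarray]
    bleb_events: list[BlebEvent]
    #: per-cell label: 'amoeboid' iff that cell's bleb rate > 0 else 'flagellate'
    phenotype_labels: dict[int, str]
    #: escape-variant log (boundary, direction, crossing times), if applicable
    escape: dict | None = None
    fluor_ratio_true: float | None = None

    def events_for(self, cell_id: int) -> list[BlebEvent]:
        return [e for e in self.bleb_events if e.cell_id == cell_id]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "times_s": self.times_s.tolist(),
            "true_tracks": {str(k): v.tolist() for k, v in self.true_tracks.items()},
            "bleb_events": [asdict(e) for e in self.bleb_events],
            "phenotype_labels": {str(k): v for k, v in self.phenotype_labels.items()},
            "escape": self.escape,
            "fluor_ratio_true": self.fluor_ratio_true,
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            times_s=np.asarray(d["times_s"], dtype=float),
            true_tracks={int(k): np.asarray(v, float) for k, v in d["true_tracks"].items()},
            bleb_events=[BlebEvent(**e) for e in d["bleb_events"]],
            phenotype_labels={int(k): v for k, v in d["phenotype_labels"].items()},
            escape=d.get("escape"),
            fluor_ratio_true=d.get("fluor_ratio_true"),
        )


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------


def _cell_streams(params: SimParams) -> tuple[np.random.Generator, list[np.random.Generator]]:
    children = np.random.SeedSequence(params.seed).spawn(params.n_cells + 1)
    placement = np.random.default_rng(children[0])
    cells = [np.random.default_rng(c) for c in children[1:]]
    return placement, cells


def _place_cells(params: SimParams, rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping initial positions (px, float), rejection sampled."""
    h, w = params.image_size_px
    margin = params.margin_px()
    reach_px = (params.body_radius_um + params.bleb_max_radius_um) / params.pixel_spacing_um
    # worst-case drift of the persistent walk keeps moving cells from ever
    # touching: path length is bounded by speed * duration
    drift_px = (
        params.migration_speed_um_min / 60.0 * params.duration_s / params.pixel_spacing_um
    )
    min_sep = 2.0 * reach_px + 2.0 * drift_px + 3.0
    positions: list[np.ndarray] = []
    for _ in range(params.n_cells):
        for _attempt in range(500):
            cand = rng.uniform([margin, margin], [h - 1 - margin, w - 1 - margin])
            if all(np.hypot(*(cand - p)) >= min_sep for p in positions):
                positions.append(cand)
                break
        else:
            raise RuntimeError(
                "could not place cells without overlap; reduce n_cells or enlarge image"
            )
    return np.asarray(positions)


def _random_walk(
    params: SimParams, rng: np.random.Generator, start_px: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Persistent random walk in pixel coordinates with reflecting walls."""
    h, w = params.image_size_px
    margin = float(params.margin_px())
    speed_px_s = params.migration_speed_um_min / 60.0 / params.pixel_spacing_um
    pos = np.empty((times.size, 2))
    pos[0] = start_px
    heading = rng.uniform(0.0, 2.0 * np.pi)
    lo = np.array([margin, margin])
    hi = np.array([h - 1 - margin, w - 1 - margin])
    for k in range(1, times.size):
        dt = times[k] - times[k - 1]
        if params.persistence_time_s > 0:
            heading += np.sqrt(2.0 * dt / params.persistence_time_s) * rng.normal()
        else:
            heading = rng.uniform(0.0, 2.0 * np.pi)
        step = speed_px_s * dt * np.array([np.cos(heading), np.sin(heading)])
        p = pos[k - 1] + step
        # reflect off the walls
        for ax in range(2):
            if p[ax] < lo[ax]:
                p[ax] = 2 * lo[ax] - p[ax]
            elif p[ax] > hi[ax]:
                p[ax] = 2 * hi[ax] - p[ax]
        pos[k] = np.clip(p, lo, hi)
    return pos


def _poisson_events(
    rng: np.random.Generator, rate_per_min: float, t_max: float
) -> np.ndarray:
    if rate_per_min <= 0 or t_max <= 0:
        return np.empty(0)
    out: list[float] = []
    t = 0.0
    scale = 60.0 / rate_per_min
    while True:
        t += rng.exponential(scale)
        if t >= t_max:
            return np.asarray(out)
        out.append(t)


def bleb_radius_um(age_s: float | np.ndarray, params: SimParams) -> np.ndarray:
    """Programmed bleb radius at a given age: linear growth, linear retraction."""
    age = np.asarray(age_s, dtype=float)
    r = np.zeros_like(age)
    expand, retract, rmax = params.bleb_expand_s, params.bleb_retract_s, params.bleb_max_radius_um
    if expand > 0:
        grow = (age >= 0) & (age < expand)
        r[grow] = rmax * age[grow] / expand
    shrink = (age >= expand) & (age < expand + retract)
    if retract > 0:
        r[shrink] = rmax * (1.0 - (age[shrink] - expand) / retract)
    elif expand > 0:
        pass  # instantaneous disappearance
    return r


def _paint_disc(frame: np.ndarray, center_px: np.ndarray, radius_px: float, label: int) -> None:
    if radius_px <= 0:
        return
    h, w = frame.shape
    r0 = max(int(np.floor(center_px[0] - radius_px)), 0)
    r1 = min(int(np.ceil(center_px[0] + radius_px)) + 1, h)
    c0 = max(int(np.floor(center_px[1] - radius_px)), 0)
    c1 = min(int(np.ceil(center_px[1] + radius_px)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    inside = (yy - center_px[0]) ** 2 + (xx - center_px[1]) ** 2 <= radius_px**2
    frame[r0:r1, c0:c1][inside] = label


def _paint_ellipse(
    frame: np.ndarray,
    center_px: np.ndarray,
    a_px: float,
    b_px: float,
    axis_angle: float,
    label: int,
) -> None:
    h, w = frame.shape
    rad = max(a_px, b_px)
    r0 = max(int(np.floor(center_px[0] - rad)), 0)
    r1 = min(int(np.ceil(center_px[0] + rad)) + 1, h)
    c0 = max(int(np.floor(center_px[1] - rad)), 0)
    c1 = min(int(np.ceil(center_px[1] + rad)) + 1, w)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy = yy - center_px[0]
    dx = xx - center_px[1]
    u = dy * np.cos(axis_angle) + dx * np.sin(axis_angle)
    v = -dy * np.sin(axis_angle) + dx * np.cos(axis_angle)
    inside = (u / a_px) ** 2 + (v / b_px) ** 2 <= 1.0
    frame[r0:r1, c0:c1][inside] = label


def _render_cell(
    frame: np.ndarray,
    params: SimParams,
    pos_px: np.ndarray,
    t: float,
    events: list[tuple[float, float]],
    label: int,
) -> None:
    """Body disc plus all active bleb discs for one cell at time ``t``."""
    spacing = params.pixel_spacing_um
    _paint_disc(frame, pos_px, params.body_radius_um / spacing, label)
    body_r_px = params.body_radius_um / spacing
    for t_nuc, angle in events:
        r_um = float(bleb_radius_um(t - t_nuc, params))
        if r_um <= 0:
            continue
        anchor = pos_px + body_r_px * np.array([np.cos(angle), np.sin(angle)])
        _paint_disc(frame, anchor, r_um / spacing, label)


# ---------------------------------------------------------------------------
# public simulators
# ---------------------------------------------------------------------------


def simulate_blebbing_movie(params: SimParams) -> tuple[MovieStack, GroundTruth]:
    """Simulate a label movie of blebbing, slowly migrating cells.

    Returns the rasterised label movie (cell ``i`` has label ``i + 1``) and
    the :class:`GroundTruth` log of programmed tracks and bleb nucleations.
    """
    placement_rng, cell_rngs = _cell_streams(params)
    times = params.frame_times()
    rates = params.cell_rates()
    start = _place_cells(params, placement_rng)

    tracks_px: dict[int, np.ndarray] = {}
    events_by_cell: dict[int, list[tuple[float, float]]] = {}
    bleb_events: list[BlebEvent] = []
    max_area = np.pi * params.bleb_max_radius_um**2
    for i in range(params.n_cells):
        rng = cell_rngs[i]
        cell_id = i + 1
        t_nucs = _poisson_events(rng, rates[i], params.duration_s)
        angles = rng.uniform(0.0, 2.0 * np.pi, size=t_nucs.size)
        events_by_cell[cell_id] = list(zip(t_nucs.tolist(), angles.tolist()))
        bleb_events.extend(
            BlebEvent(cell_id, float(t), float(a), max_area)
            for t, a in events_by_cell[cell_id]
        )
        tracks_px[cell_id] = _random_walk(params, rng, start[i], times)

    frames = np.zeros((times.size, *params.image_size_px), dtype=np.uint16)
    for k, t in enumerate(times):
        for cell_id in range(1, params.n_cells + 1):
            _render_cell(
                frames[k], params, tracks_px[cell_id][k], t, events_by_cell[cell_id], cell_id
            )

    movie = MovieStack(
        frames=frames,
        pixel_spacing_um=params.pixel_spacing_um,
        frame_interval_s=params.frame_interval_s,
        timestamps_s=times,
    )
    truth = GroundTruth(
        times_s=times,
        true_tracks={cid: p * params.pixel_spacing_um for cid, p in tracks_px.items()},
        bleb_events=sorted(bleb_events, key=lambda e: (e.t_s, e.cell_id)),
        phenotype_labels={
            i + 1: ("amoeboid" if rates[i] > 0 else "flagellate")
            for i in range(params.n_cells)
        },
    )
    return movie, truth


def simulate_escape_movie(
    params: SimParams,
    boundary: ConfinementBoundary,
    start_dist_um: float,
    *,
    bleb_phase_s: float = 120.0,
    aspect_peak: float = 2.0,
) -> tuple[MovieStack, GroundTruth]:
    """Simulate a single cell escaping a circular confinement boundary.

    The cell blebs in place for ``bleb_phase_s``, then crawls radially
    outward at ``migration_speed_um_min``.  While its body straddles the
    boundary, its programmed aspect ratio ramps up to ``aspect_peak`` (the
    body becomes an area-preserving ellipse elongated along the escape
    direction) and relaxes back to 1 afterwards.  Ground truth records the
    front-crossing time (first frame with any cell pixel outside the circle)
    and the completion time (first frame with every pixel outside), measured
    on the rasterised movie at the native frame rate, plus the programmed
    escape direction.

    Raises
    ------
    ValueError
        If ``start_dist_um`` exceeds the boundary radius (the cell would not
        start inside the confinement zone) or the programmed path would leave
        the frame.
    """
    if params.n_cells != 1:
        raise ValueError("escape movies simulate a single cell (n_cells must be 1)")
    if not (0 < start_dist_um <= boundary.radius_um):
        raise ValueError("start_dist_um must lie in (0, boundary radius]")
    if aspect_peak < 1:
        raise ValueError("aspect_peak must be >= 1")

    _, cell_rngs = _cell_streams(params)
    rng = cell_rngs[0]
    times = params.frame_times()
    spacing = params.pixel_spacing_um
    h, w = params.image_size_px
    center_px = np.asarray(boundary.center_um) / spacing

    direction = rng.uniform(0.0, 2.0 * np.pi)
    u = np.array([np.cos(direction), np.sin(direction)])
    start_um = np.asarray(boundary.center_um) + (boundary.radius_um - start_dist_um) * u

    speed_um_s = params.migration_speed_um_min / 60.0
    crawl_dist = speed_um_s * max(params.duration_s - bleb_phase_s, 0.0)
    a_max = params.body_radius_um * np.sqrt(aspect_peak)  # longest semi-axis
    final_radial = (boundary.radius_um - start_dist_um) + crawl_dist
    farthest_px = center_px + (final_radial + a_max) / spacing * u
    margin = params.margin_px()
    if not (
        margin <= farthest_px[0] <= h - 1 - margin
        and margin <= farthest_px[1] <= w - 1 - margin
    ):
        raise ValueError("programmed escape path leaves the frame; enlarge the image")

    def pos_um(t: float) -> np.ndarray:
        if t <= bleb_phase_s:
            return start_um
        return start_um + speed_um_s * (t - bleb_phase_s) * u

    # elongation zone: the body elongates only while it straddles the border
    elong_halfwidth = params.body_radius_um

    def aspect_at(t: float) -> float:
        d = float(np.linalg.norm(pos_um(t) - np.asarray(boundary.center_um)))
        s = boundary.radius_um - d  # signed centroid depth inside the boundary
        bump = max(0.0, 1.0 - abs(s) / elong_halfwidth)
        return 1.0 + (aspect_peak - 1.0) * bump

    rate = float(params.cell_rates()[0])
    t_nucs = _poisson_events(rng, rate, min(bleb_phase_s, params.duration_s))
    angles = rng.uniform(0.0, 2.0 * np.pi, size=t_nucs.size)
    events = list(zip(t_nucs.tolist(), angles.tolist()))
    max_area = np.pi * params.bleb_max_radius_um**2

    frames = np.zeros((times.size, h, w), dtype=np.uint16)
    track_um = np.empty((times.size, 2))
    for k, t in enumerate(times):
        p_um = pos_um(float(t))
        track_um[k] = p_um
        p_px = p_um / spacing
        ar = aspect_at(float(t))
        a_px = params.body_radius_um * np.sqrt(ar) / spacing
        b_px = params.body_radius_um / np.sqrt(ar) / spacing
        _paint_ellipse(frames[k], p_px, a_px, b_px, direction, 1)
        if t <= bleb_phase_s:
            body_r_px = params.body_radius_um / spacing
            for t_nuc, angle in events:
                r_um = float(bleb_radius_um(t - t_nuc, params))
                if r_um > 0:
                    anchor = p_px + body_r_px * np.array([np.cos(angle), np.sin(angle)])
                    _paint_disc(frames[k], anchor, r_um / spacing, 1)

    # ground-truth crossing times from the rasterised frames (pixel-centre test)
    t_front = t_complete = None
    yy, xx = np.mgrid[0:h, 0:w]
    rad_px = np.hypot(yy - center_px[0], xx - center_px[1])
    boundary_r_px = boundary.radius_um / spacing
    for k, t in enumerate(times):
        cell = frames[k] > 0
        outside = rad_px[cell] > boundary_r_px
        if t_front is None and outside.any():
            t_front = float(t)
        if t_complete is None and outside.all():
            t_complete = float(t)
            break

    movie = MovieStack(
        frames=frames,
        pixel_spacing_um=spacing,
        frame_interval_s=params.frame_interval_s,
        timestamps_s=times,
    )
    truth = GroundTruth(
        times_s=times,
        true_tracks={1: track_um},
        bleb_events=[BlebEvent(1, float(t), float(a), max_area) for t, a in events],
        phenotype_labels={1: "amoeboid" if rate > 0 else "flagellate"},
        escape={
            "boundary_center_um": [float(c) for c in boundary.center_um],
            "boundary_radius_um": float(boundary.radius_um),
            "direction_rad": float(direction),
            "start_dist_um": float(start_dist_um),
            "bleb_phase_s": float(bleb_phase_s),
            "aspect_peak": float(aspect_peak),
            "t_front_s": t_front,
            "t_complete_s": t_complete,
            "escaped": t_complete is not None,
        },
    )
    return movie, truth


# ---------------------------------------------------------------------------
# intensity rendering
# ---------------------------------------------------------------------------


def render_intensity_movie(
    labels: MovieStack,
    mode: str = "cortex_fluor",
    *,
    cortex_width_um: float = 0.5,
    cortex_to_cytoplasm_ratio: float = 2.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    baseline: float = 100.0,
) -> MovieStack:
    """Render a label movie into a noisy intensity movie.

    ``cortex_fluor`` paints each cell's cytoplasm at ``baseline`` intensity
    and a cortex band of width ``cortex_width_um`` along the cell boundary at
    ``cortex_to_cytoplasm_ratio × baseline`` — except on boundary segments
    belonging to currently expanding blebs (pixels gained since the previous
    frame), which stay cortex-free, emulating F-actin-free expanding blebs.
    ``dic_like`` produces a flat mid-grey background with brighter cell
    interiors and an edge-shading texture.  Gaussian noise with standard
    deviation ``noise_sd × baseline`` is added in both modes; the render is
    deterministic per ``seed``.

    Raises
    ------
    ValueError
        If the cortex band would swallow a whole cell (width must stay below
        the cell's inscribed radius) or the ratio is not positive.
    """
    from scipy import ndimage as ndi

    if mode not in ("cortex_fluor", "dic_like"):
        raise ValueError("mode must be 'cortex_fluor' or 'dic_like'")
    if cortex_to_cytoplasm_ratio <= 0:
        raise ValueError("cortex_to_cytoplasm_ratio must be positive")
    if not labels.is_label:
        raise ValueError("render_intensity_movie expects a label movie")

    rng = np.random.default_rng(np.random.SeedSequence(seed))
    out = np.zeros(labels.frames.shape, dtype=np.float32)
    struct = np.ones((3, 3), bool)

    for k in range(labels.n_frames):
        frame = labels.frames[k]
        img = out[k]
        if mode == "dic_like":
            img += 0.5 * baseline
        for cell_id in np.unique(frame):
            if cell_id == 0:
                continue
            mask = frame == cell_id
            if mode == "dic_like":
                img[mask] = 0.7 * baseline
                edge = ndi.sobel(ndi.gaussian_filter(mask.astype(np.float32), 1.0), axis=1)
                img += 0.3 * baseline * edge
                continue
            dist_in = ndi.distance_transform_edt(mask)
            band = mask & (dist_in * labels.pixel_spacing_um <= cortex_width_um)
            if not (mask & ~band).any():
                raise ValueError(
                    "cortex_width_um covers the whole cell; it must be smaller "
                    "than the cell's inscribed radius"
                )
            if k > 0:
                gained = mask & ~(labels.frames[k - 1] == cell_id)
                if gained.any():
                    band &= ~ndi.binary_dilation(gained, structure=struct)
            img[mask] = baseline
            img[band] = cortex_to_cytoplasm_ratio * baseline
    if noise_sd > 0:
        out += rng.normal(0.0, noise_sd * baseline, size=out.shape).astype(np.float32)
    return MovieStack(
        frames=out,
        pixel_spacing_um=labels.pixel_spacing_um,
        frame_interval_s=labels.frame_interval_s,
        timestamps_s=labels.timestamps_s.copy(),
    )
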