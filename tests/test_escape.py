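"""Escape geometry, crossing detection, angles, motility and event alignment."""

import numpy as np
import pytest
from scipy import stats as sps

from blebquant.escape import (
    ConfinementBoundary,
    align_to_event,
    boundary_distances,
    detect_escape,
    escape_angle_series,
    speed_and_persistence,
)
from blebquant.segmentation import resample_movie
from blebquant.simulate import SimParams, simulate_escape_movie
from blebquant.tracking import tracks_from_labels
from helpers import (
    SPACING,
    disc_mask,
    oracle_boundary_distances,
    random_blob,
    track_from_masks,
)

BOUNDARY = ConfinementBoundary(center_um=(100 * SPACING, 100 * SPACING), radius_um=10.0)


def test_single_pixel_cell_distances():
    mask = np.zeros((200, 200), bool)
    # pixel 3 µm inside the border, along +col from the centre
    col = 100 + round((BOUNDARY.radius_um - 3.0) / SPACING)
    mask[100, col] = True
    front, cent, rear = boundary_distances(mask, BOUNDARY, SPACING)
    d = abs((col - 100) * SPACING - BOUNDARY.radius_um)
    assert front == pytest.approx(d) and rear == pytest.approx(d)
    assert cent == pytest.approx(d)
    assert d == pytest.approx(3.0, abs=SPACING)


def test_segment_straddling_border_touches_it():
    mask = np.zeros((200, 200), bool)
    col0 = 100 + round(BOUNDARY.radius_um / SPACING) - 5
    mask[100, col0 : col0 + 11] = True  # 11 px straddling the border
    front, _, rear = boundary_distances(mask, BOUNDARY, SPACING)
    assert front <= 0.5 * SPACING  # a pixel sits on the border (half-pixel tol)
    assert front <= rear


@pytest.mark.parametrize("seed", range(5))
def test_distances_match_bruteforce_enumeration(seed):
    rng = np.random.default_rng(seed)
    mask = np.zeros((200, 200), bool)
    blob = random_blob(rng, shape=(40, 40))
    mask[80:120, 80:120] = blob
    got = boundary_distances(mask, BOUNDARY, SPACING)
    want = oracle_boundary_distances(mask, BOUNDARY.center_um, BOUNDARY.radius_um, SPACING)
    assert got == pytest.approx(want, abs=1e-9)


def test_detect_escape_on_simulated_escape_movie():
    params = SimParams(
        image_size_px=(320, 320), frame_interval_s=10.0, duration_s=1500.0,
        n_cells=1, bleb_rate_per_min=1.0, migration_speed_um_min=0.3, seed=1,
    )
    c = (320 - 1) / 2 * params.pixel_spacing_um
    boundary = ConfinementBoundary(center_um=(c, c), radius_um=12.0)
    movie, truth = simulate_escape_movie(params, boundary, 3.0)
    track = tracks_from_labels(resample_movie(movie, 20.0))[0]
    rec = detect_escape(track, boundary)
    assert rec.escaped
    assert abs(rec.t_complete_s - truth.escape["t_complete_s"]) <= 20.0
    assert abs(rec.t_front_s - truth.escape["t_front_s"]) <= 20.0
    assert np.all(rec.front_dist_um <= rec.rear_dist_um + 1e-9)


def test_cell_that_never_reaches_border_does_not_escape():
    masks = [disc_mask((200, 200), (100, 100), 12)] * 6
    rec = detect_escape(track_from_masks(masks), BOUNDARY)
    assert not rec.escaped
    assert rec.t_front_s is None and rec.t_complete_s is None


def test_cell_straddling_at_t0_has_immediate_front_crossing():
    center = (100, 100 + int(BOUNDARY.radius_um / SPACING))  # just inside
    masks = [disc_mask((200, 200), center, 10)] * 4
    rec = detect_escape(track_from_masks(masks), BOUNDARY)
    assert rec.t_front_s == 0.0


def test_initial_centroid_outside_rejected():
    center = (100, 100 + round(14.0 / SPACING))
    masks = [disc_mask((200, 200), center, 5)] * 3
    with pytest.raises(ValueError, match="outside"):
        detect_escape(track_from_masks(masks), BOUNDARY)


def _moving_track(step_px, n=12, start=(100, 60)):
    masks = []
    pos = np.array(start)
    for _ in range(n):
        masks.append(disc_mask((200, 200), tuple(pos), 6))
        pos = pos + np.array(step_px)
    return track_from_masks(masks)


def test_radial_motion_has_zero_escape_angle():
    # start at (100, 60), centre at (100, 100): outward radial is -col
    track = _moving_track((0, -2), start=(100, 60))
    angles = escape_angle_series(track, BOUNDARY)
    valid = angles[np.isfinite(angles)]
    assert valid.size > 0
    assert np.all(valid <= 5.0)


def test_tangential_motion_is_90_degrees():
    # short tangential hop (the radial direction rotates as the cell moves)
    track = _moving_track((2, 0), n=3, start=(100, 60))
    angles = escape_angle_series(track, BOUNDARY)
    valid = angles[np.isfinite(angles)]
    assert valid.size == 2
    assert np.all(np.abs(valid - 90.0) <= 5.0)


def test_random_walk_angles_uniform():
    rng = np.random.default_rng(0)
    masks = []
    pos = np.array([100.0, 100.0])
    for _ in range(220):
        masks.append(disc_mask((200, 200), tuple(pos), 3))
        theta = rng.uniform(0, 2 * np.pi)
        pos = np.clip(pos + 3 * np.array([np.cos(theta), np.sin(theta)]), 60, 140)
    angles = escape_angle_series(track_from_masks(masks), BOUNDARY)
    valid = angles[np.isfinite(angles)]
    assert valid.size >= 200
    assert sps.kstest(valid, sps.uniform(0, 180).cdf).pvalue > 0.01


def test_small_steps_are_skipped():
    track = track_from_masks([disc_mask((200, 200), (100, 60), 6)] * 5)
    angles = escape_angle_series(track, BOUNDARY)
    assert np.all(np.isnan(angles))


# -- speed and persistence --------------------------------------------------


def _point_track(positions_px, spacing=0.1, dt=20.0):
    masks = []
    for p in positions_px:
        m = np.zeros((64, 256), bool)
        m[p[0], p[1]] = True
        masks.append(m)
    return track_from_masks(masks, dt_s=dt, spacing=spacing)


def test_straight_line_track_speed_is_exact():
    # 1 px = 0.1 µm per 20 s step -> 0.3 µm/min, perfectly straight
    track = _point_track([(32, 10 + k) for k in range(10)])
    for definition, expected in (("paper_literal", 1.0), ("conventional", 1.0)):
        rec = speed_and_persistence(track, window_s=120.0, definition=definition)
        assert np.allclose(rec.speed_um_min, 0.3)
        assert np.allclose(rec.persistence, expected)


def test_zigzag_track_has_persistence_two():
    # up1 right2 down1 up1 right2 down1: path 8, net 4 over a 120 s window
    steps = [(-1, 0), (0, 2), (1, 0), (-1, 0), (0, 2), (1, 0)] * 2
    pos = [(32, 10)]
    for s in steps:
        pos.append((pos[-1][0] + s[0], pos[-1][1] + s[1]))
    track = _point_track(pos)
    literal = speed_and_persistence(track, window_s=120.0, definition="paper_literal")
    conventional = speed_and_persistence(track, window_s=120.0, definition="conventional")
    assert literal.persistence[0] == pytest.approx(2.0)
    assert conventional.persistence[0] == pytest.approx(0.5)
    assert np.allclose(conventional.persistence, 1.0 / literal.persistence)
    assert np.all(literal.persistence >= 1.0)


def test_static_cell_speed_zero_persistence_missing():
    track = _point_track([(32, 10)] * 8)
    rec = speed_and_persistence(track, window_s=120.0)
    assert np.allclose(rec.speed_um_min, 0.0)
    assert np.all(np.isnan(rec.persistence))


def test_window_longer_than_track_rejected():
    track = _point_track([(32, 10 + k) for k in range(4)])
    with pytest.raises(ValueError, match="window"):
        speed_and_persistence(track, window_s=120.0)


# -- event alignment --------------------------------------------------------


def test_align_single_track_mean_is_track_sd_zero():
    masks = [disc_mask((96, 96), (48, 48), 15)] * 5
    track = track_from_masks(masks)
    agg = align_to_event([track], [40.0])
    assert (agg["aspect_ratio_sd"] == 0).all()
    assert (agg["n_cells"] == 1).all()
    assert agg["time_s"].tolist() == [-40.0, -20.0, 0.0, 20.0, 40.0]


def test_align_empty_input_gives_empty_aggregate():
    agg = align_to_event([], [])
    assert agg.empty
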