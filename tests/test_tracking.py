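"""Linking and QC-filter behaviour, including the canonical exclusion fixture."""

import numpy as np
import pytest

from blebquant.io import MovieStack
from blebquant.simulate import SimParams, simulate_blebbing_movie
from blebquant.tracking import (
    QCParams,
    filter_tracks,
    link_tracks,
    tracks_from_labels,
    truncate_track,
)
from helpers import SPACING, disc_mask, ellipse_mask, track_from_masks


def _label_movie(frames, interval=20.0):
    return MovieStack(np.stack(frames).astype(np.int32), SPACING, interval)


def test_two_static_cells_give_two_full_tracks():
    frame = np.zeros((64, 96), np.int32)
    frame[disc_mask(frame.shape, (32, 24), 10)] = 1
    frame[disc_mask(frame.shape, (32, 70), 10)] = 2
    movie = _label_movie([frame] * 10)
    tracks = link_tracks(movie)
    assert len(tracks) == 2
    assert all(len(t) == 10 for t in tracks)


def test_linking_matches_simulator_identities():
    params = SimParams(
        image_size_px=(256, 256), n_cells=3, bleb_rate_per_min=0.0,
        migration_speed_um_min=0.3, duration_s=240.0, frame_interval_s=20.0, seed=4,
    )
    movie, truth = simulate_blebbing_movie(params)
    tracks = link_tracks(movie)
    assert len(tracks) == 3
    for track in tracks:
        assert len(track) == movie.n_frames
        # identify the ground-truth cell by the initial centroid
        c0 = track.centroids_um[0]
        errs = {
            cid: np.linalg.norm(truth.true_tracks[cid][0] - c0)
            for cid in truth.true_tracks
        }
        cid = min(errs, key=errs.get)
        rms_px = np.sqrt(
            np.mean(
                np.sum(
                    (track.centroids_px - truth.true_tracks[cid] / SPACING) ** 2, axis=1
                )
            )
        )
        assert rms_px < 1.0  # end-to-end centroid recovery within 1 px RMS


def test_disappearing_cell_ends_its_track():
    frames = []
    for k in range(8):
        f = np.zeros((64, 96), np.int32)
        f[disc_mask(f.shape, (32, 24), 10)] = 1
        if k < 4:
            f[disc_mask(f.shape, (32, 70), 10)] = 2
        frames.append(f)
    tracks = link_tracks(_label_movie(frames))
    lengths = sorted(len(t) for t in tracks)
    assert lengths == [4, 8]


def test_jump_beyond_link_distance_starts_new_track():
    frames = []
    for k in range(6):
        f = np.zeros((64, 128), np.int32)
        col = 30 if k < 3 else 95
        f[disc_mask(f.shape, (32, col), 10)] = 1
        frames.append(f)
    tracks = link_tracks(_label_movie(frames), max_link_dist_px=10.0)
    assert sorted(len(t) for t in tracks) == [3, 3]


def test_region_count_conserved_by_linking():
    params = SimParams(
        image_size_px=(256, 256), n_cells=4, bleb_rate_per_min=1.0,
        migration_speed_um_min=0.0, duration_s=200.0, frame_interval_s=20.0, seed=8,
    )
    movie, _ = simulate_blebbing_movie(params)
    n_regions = sum(len(np.unique(f)) - 1 for f in movie.frames)
    tracks = link_tracks(movie)
    assert sum(len(t) for t in tracks) == n_regions


# -- QC filter --------------------------------------------------------------

N_FRAMES = 13  # 240 s at 20 s
SHAPE = (96, 96)
CENTER = (48, 48)


def _compliant_masks():
    return [disc_mask(SHAPE, CENTER, 15)] * N_FRAMES  # area 709 px, circular


def qc_fixture_tracks():
    """12 tracks: 7 compliant, 5 violating exactly one exclusion rule each."""
    tracks = [track_from_masks(_compliant_masks(), cell_id=i) for i in range(1, 8)]
    # duration: 180 s < 200 s
    tracks.append(track_from_masks(_compliant_masks()[:10], cell_id=8))
    # area: constant 452 px (< 500 px) track; constant so no area-change step
    tracks.append(track_from_masks([disc_mask(SHAPE, CENTER, 12)] * N_FRAMES, cell_id=9))
    # displacement: one 6 px jump (> 5 px)
    masks = _compliant_masks()[:]
    masks[6] = disc_mask(SHAPE, (48, 54), 15)
    masks[7:] = [disc_mask(SHAPE, (48, 54), 15)] * (N_FRAMES - 7)
    tracks.append(track_from_masks(masks, cell_id=10))
    # area change: one frame at r=17 (908 px, +28% then -22%)
    masks = _compliant_masks()[:]
    masks[5] = disc_mask(SHAPE, CENTER, 17)
    tracks.append(track_from_masks(masks, cell_id=11))
    # circularity: one elongated frame of similar area (ellipse 30 x 7.4)
    masks = _compliant_masks()[:]
    masks[4] = ellipse_mask(SHAPE, CENTER, 30, 7.4)
    tracks.append(track_from_masks(masks, cell_id=12))
    return tracks


def test_qc_fixture_survivors_and_reason_counts():
    kept, report = filter_tracks(qc_fixture_tracks(), QCParams())
    assert report.n_input == 12
    assert {t.cell_id for t in kept} == set(range(1, 8))
    assert report.excluded_counts == {
        "duration": 1,
        "area": 1,
        "displacement": 1,
        "area_change": 1,
        "circularity": 1,
    }
    assert report.reasons_by_track == {
        8: ["duration"],
        9: ["area"],
        10: ["displacement"],
        11: ["area_change"],
        12: ["circularity"],
    }


@pytest.mark.parametrize(
    "field,tighter",
    [
        ("min_area_px", 800),
        ("max_step_disp_px", 0.5),
        ("max_area_change_frac", 0.01),
        ("min_circularity", 0.99),
        ("min_track_duration_s", 239.0),
    ],
)
def test_tightening_any_threshold_never_keeps_more(field, tighter):
    tracks = qc_fixture_tracks()
    base_kept, _ = filter_tracks(tracks, QCParams())
    tight_kept, _ = filter_tracks(tracks, QCParams(**{field: tighter}))
    assert len(tight_kept) <= len(base_kept)


def test_unresampled_track_rejected():
    track = track_from_masks(_compliant_masks()[:5], dt_s=7.0)
    with pytest.raises(ValueError, match="resampled"):
        filter_tracks([track], QCParams())


def test_truncate_track_keeps_window():
    track = track_from_masks(_compliant_masks())
    short = truncate_track(track, 100.0)
    assert short.times_s[-1] <= 100.0
    assert len(short) == 6


def test_tracks_from_labels_uses_frame_consistent_ids():
    params = SimParams(
        image_size_px=(160, 160), n_cells=2, bleb_rate_per_min=0.0,
        migration_speed_um_min=0.0, duration_s=100.0, frame_interval_s=20.0, seed=3,
    )
    movie, truth = simulate_blebbing_movie(params)
    tracks = tracks_from_labels(movie)
    assert [t.cell_id for t in tracks] == [1, 2]
    for t in tracks:
        np.testing.assert_allclose(
            t.centroids_um, truth.true_tracks[t.cell_id], atol=0.2
        )
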