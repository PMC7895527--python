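"""Simulator correctness: determinism, event statistics, geometry, rendering."""

import numpy as np
import pytest
from scipy import stats as sps

from blebquant.escape import ConfinementBoundary
from blebquant.io import read_movie, write_movie
from blebquant.simulate import (
    GroundTruth,
    SimParams,
    bleb_radius_um,
    render_intensity_movie,
    simulate_blebbing_movie,
    simulate_escape_movie,
)

SMALL = dict(image_size_px=(128, 128), duration_s=100.0, frame_interval_s=20.0)


def test_static_case_all_frames_identical():
    params = SimParams(n_cells=2, bleb_rate_per_min=0.0, migration_speed_um_min=0.0, **SMALL)
    movie, truth = simulate_blebbing_movie(params)
    assert len(truth.bleb_events) == 0
    for frame in movie.frames[1:]:
        assert np.array_equal(frame, movie.frames[0])


def test_same_seed_bitwise_identical():
    params = SimParams(n_cells=3, bleb_rate_per_min=1.0, seed=7, **SMALL)
    m1, t1 = simulate_blebbing_movie(params)
    m2, t2 = simulate_blebbing_movie(params)
    assert np.array_equal(m1.frames, m2.frames)
    assert t1.bleb_events == t2.bleb_events
    for cid in t1.true_tracks:
        assert np.array_equal(t1.true_tracks[cid], t2.true_tracks[cid])


def test_cell_stream_stable_under_cell_count_change():
    """Cell i's bleb schedule must not change when more cells are added."""
    base = dict(image_size_px=(256, 256), duration_s=200.0, frame_interval_s=20.0,
                bleb_rate_per_min=1.0, migration_speed_um_min=0.0, seed=5)
    _, t1 = simulate_blebbing_movie(SimParams(n_cells=1, **base))
    _, t3 = simulate_blebbing_movie(SimParams(n_cells=3, **base))
    assert t1.events_for(1) == t3.events_for(1)


def test_poisson_event_count_in_99pct_interval():
    """20 cells x 600 s at 1/min: expected 200 nucleations."""
    params = SimParams(
        image_size_px=(512, 512),
        duration_s=600.0,
        frame_interval_s=60.0,
        n_cells=20,
        bleb_rate_per_min=1.0,
        migration_speed_um_min=0.0,
        seed=42,
    )
    _, truth = simulate_blebbing_movie(params)
    lam = 20 * 10 * 1.0
    lo, hi = sps.poisson(lam).ppf([0.005, 0.995])
    assert lo <= len(truth.bleb_events) <= hi


def test_body_area_conserved_during_migration():
    params = SimParams(
        image_size_px=(128, 128),
        duration_s=240.0,
        frame_interval_s=20.0,
        n_cells=1,
        bleb_rate_per_min=0.0,
        migration_speed_um_min=1.0,
        seed=1,
    )
    movie, _ = simulate_blebbing_movie(params)
    areas = np.array([(f > 0).sum() for f in movie.frames])
    assert np.all(np.abs(areas / areas.mean() - 1) < 0.02)


def test_every_protrusion_matches_a_logged_bleb():
    """Event-log completeness: each protrusion component maps to an active bleb."""
    from scipy import ndimage as ndi

    params = SimParams(
        image_size_px=(160, 160),
        duration_s=300.0,
        frame_interval_s=20.0,
        n_cells=1,
        bleb_rate_per_min=2.0,
        migration_speed_um_min=0.0,
        seed=9,
    )
    movie, truth = simulate_blebbing_movie(params)
    spacing = params.pixel_spacing_um
    body_r_px = params.body_radius_um / spacing
    for k, t in enumerate(movie.timestamps_s):
        center_px = truth.true_tracks[1][k] / spacing
        yy, xx = np.mgrid[0 : 160, 0 : 160]
        body = (yy - center_px[0]) ** 2 + (xx - center_px[1]) ** 2 <= body_r_px**2
        protrusions = (movie.frames[k] > 0) & ~body
        labeled, n = ndi.label(protrusions, structure=np.ones((3, 3), bool))
        active = []
        for ev in truth.bleb_events:
            r_um = float(bleb_radius_um(t - ev.t_s, params))
            if r_um > 0:
                anchor = center_px + body_r_px * np.array(
                    [np.cos(ev.angle_rad), np.sin(ev.angle_rad)]
                )
                active.append((anchor, r_um / spacing))
        for comp_id in range(1, n + 1):
            rows, cols = np.nonzero(labeled == comp_id)
            covered = np.zeros(rows.size, bool)
            for anchor, r_px in active:
                covered |= (rows - anchor[0]) ** 2 + (cols - anchor[1]) ** 2 <= r_px**2
            assert covered.all(), f"unlogged protrusion at t={t}"


def test_rejects_invalid_params():
    with pytest.raises(ValueError):
        SimParams(image_size_px=(32, 32))  # too small for default radii
    with pytest.raises(ValueError):
        SimParams(bleb_rate_per_min=-1.0, **SMALL)
    with pytest.raises(ValueError):
        SimParams(duration_s=-5)


def test_overcrowded_placement_fails_cleanly():
    params = SimParams(
        image_size_px=(128, 128), duration_s=40.0, frame_interval_s=20.0, n_cells=30
    )
    with pytest.raises(RuntimeError, match="place"):
        simulate_blebbing_movie(params)


# -- escape variant ---------------------------------------------------------


def _escape_setup(duration_s=1500.0, start=3.0):
    params = SimParams(
        image_size_px=(320, 320),
        frame_interval_s=10.0,
        duration_s=duration_s,
        n_cells=1,
        bleb_rate_per_min=1.0,
        migration_speed_um_min=0.3,
        seed=2,
    )
    c = (320 - 1) / 2 * params.pixel_spacing_um
    boundary = ConfinementBoundary(center_um=(c, c), radius_um=12.0)
    return params, boundary, start


def test_escape_movie_crosses_and_logs_times():
    params, boundary, start = _escape_setup()
    movie, truth = simulate_escape_movie(params, boundary, start)
    esc = truth.escape
    assert esc["escaped"]
    assert esc["t_front_s"] is not None and esc["t_complete_s"] is not None
    assert esc["t_front_s"] <= esc["t_complete_s"]
    # programmed crawl is radial: direction recorded
    assert 0 <= esc["direction_rad"] < 2 * np.pi


def test_escape_aspect_ratio_rises_then_relaxes():
    from blebquant.tracking import tracks_from_labels

    params, boundary, start = _escape_setup(duration_s=1800.0)
    movie, truth = simulate_escape_movie(params, boundary, start)
    track = tracks_from_labels(movie)[0]
    ars = track.aspect_ratios
    assert ars.max() > 1.5  # elongation while crossing
    assert ars[0] < 1.1 and ars[-1] < 1.1  # round before and after


def test_escape_beyond_reach_never_crosses():
    params, boundary, _ = _escape_setup(duration_s=300.0)
    movie, truth = simulate_escape_movie(params, boundary, 8.0)
    assert truth.escape["escaped"] is False
    assert truth.escape["t_front_s"] is None


def test_escape_start_outside_radius_rejected():
    params, boundary, _ = _escape_setup()
    with pytest.raises(ValueError, match="start_dist"):
        simulate_escape_movie(params, boundary, boundary.radius_um + 1.0)


# -- intensity rendering ----------------------------------------------------


def _static_cell_movie():
    params = SimParams(
        image_size_px=(96, 96), duration_s=20.0, frame_interval_s=20.0,
        n_cells=1, bleb_rate_per_min=0.0, migration_speed_um_min=0.0, seed=3,
    )
    return simulate_blebbing_movie(params)


def test_render_ratio_one_no_noise_is_uniform_inside():
    movie, _ = _static_cell_movie()
    intensity = render_intensity_movie(
        movie, "cortex_fluor", cortex_to_cytoplasm_ratio=1.0, noise_sd=0.0
    )
    cell = movie.frames[0] > 0
    assert np.all(intensity.frames[0][cell] == intensity.frames[0][cell][0])
    assert np.all(intensity.frames[0][~cell] == 0)


def test_render_deterministic_per_seed_and_validates():
    movie, _ = _static_cell_movie()
    a = render_intensity_movie(movie, "cortex_fluor", noise_sd=0.05, seed=8)
    b = render_intensity_movie(movie, "cortex_fluor", noise_sd=0.05, seed=8)
    assert np.array_equal(a.frames, b.frames)
    with pytest.raises(ValueError, match="ratio"):
        render_intensity_movie(movie, "cortex_fluor", cortex_to_cytoplasm_ratio=0.0)
    with pytest.raises(ValueError, match="cortex_width"):
        render_intensity_movie(movie, "cortex_fluor", cortex_width_um=5.0)


def test_expanding_bleb_boundary_lacks_cortex():
    params = SimParams(
        image_size_px=(96, 96), duration_s=40.0, frame_interval_s=20.0,
        n_cells=1, bleb_rate_per_min=0.0, migration_speed_um_min=0.0, seed=3,
    )
    movie, _ = simulate_blebbing_movie(params)
    frames = movie.frames.copy()
    # graft a synthetic expanding bleb onto frame 1
    yy, xx = np.mgrid[0:96, 0:96]
    rows, cols = np.nonzero(frames[0])
    anchor = (rows.min(), int(cols[rows == rows.min()].mean()))
    bleb = (yy - anchor[0]) ** 2 + (xx - anchor[1]) ** 2 <= 5**2
    frames[1][bleb] = 1
    movie2 = type(movie)(
        frames=frames, pixel_spacing_um=movie.pixel_spacing_um,
        frame_interval_s=movie.frame_interval_s, timestamps_s=movie.timestamps_s,
    )
    intensity = render_intensity_movie(
        movie2, "cortex_fluor", cortex_to_cytoplasm_ratio=2.0, noise_sd=0.0
    )
    gained = bleb & ~(frames[0] == 1)
    # gained bleb region is cytoplasm-bright only, never cortex-bright
    assert intensity.frames[1][gained].max() <= 100.0


def test_movie_and_ground_truth_roundtrip(tmp_path):
    params = SimParams(n_cells=1, bleb_rate_per_min=1.0, seed=6, **SMALL)
    movie, truth = simulate_blebbing_movie(params)
    path = write_movie(movie, tmp_path / "m.tif")
    loaded = read_movie(path)
    assert np.array_equal(loaded.frames, movie.frames)
    assert loaded.pixel_spacing_um == movie.pixel_spacing_um
    truth.to_json(tmp_path / "gt.json")
    back = GroundTruth.from_json(tmp_path / "gt.json")
    assert back.bleb_events == truth.bleb_events
    assert back.phenotype_labels == truth.phenotype_labels
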