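# blebquant

Quantitative image analysis for cells that switch to **bleb-based amoeboid
motility under physical confinement** — as choanoflagellates (and many animal
cells) do when squeezed below their body diameter.  The package turns
time-lapse movies of such cells into per-cell measurements: blebbing
activity, protrusion events, escape-assay geometry and morphodynamics,
cortical fluorescence enrichment, and nested-replicate statistics.  Because
raw confinement movies are rarely shareable, it ships a synthetic movie
generator with full ground truth, so the entire pipeline is testable end to
end without any external data.

## What it computes

**Blebbing activity** of a cell is the rate of cell shape change: with masks
resampled to one frame per 20 s and truncated to the first 240 s,

```
activity = mean_t [ ( |M_t \ M_{t-20s}| + |M_{t-20s} \ M_t| ) / |M_t| ]
```

the per-step symmetric-difference area normalised by the current cell area.
Connected components of the gained set are *expanding* blebs, of the lost
set *retracting* blebs.  Tracks are QC-filtered first (area < 500 px, step
displacement > 5 px, step area change > 10 %, circularity < 0.7, duration
< 200 s at 0.1625 µm/px all exclude).

**Morphometrics**: centroid, projected area, Crofton perimeter, aspect ratio
`AR = a/b` from the moment-equivalent ellipse, circularity `4πA/P²`.

**Escape assay**: for a circular confinement boundary (centre c, radius R),
front/centroid/rear distances `| ‖p − c‖ − R |`, front-crossing and
whole-cell crossing times, the angle between each crawling step and the
shortest escape path, windowed speed (µm/min) and directional persistence
(total path / Euclidean displacement over 2 min, or its reciprocal).

**Fluorescence**: bilinear linescans with perpendicular averaging, peak
detection, and the cortical/cytoplasmic ratio (mean intensity in a boundary
band over the eroded interior).

**Statistics**: SuperPlot-style aggregation (cells = technical replicates
nested in biological replicates), Dunnett's many-to-one test on replicate
means, exact/tie-corrected Mann–Whitney U.

## Worked example

```python
import blebquant as bq

# simulate one blebbing cell (body radius 2.5 um, one bleb per minute)
params = bq.SimParams(n_cells=1, bleb_rate_per_min=1.0, duration_s=240.0,
                      frame_interval_s=20.0, image_size_px=(192, 192), seed=3)
movie, truth = bq.simulate_blebbing_movie(params)

track = bq.tracks_from_labels(movie)[0]
result = bq.blebbing_activity(track)
print(f"{len(truth.bleb_events)} blebs, activity {result.activity:.4f}")
```

prints

```
5 blebs, activity 0.0772
```

five blebs nucleated in the 4-minute window, and on average 7.7 % of the
cell's area changed per 20-s step — an order of magnitude above the
segmentation noise floor (~0.1–0.6 %), so this cell is called `amoeboid` by
`bq.classify_phenotype` at the simulation-calibrated threshold.

The same movie can be rendered into a noisy cortex-fluorescence movie
(`bq.render_intensity_movie`), segmented (`bq.segment_movie`), linked
(`bq.link_tracks`) and measured identically — that round trip is how the
package validates itself.

A thin CLI wraps the same functions:

```bash
blebquant simulate blebbing --seed 3 --out run/   # labels.tif + ground_truth.json
blebquant activity --movie run/labels.tif --out run/analysis/
blebquant stats --table cells.csv --control control --out report.json
```

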