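# Methods

This note documents the models, conventions and numerical choices behind
`blebquant`, and what the synthetic benchmarks do and do not demonstrate
about real microscopy data.

## Coordinate and unit conventions

Pixel indices are 0-based `(row, col)`; the centre of pixel `(i, j)` lies at
physical coordinate `(i, j) × spacing` µm with y pointing down.  The default
pixel spacing is 0.1625 µm/px and the default acquisition interval 5 s.
Analyses that mirror the published pipeline operate at a 20-s cadence over
the first 240 s of a movie.  Intensities are arbitrary units; no photometric
calibration is applied anywhere.

## The synthetic movie generator

A cell is modelled as a disc (body radius 2.5 µm, the middle of the 2–10 µm
choanoflagellate diameter range) plus the union of its active bleb discs.
Blebs nucleate as a Poisson process per cell (default 1 min⁻¹) at anchor
angles uniform on [0, 2π); each bleb disc is anchored at a fixed angle on
the body boundary and grows linearly to 0.9 µm radius over 20 s, then
shrinks linearly to zero over 150 s.  The ~3-minute lifetime keeps the
minutes-scale dynamics of confined-cell blebs; the fast expansion follows
the seconds-scale expansion canonical for cellular blebs and keeps
individual nucleations resolvable at the 20-s analysis cadence — single
slower exemplars exist in the source system, and both phases are plain
parameters (`bleb_expand_s`, `bleb_retract_s`).  No bleb nucleation rate has
been measured for this system; the defaults are calibrated only to lifetime
scale, not to a measured rate.

Cell motion is a persistent random walk at constant speed (default
0.3 µm/min, the measured initial median crawling speed; persistence time
60 s) with reflecting walls.  Cells never overlap: initial placement is
rejection-sampled with a separation that includes each cell's worst-case
path length, so the no-overlap guarantee holds for the whole movie.
Cell–cell collisions, membrane mechanics and realistic DIC optics are
explicitly out of scope.

Shapes are rasterised by pixel-centre membership (a pixel belongs to a disc
iff its centre does), which makes exact pixel-set oracles possible.  Body
area is conserved over time to within rasterisation jitter (±2 % for radii
≥ 15 px).  Randomness derives from one `SeedSequence` spawned into one
stream per cell plus one for placement, so cell *i*'s realisation is
unchanged when more cells are added and identical seeds give bit-identical
movies and logs.

The escape variant places a single cell `start_dist` inside a circular
boundary, lets it bleb in place for 2 min, then crawls it radially outward.
While the body straddles the border (centroid within one body radius of it)
the programmed aspect ratio ramps linearly to 2.0 as an area-preserving
ellipse aligned with the escape direction, relaxing back to 1 outside.
Ground-truth crossing times are measured on the rasterised frames at the
native frame rate, so the analysis-side detection (at the 20-s cadence) can
be held to within one resampled frame.

The intensity renderer paints cytoplasm at a baseline intensity and a
cortex band (default width 0.5 µm) at `ratio ×` baseline along the cell
boundary, omitting the band on boundary segments gained since the previous
frame — expanding blebs are cortex-free, as F-actin/myosin imaging of
blebbing cells shows.  Gaussian noise (default SD 5 % of baseline) is added
per pixel.

## Segmentation, registration, resampling, tracking

The segmenter is a classical stand-in for a trained model: Gaussian
smoothing (default 0.1 µm; raise it for noisier or textured data), optional
large-kernel background subtraction, Otsu threshold, distance-transform
maxima (minimum separation `seed_min_distance_px`, default 10 px; use ~20 px
for 2.5-µm-radius cells so a large bleb cannot seed its own object) and
seeded watershed, discarding objects under `min_object_px`.  On rendered
cortex movies with ≤ 10 % noise it recovers cells at IoU ≥ 0.99; on real DIC
data a learned segmenter would be substituted upstream and everything
downstream is unchanged.

Registration is translation-only to the first frame by phase
cross-correlation at integer-pixel precision with zero padding; degenerate
(constant) frames get zero shift and a log message.  Resampling keeps the
frame nearest each 20-s target timestamp — masks are not interpolable
without a shape model — and refuses to upsample.

Linking is greedy nearest-centroid bipartite matching between consecutive
frames: candidate pairs in order of increasing distance (ties by smaller
label), links only within `max_link_dist_px`, unmatched regions start new
tracks.  With non-overlapping, slowly moving cells this is exact; it is not
meant to survive occlusions or divisions.

QC filtering removes a track iff duration < 200 s or any analysed time
point has area < 500 px, step displacement > 5 px, |step area change| >
10 % (the published "change > 10 %" is read as absolute change), or
circularity < 0.7.  Displacement is centroid displacement between
consecutive 20-s samples in pixels at 0.1625 µm/px.  The report counts every
violated rule per track.

## Morphometrics

Axes come from the moment-equivalent ellipse (axis length = 4·√eigenvalue of
the normalised second central moments) — not bounding boxes or Feret
diameters — matching automated long/short-axis detection and robust to
boundary noise.  The perimeter uses the **4-direction Crofton estimator**
(`skimage.measure.perimeter_crofton`): a rasterised disc of radius 50 px has
circularity 0.992, and circularity decreases monotonically along ellipse
families of growing eccentricity.  The weighted boundary-step estimator was
rejected because it biases disc circularity to ~0.91, which would silently
shift the 0.7 circularity QC cut.  Circularity may exceed 1 by up to
ε = 0.05 for small rasterised discs.  Empty and multi-component masks are
errors; callers take the largest component explicitly (the tracker does so,
with a log message).

## Blebbing activity and protrusions

Activity is the per-step symmetric-difference area normalised by the
**current-frame** area, averaged over steps.  The normaliser frame is a
choice (the published description does not fix it); current-frame keeps each
step a local rate, and the mean-area alternative differs only in the third
decimal for near-constant areas.  The difference is computed on globally
registered frames without per-cell re-centring; because QC excludes cells
moving > 5 px per step, translation leakage is bounded (a cell crawling at
0.3 µm/min adds ~0.05 to activity via its leading/trailing crescents —
stationary cells are the cleanest substrate for the statistic, and confined
blebbing cells are typically stationary).

Protrusion events are 8-connected components of the gained (expanding) and
lost (retracting) sets, dropping components below `min_protrusion_px`
(default 10 px at 0.1625 µm/px, suppressing 1–2 px boundary flicker).
Nucleation counting links an expanding component to the previous step's
expanding set by 1-px dilation overlap; unlinked components count as new
blebs.  Counting runs best at the native (5 s) cadence, where closely
spaced blebs are separated in time; recovery on simulated cohorts is 87–97 %
of logged nucleations at rates 0.5–2 min⁻¹ (misses are blebs nucleating
within another bleb's footprint or too close to the movie end to reach
detectable size).

The amoeboid/flagellate call thresholds the activity (≥ is amoeboid).  The
published criterion — presence of dynamic protrusions — was scored by eye,
so the threshold is calibrated as the 99th percentile of activity in a
simulated non-blebbing population measured through the full
render–segment–track pipeline (150 cells; a 99th percentile cannot be
estimated from a few dozen).  At 5 % render noise the floor is ~0.001–0.002
against a blebbing signal of ~0.01–0.06, giving 98–99 % classification
accuracy; the residual errors are blebbing cells that happen to realise no
nucleation in the 240-s window (~2 % at 1 min⁻¹ by Poisson statistics) —
a property of the observation window, not of the classifier.

## Escape analysis

Front/rear distances are the min/max over cell pixel centres of the unsigned
distance to the circle, `| ‖p − c‖ − R |`; escape state uses the signed side
(outside = `‖p − c‖ > R`).  Both crossing times are reported: `t_front`
(first pixel outside) and `t_complete` (all pixels outside); completion is
the sharper proxy for "escape complete" and is the event used for
time-alignment.  Escape angles are measured per step between the centroid
displacement and the outward radial direction at the step start, for steps
starting inside the zone with displacement ≥ 0.5 px; steps from the exact
circle centre are skipped and logged.  On the simulated radial-escape
cohort the mean angle is ~8° — the programmed deviation is 0°, and the
residual is centroid rasterisation jitter on 0.6-px steps plus bleb-phase
centroid wobble.

Speed is total path over window duration in sliding 2-min windows stepping
one resampled frame.  Directional persistence defaults to the literal
published definition, total path / Euclidean displacement (≥ 1; larger =
less straight); the conventional reciprocal (∈ [0, 1], larger = straighter)
is available as `definition="conventional"` — both are exposed because the
published text pairs the literal definition with language implying the
conventional one, and no intent is guessed.  Zero-displacement windows have
undefined persistence (NaN, logged).

Event alignment re-zeroes each track at its event time, snaps to bins of
the sampling interval, and reports mean and population SD (single track →
SD 0) of aspect ratio and projected area per bin.

## Fluorescence

Linescans sample at ≤ 1 px spacing with bilinear interpolation, averaged
over `width_px` perpendicular offsets; peaks are local maxima with
prominence ≥ a fraction of the profile range.  The cortical/cytoplasmic
ratio divides the mean intensity of the mask pixels within `cortex_band_um`
of the boundary (Euclidean distance transform) by the mean of the remaining
interior, with an optional constant background subtracted from both — which
makes the ratio invariant under global scaling and under an added,
re-subtracted background.  The published procedure for this ratio is not
specified; the band default (0.5 µm ≈ 3 px) matches the visible cortex
width, and a peak-height alternative is available via linescan + peak
detection.  On matched-band renders the recovered ratio is within a few
per mil of truth at 5 % noise.

## Statistics

SuperPlot aggregation reduces cells (technical replicates) to biological
replicate means; the tests consume replicate means by default — running them
on pooled cells pseudoreplicates, and the per-cell mode exists only behind
an explicit warning.  Dunnett's test uses the multivariate-t reference
distribution with pooled variance (scipy's implementation, seeded internally
so p-values are reproducible; quadrature noise is ~10⁻⁴).  With one
treatment group it reduces to the two-sided pooled-variance t-test within
10⁻³, and the simulated family-wise error at α = 0.05 under a 3-group null
is 0.046–0.051 (10⁴ replicates).  Mann–Whitney U is exact by enumeration
for tie-free samples with n ≤ 12 and otherwise uses the tie-corrected
normal approximation with continuity correction; `U_x + U_y = n_x·n_y`.

## What the benchmarks do and do not show

All validation is against the simulator: rasterised discs/ellipses, binary
intensity profiles with Gaussian noise, no debris, no focus drift, no
cell–cell contact, no divisions, and a segmenter matched to the renderer.
Passing therefore demonstrates that the *measurement pipeline* is correct —
the statistics match brute-force oracles exactly, programmed rates,
phenotypes, escape times and fluorescence ratios are recovered — not that
segmentation or tracking would reach the same fidelity on real DIC movies,
where a trained segmenter and manual QC of the boundary circle were needed.
Problem sizes (20-cell rate cohorts over 600 s, 100-cell phenotype
benchmark, 8-cell escape cohort, 10⁴-rep statistical calibration) were
chosen to give stable estimates at desk scale.

## Known limitations

* The greedy linker assumes well-separated cells; no occlusion handling.
* Activity conflates protrusion dynamics with any residual translation;
  the QC displacement filter bounds but does not remove this.
* Nucleation counting undercounts blebs that nucleate inside another bleb's
  footprint (by ~5–10 % at 2 min⁻¹).
* The cortex-ratio band and the segmentation smoothing are tuned to the
  renderer's sharp-edged cells; real point-spread functions will need wider
  bands and more smoothing.
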