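"""Shared test utilities: simple rasterisers and brute-force oracles.

The oracles here deliberately use plain Python loops and pixel sets so they
stay independent of the vectorised implementation paths they check.
"""

from __future__ import annotations

import numpy as np

from blebquant.morphometrics import shape_descriptors
from blebquant.tracking import CellTrack

SPACING = 0.1625


def disc_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius**2


def ellipse_mask(shape, center, a, b, angle=0.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy = yy - center[0]
    dx = xx - center[1]
    u = dy * np.cos(angle) + dx * np.sin(angle)
    v = -dy * np.sin(angle) + dx * np.cos(angle)
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def track_from_masks(masks, dt_s=20.0, spacing=SPACING, cell_id=1):
    return CellTrack(
        cell_id=cell_id,
        times_s=np.arange(len(masks)) * dt_s,
        masks=[np.asarray(m, bool) for m in masks],
        descriptors=[shape_descriptors(m, spacing) for m in masks],
        pixel_spacing_um=spacing,
    )


def random_blob(rng, shape=(48, 48), n_steps=60):
    """Random connected blob grown by a lattice walk plus thickening."""
    mask = np.zeros(shape, bool)
    pos = np.array([shape[0] // 2, shape[1] // 2])
    for _ in range(n_steps):
        mask[pos[0], pos[1]] = True
        pos = pos + rng.integers(-1, 2, size=2)
        pos = np.clip(pos, 1, np.array(shape) - 2)
    # thicken so the blob has area
    out = mask.copy()
    out[1:, :] |= mask[:-1, :]
    out[:, 1:] |= mask[:, :-1]
    return out


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def pixel_set(mask):
    return {(int(r), int(c)) for r, c in zip(*np.nonzero(mask))}


def oracle_shape_difference(mask_now, mask_prev):
    now, prev = pixel_set(mask_now), pixel_set(mask_prev)
    return now - prev, prev - now


def oracle_activity(masks):
    """Mean over steps of (|gained| + |lost|) / |current|, by set enumeration."""
    vals = []
    for i in range(1, len(masks)):
        gained, lost = oracle_shape_difference(masks[i], masks[i - 1])
        vals.append((len(gained) + len(lost)) / len(pixel_set(masks[i])))
    return sum(vals) / len(vals)


def oracle_boundary_distances(mask, center_um, radius_um, spacing):
    import math

    front = math.inf
    rear = -math.inf
    rows, cols = [], []
    for r, c in pixel_set(mask):
        rows.append(r)
        cols.append(c)
        d = abs(
            math.hypot(r * spacing - center_um[0], c * spacing - center_um[1])
            - radius_um
        )
        front = min(front, d)
        rear = max(rear, d)
    cr = sum(rows) / len(rows) * spacing
    cc = sum(cols) / len(cols) * spacing
    cd = abs(math.hypot(cr - center_um[0], cc - center_um[1]) - radius_um)
    return front, cd, rear


def oracle_escape_times(masks, times, center_um, radius_um, spacing):
    import math

    t_front = t_complete = None
    for mask, t in zip(masks, times):
        outside = [
            math.hypot(r * spacing - center_um[0], c * spacing - center_um[1])
            > radius_um
            for r, c in pixel_set(mask)
        ]
        if t_front is None and any(outside):
            t_front = float(t)
        if t_complete is None and all(outside):
            t_complete = float(t)
    return t_front, t_complete


def oracle_mannwhitney(x, y):
    """Exact two-sided Mann-Whitney by enumerating all labelings."""
    from itertools import combinations

    x = list(x)
    y = list(y)
    pooled = x + y
    n_x = len(x)

    def u_stat(xs, ys):
        return sum(1 for xi in xs for yi in ys if xi > yi) + 0.5 * sum(
            1 for xi in xs for yi in ys if xi == yi
        )

    u_obs = u_stat(x, y)
    mean_u = n_x * len(y) / 2.0
    dev_obs = abs(u_obs - mean_u)
    count = total = 0
    for idx in combinations(range(len(pooled)), n_x):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(xs, ys) - mean_u) >= dev_obs - 1e-12:
            count += 1
    return u_obs, count / total
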