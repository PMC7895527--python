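"""Per-mask shape descriptors.

Every downstream analysis (QC filtering, blebbing activity normalisation,
escape-assay elongation) consumes the same set of descriptors computed from a
single binary mask: centroid, projected area, perimeter, moment-equivalent
ellipse axes, aspect ratio and circularity.

Conventions
-----------
* Pixel indices are 0-based ``(row, col)``; the centre of pixel ``(i, j)``
  sits at physical coordinate ``(i, j) * spacing`` µm, y pointing down.
* The long/short axes come from the ellipse with the same second central
  moments as the mask (axis length ``4 * sqrt(eigenvalue)`` of the normalised
  covariance), matching automated long/short-axis detection on segmented
  cells; aspect ratio = long / short ≥ 1.
* The perimeter uses the 4-direction Crofton estimator
  (:func:`skimage.measure.perimeter_crofton`), which keeps the circularity
  ``4πA/P²`` of a rasterised disc within a few percent of 1.  Circularity
  thresholds (e.g. the 0.7 QC cut) are defined relative to this estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure

__all__ = ["ShapeDescriptor", "shape_descriptors"]

#: slack allowed above 1 for the circularity of near-circular rasterised masks
CIRCULARITY_EPS = 0.05


@dataclass(frozen=True)
class ShapeDescriptor:
    """Shape measurements of a single connected binary mask."""

    centroid_um: tuple[float, float]  # (row, col) in µm
    area_um2: float
    projected_area_px: int
    perimeter_um: float
    long_axis_um: float
    short_axis_um: float
    orientation_rad: float  # major-axis direction from the row axis, in [0, π)
    aspect_ratio: float  # long / short, ≥ 1
    circularity: float  # 4πA / P² (unitless, computed in pixel units)


def shape_descriptors(mask: np.ndarray, spacing_um: float) -> ShapeDescriptor:
    """Compute :class:`ShapeDescriptor` for one connected component.

    Parameters
    ----------
    mask
        2-D boolean array with a single 8-connected foreground component.
    spacing_um
        Pixel spacing in µm.

    Raises
    ------
    ValueError
        If the mask is empty or has more than one 8-connected component
        (take the largest component explicitly before calling).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not mask.any():
        raise ValueError("mask is empty")
    labeled, n_comp = measure.label(mask, connectivity=2, return_num=True)
    if n_comp != 1:
        raise ValueError(
            f"mask has {n_comp} connected components; expected exactly one"
        )
    prop = measure.regionprops(labeled)[0]

    area_px = int(prop.area)
    perimeter_px = float(measure.perimeter_crofton(mask, directions=4))
    centroid = (float(prop.centroid[0]) * spacing_um, float(prop.centroid[1]) * spacing_um)

    long_px = float(prop.axis_major_length)
    short_px = float(prop.axis_minor_length)
    if short_px > 0:
        aspect = long_px / short_px
    elif long_px > 0:
        aspect = math.inf
    else:  # single pixel / degenerate: treat as round
        aspect = 1.0
    # regionprops orientation is in (-π/2, π/2] relative to the row axis
    orientation = float(prop.orientation) % math.pi

    circularity = 4.0 * math.pi * area_px / perimeter_px**2 if perimeter_px > 0 else 0.0

    return ShapeDescriptor(
        centroid_um=centroid,
        area_um2=area_px * spacing_um**2,
        projected_area_px=area_px,
        perimeter_um=perimeter_px * spacing_um,
        long_axis_um=long_px * spacing_um,
        short_axis_um=short_px * spacing_um,
        orientation_rad=orientation,
        aspect_ratio=aspect,
        circularity=circularity,
    )
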