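"""Morphometric descriptors and volumetric estimators for gel-bead colonies.

Colonies growing inside agarose microbeads are treated as ellipsoids whose 2D
microscope projection is an ellipse with a major and a minor axis.  From the
projected (area, perimeter, axes) this module derives:

* circularity       C  = 4π·area / perimeter²           (1 for a circle)
* aspect ratio      AR = major / minor                   (≥ 1)
* colony volume     V  = (4/3)π·(major/2)·(minor/2)²     (prolate spheroid)
* generations       G  = log2(V_colony / V_cell)
* bead occupancy    O  = n_strain · V_colony / V_bead · 100 %
* population size   N  = Σ_strain n_strain · V_strain / V_cell

All scalar functions accept numpy arrays and broadcast.  An optional mask
rasterizer / measurer (scikit-image) exists so that the descriptor pipeline can
be exercised on synthetic pixel masks the way the study measured microscope
images.
"""

from __future__ import annotations

import math
import warnings
from typing import NamedTuple

import numpy as np

#: volume of a typical E. coli cell, μm³
V_ECOLI_UM3 = 1.3
#: default gel-bead volume, 240 nL expressed in μm³ (1 nL = 1e6 μm³)
V_BEAD_UM3 = 240.0 * 1e6

NL_TO_UM3 = 1e6


class ColonyShape(NamedTuple):
    """Single-time-point morphometric record of one colony (all in μm / μm²)."""

    area: float
    perimeter: float
    major_axis: float
    minor_axis: float


def _require_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if np.any(np.asarray(value) <= 0):
            raise ValueError(f"{name} must be positive, got {value!r}")


def circularity(area, perimeter):
    """4π·area/perimeter²: 1.0 for a perfect circle, → 0 for slivers.

    Values slightly above 1 can occur for rasterized masks (the digital
    perimeter estimator underestimates smooth contours); a warning is emitted
    but the raw value is returned unclipped.
    """
    _require_positive(area=area, perimeter=perimeter)
    c = 4.0 * np.pi * np.asarray(area, dtype=float) / np.asarray(perimeter, dtype=float) ** 2
    if np.any(c > 1.0 + 1e-12):
        warnings.warn("circularity exceeds 1 (rasterization artifact)", stacklevel=2)
    return c if np.ndim(c) else float(c)


def aspect_ratio(major_axis, minor_axis):
    """Fitted-ellipse aspect ratio, major/minor (dimensionless, ≥ 1)."""
    _require_positive(major_axis=major_axis, minor_axis=minor_axis)
    ar = np.asarray(major_axis, dtype=float) / np.asarray(minor_axis, dtype=float)
    return ar if np.ndim(ar) else float(ar)


def aspect_ratio_from_area(area, minor_axis):
    """Alternate aspect-ratio form, area/(π·(minor/2)²).

    Identical to ``aspect_ratio`` for an exact ellipse (area = π·a·b/4 with
    axes a ≥ b); exposed so mask-based measurements can cross-check the two.
    """
    _require_positive(area=area, minor_axis=minor_axis)
    ar = np.asarray(area, dtype=float) / (np.pi * (np.asarray(minor_axis, dtype=float) / 2.0) ** 2)
    return ar if np.ndim(ar) else float(ar)


def colony_volume(major_axis, minor_axis):
    """Prolate-spheroid colony volume (4/3)π·(major/2)·(minor/2)², μm³."""
    _require_positive(major_axis=major_axis, minor_axis=minor_axis)
    v = (4.0 / 3.0) * np.pi * (np.asarray(major_axis, float) / 2.0) * (np.asarray(minor_axis, float) / 2.0) ** 2
    return v if np.ndim(v) else float(v)


def colony_volume_from_area(area, ar):
    """Colony volume from projected area and aspect ratio only.

    V = (π/6)·AR·(4·area/(π·AR))^{3/2}; algebraically identical to
    :func:`colony_volume` for a self-consistent ellipse.
    """
    _require_positive(area=area, ar=ar)
    area = np.asarray(area, dtype=float)
    ar = np.asarray(ar, dtype=float)
    v = (np.pi / 6.0) * ar * (4.0 * area / (np.pi * ar)) ** 1.5
    return v if np.ndim(v) else float(v)


def generations(v_colony, v_cell=V_ECOLI_UM3):
    """Number of doublings implied by colony volume, log2(V_colony/V_cell).

    Real-valued; use :func:`generations_floor` for the integer count (a
    partially completed doubling is not counted).
    """
    _require_positive(v_colony=v_colony, v_cell=v_cell)
    g = np.log2(np.asarray(v_colony, dtype=float) / v_cell)
    return g if np.ndim(g) else float(g)


def generations_floor(v_colony, v_cell=V_ECOLI_UM3):
    """Integer generation count, floor(log2(V_colony/V_cell))."""
    g = np.floor(generations(v_colony, v_cell))
    return g.astype(int) if np.ndim(g) else int(g)


def occupancy(v_colony, n=2, v_bead_um3=V_BEAD_UM3, n_strain=None):
    """Per-strain volumetric occupancy of the bead, in percent.

    ``n`` is the total inoculum per bead; at the study's 1:1 ratio each strain
    contributes n/2 founders, each growing one colony of volume ``v_colony``.
    Pass ``n_strain`` to override the per-strain founder count directly.
    A colony volume exceeding the bead volume is physically impossible and
    triggers a warning, but the value is still computed.
    """
    _require_positive(v_bead_um3=v_bead_um3)
    if np.any(np.asarray(v_colony) < 0):
        raise ValueError("v_colony must be nonnegative")
    founders = (n / 2.0) if n_strain is None else n_strain
    if np.any(np.asarray(v_colony) > v_bead_um3):
        warnings.warn("colony volume exceeds bead volume", stacklevel=2)
    o = founders * np.asarray(v_colony, dtype=float) / v_bead_um3 * 100.0
    return o if np.ndim(o) else float(o)


class PopulationEstimate(NamedTuple):
    total: float
    n_b: float
    n_y: float


def population_estimate(v_colony_b, v_colony_y, n=2, v_cell=V_ECOLI_UM3,
                        n_b=None, n_y=None) -> PopulationEstimate:
    """Total cells per bead from per-strain colony volumes.

    N = n_B·V_B/V_cell + n_Y·V_Y/V_cell with n_B = n_Y = n/2 by default
    (1:1 inoculation).  Returns the total and the per-strain components.
    """
    _require_positive(v_cell=v_cell)
    if np.any(np.asarray(v_colony_b) < 0) or np.any(np.asarray(v_colony_y) < 0):
        raise ValueError("colony volumes must be nonnegative")
    fb = (n / 2.0) if n_b is None else n_b
    fy = (n / 2.0) if n_y is None else n_y
    cells_b = fb * np.asarray(v_colony_b, dtype=float) / v_cell
    cells_y = fy * np.asarray(v_colony_y, dtype=float) / v_cell
    total = cells_b + cells_y
    if np.ndim(total):
        return PopulationEstimate(total, cells_b, cells_y)
    return PopulationEstimate(float(total), float(cells_b), float(cells_y))


# ---------------------------------------------------------------------------
# mask rasterizer / measurer (synthetic counterpart of the image analysis)
# ---------------------------------------------------------------------------

def rasterize_ellipse(major_px: float, minor_px: float, orientation: float = 0.0,
                      pad: int = 4) -> np.ndarray:
    """Boolean pixel mask of a filled ellipse with the given full axes (px)."""
    from skimage.draw import ellipse as _ellipse

    _require_positive(major_px=major_px, minor_px=minor_px)
    if minor_px > major_px:
        raise ValueError("major_px must be >= minor_px")
    half = int(math.ceil(major_px / 2.0)) + pad
    size = 2 * half + 1
    mask = np.zeros((size, size), dtype=bool)
    rr, cc = _ellipse(half, half, major_px / 2.0, minor_px / 2.0,
                      shape=mask.shape, rotation=orientation)
    mask[rr, cc] = True
    return mask


def measure_mask(mask: np.ndarray, pixel_size: float = 1.0) -> ColonyShape:
    """Measure a single-colony mask the way the image pipeline would.

    Area is the pixel count, the perimeter is scikit-image's polygonal contour
    estimator, and the axes are those of the ellipse with the same normalized
    second central moments (the fitted-ellipse convention).
    """
    from skimage.measure import label, regionprops

    labeled = label(mask)
    props = regionprops(labeled)
    if len(props) != 1:
        raise ValueError(f"expected exactly one connected region, found {len(props)}")
    rp = props[0]
    return ColonyShape(
        area=float(rp.area) * pixel_size**2,
        perimeter=float(rp.perimeter) * pixel_size,
        major_axis=float(rp.axis_major_length) * pixel_size,
        minor_axis=float(rp.axis_minor_length) * pixel_size,
    )


def annotate_shapes(table, v_cell=V_ECOLI_UM3, bead_volume_nl=240.0, n=2):
    """Add C, AR, V_colony and G columns to a measurement table.

    Returns a copy of the table with ``circularity``, ``aspect_ratio``,
    ``volume_um3``, ``generations`` and ``occupancy_pct`` columns derived from
    the morphometric columns row by row.
    """
    out = table.copy()
    if len(out) == 0:
        for col in ("circularity", "aspect_ratio", "volume_um3", "generations",
                    "occupancy_pct"):
            out[col] = np.nan
        return out
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        out["circularity"] = circularity(out["area_um2"].to_numpy(),
                                         out["perimeter_um"].to_numpy())
        out["aspect_ratio"] = aspect_ratio(out["major_axis_um"].to_numpy(),
                                           out["minor_axis_um"].to_numpy())
        out["volume_um3"] = colony_volume(out["major_axis_um"].to_numpy(),
                                          out["minor_axis_um"].to_numpy())
        out["generations"] = generations(out["volume_um3"].to_numpy(), v_cell)
        out["occupancy_pct"] = occupancy(out["volume_um3"].to_numpy(), n=n,
                                         v_bead_um3=bead_volume_nl * NL_TO_UM3)
    return out
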