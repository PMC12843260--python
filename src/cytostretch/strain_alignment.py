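"""Spatial correlation of image-derived actin alignment with membrane strain.

Both the FEM strain field and the orientation field are averaged onto a common
coarse grid; per-bin coherency index is then correlated with per-bin maximum
principal strain, and the angular deviation between the mean fiber axis and
the principal strain direction is reported as an axial angle folded to
[0, 90] degrees.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment_stats import alignment_metrics
from .membrane_mechanics import StrainField
from .orientation_analysis import OrientationField

__all__ = [
    "StrainAlignmentRecord",
    "axial_deviation_deg",
    "map_strain_to_image_grid",
    "local_alignment_map",
    "correlate",
]


@dataclass(frozen=True)
class StrainAlignmentRecord:
    bin_center_mm: tuple[float, float]
    local_CI: float
    local_mean_axial_direction_deg: float
    local_max_principal_strain: float
    local_principal_direction_deg: float
    angular_deviation_deg: float


def axial_deviation_deg(theta_a_deg: float, theta_b_deg: float) -> float:
    """Deviation between two axial angles, folded to [0, 90] degrees."""
    d = abs((theta_a_deg - theta_b_deg) % 180.0)
    return min(d, 180.0 - d)


def _bin_edges(extent, n):
    lo, hi = extent
    return np.linspace(lo, hi, n + 1)


def map_strain_to_image_grid(
    field: StrainField, image_extent_mm, grid: tuple[int, int]
) -> dict:
    """Average element strain measures into spatial bins over the image extent.

    ``image_extent_mm`` is ((x_lo, x_hi), (y_lo, y_hi)) in membrane
    coordinates.  Per bin: mean maximum principal engineering strain and the
    axial (doubled-angle) mean of the principal directions.  Empty bins are
    marked missing (NaN) and excluded downstream.
    """
    gx, gy = grid
    if gx < 1 or gy < 1 or (gx * gy) < 1:
        raise ValueError("grid must be at least 1x1")
    (x_lo, x_hi), (y_lo, y_hi) = image_extent_mm
    xe = _bin_edges((x_lo, x_hi), gx)
    ye = _bin_edges((y_lo, y_hi), gy)
    cx = field.element_centroids[:, 0]
    cy = field.element_centroids[:, 1]
    eng = field.max_principal_engineering_strain
    dirs = field.principal_directions_deg

    strain = np.full((gy, gx), np.nan)
    direction = np.full((gy, gx), np.nan)
    for j in range(gy):
        for i in range(gx):
            sel = ((cx >= xe[i]) & (cx < xe[i + 1]) &
                   (cy >= ye[j]) & (cy < ye[j + 1]))
            if not np.any(sel):
                continue
            strain[j, i] = eng[sel].mean()
            doubled = np.deg2rad(2.0 * dirs[sel])
            direction[j, i] = (math.degrees(
                math.atan2(np.sin(doubled).mean(), np.cos(doubled).mean())) / 2.0
            ) % 180.0
    centers_x = 0.5 * (xe[:-1] + xe[1:])
    centers_y = 0.5 * (ye[:-1] + ye[1:])
    return {"strain": strain, "direction_deg": direction,
            "centers_x": centers_x, "centers_y": centers_y}


def local_alignment_map(
    field: OrientationField, grid: tuple[int, int],
    energy_percentile_mask: float = 50.0,
) -> dict:
    """Per-bin alignment metrics (CI, mean axial direction) of an image field.

    The energy mask percentile is taken over the whole image so that bins are
    masked consistently; bins with no retained pixels are missing (NaN).
    A 1x1 grid reproduces the global metrics exactly.
    """
    gx, gy = grid
    if gx < 1 or gy < 1:
        raise ValueError("grid must be at least 1x1")
    rows, cols = field.theta_deg.shape
    cut = np.percentile(field.energy, energy_percentile_mask)
    xe = np.linspace(0, cols, gx + 1).astype(int)
    ye = np.linspace(0, rows, gy + 1).astype(int)
    ci = np.full((gy, gx), np.nan)
    mean_dir = np.full((gy, gx), np.nan)
    for j in range(gy):
        for i in range(gx):
            th = field.theta_deg[ye[j]:ye[j + 1], xe[i]:xe[i + 1]]
            co = field.coherence[ye[j]:ye[j + 1], xe[i]:xe[i + 1]]
            en = field.energy[ye[j]:ye[j + 1], xe[i]:xe[i + 1]]
            keep = en > cut if energy_percentile_mask > 0 else en >= 0
            w = co[keep] * en[keep]
            if w.sum() <= 0:
                continue
            m = alignment_metrics(th[keep], w)
            ci[j, i] = m.coherency_index_CI
            mean_dir[j, i] = m.mean_axial_direction_deg
    return {"CI": ci, "mean_direction_deg": mean_dir}


def correlate(strain_bins: dict, alignment_bins: dict
              ) -> tuple[float, float, pd.DataFrame]:
    """Correlate per-bin CI with per-bin maximum principal strain.

    Returns the Pearson correlation (NaN with an attached note when the strain
    is constant across bins — degenerate by design in uniform fields), the
    mean axial deviation between fiber mean direction and principal strain
    direction, and the per-bin record table.
    """
    strain = strain_bins["strain"]
    sdir = strain_bins["direction_deg"]
    ci = alignment_bins["CI"]
    adir = alignment_bins["mean_direction_deg"]
    if strain.shape != ci.shape:
        raise ValueError("strain and alignment grids must match")
    ok = np.isfinite(strain) & np.isfinite(ci)
    if ok.sum() < 3:
        raise ValueError("need at least 3 matched non-missing bins")

    s = strain[ok]
    c = ci[ok]
    if np.ptp(s) == 0 or np.ptp(c) == 0:
        r = float("nan")  # constant field: correlation undefined by design
    else:
        r = float(np.corrcoef(s, c)[0, 1])

    dev = np.array([
        axial_deviation_deg(a, b)
        for a, b in zip(adir[ok], sdir[ok])
        if np.isfinite(a) and np.isfinite(b)
    ])
    mean_dev = float(dev.mean()) if dev.size else float("nan")

    jj, ii = np.nonzero(ok)
    records = pd.DataFrame({
        "bin_row": jj,
        "bin_col": ii,
        "local_CI": ci[ok],
        "local_mean_axial_direction_deg": adir[ok],
        "local_max_principal_strain": strain[ok],
        "local_principal_direction_deg": sdir[ok],
        "angular_deviation_deg": [
            axial_deviation_deg(a, b) if np.isfinite(a) and np.isfinite(b)
            else np.nan
            for a, b in zip(adir[ok], sdir[ok])
        ],
    })
    return r, mean_dev, records
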