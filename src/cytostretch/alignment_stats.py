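"""Axial circular statistics for fiber-orientation data.

Fiber orientations are axial: an angle ``theta`` and ``theta + 180`` describe
the same fiber.  All statistics therefore operate on doubled angles ``2*theta``,
where the axial data become ordinary circular data.  The central summary is the
coherency index

    CI = 1 - CV_deg / 180,

where the circular variance in degrees is defined as ``CV_deg = (1 - R2) * 180``
and ``R2`` is the mean resultant length of the doubled angles.  With these
definitions CI equals R2 exactly: CI = 1 for a perfectly aligned population and
CI -> 0 for a uniform (random) one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AlignmentMetrics",
    "resultant_and_mean",
    "circular_variance_deg",
    "coherency_index",
    "alignment_metrics",
]


@dataclass(frozen=True)
class AlignmentMetrics:
    """Summary statistics of an axial orientation sample.

    ``mean_axial_direction_deg`` is NaN when the doubled-angle resultant vector
    vanishes (e.g. equal weight at 0 and 90 degrees), in which case the mean
    direction is undefined.
    """

    mean_axial_direction_deg: float
    resultant_length_R2: float
    circular_variance_deg: float
    coherency_index_CI: float
    n: int


def _resultant(angles_deg: np.ndarray, weights: np.ndarray) -> tuple[float, float]:
    doubled = np.deg2rad(2.0 * angles_deg)
    wsum = weights.sum()
    c = float(np.sum(weights * np.cos(doubled)) / wsum)
    s = float(np.sum(weights * np.sin(doubled)) / wsum)
    return c, s


def resultant_and_mean(
    angles_deg=None, weights=None, *, histogram=None
) -> tuple[float, float]:
    """Mean resultant length on doubled angles and the mean axial direction.

    Parameters
    ----------
    angles_deg : array-like
        Axial angles in degrees, interpreted modulo 180.
    weights : array-like, optional
        Nonnegative weights, one per angle.  Defaults to equal weights.
    histogram : AngularHistogram, optional
        Alternative input: bin centers are used as angles, bin weights as
        weights (keyword-only; exclusive with ``angles_deg``).

    Returns
    -------
    (R2, mean_axial_direction_deg)
        ``R2`` in [0, 1]; the mean direction in [0, 180), or NaN when R2 = 0
        (antipodal cancellation on the doubled circle).
    """
    if histogram is not None:
        if angles_deg is not None:
            raise ValueError("pass either angles_deg or histogram, not both")
        edges = np.asarray(histogram.bin_edges_deg, dtype=float)
        angles_deg = 0.5 * (edges[:-1] + edges[1:])
        weights = np.asarray(histogram.weights, dtype=float)
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float)).ravel()
    if angles.size == 0:
        raise ValueError("empty angle sample")
    if weights is None:
        w = np.ones_like(angles)
    else:
        w = np.atleast_1d(np.asarray(weights, dtype=float)).ravel()
        if w.shape != angles.shape:
            raise ValueError("weights must match angles in length")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
    if w.sum() <= 0:
        raise ValueError("at least one nonzero weight required")

    c, s = _resultant(angles, w)
    r2 = math.hypot(c, s)
    r2 = min(r2, 1.0)
    if r2 < 1e-12:
        return 0.0, float("nan")
    mean_deg = math.degrees(math.atan2(s, c)) / 2.0
    return r2, mean_deg % 180.0


def circular_variance_deg(r2: float) -> float:
    """Circular variance expressed in degrees: ``(1 - R2) * 180``."""
    if not 0.0 <= r2 <= 1.0 + 1e-12:
        raise ValueError(f"R2 must lie in [0, 1], got {r2}")
    return (1.0 - min(r2, 1.0)) * 180.0


def coherency_index(cv_deg: float) -> float:
    """Coherency index ``CI = 1 - CV/180`` from a circular variance in degrees.

    CI = 1 indicates perfect alignment; CI = 0 a random orientation
    distribution.  The result is clipped to [0, 1] only against floating-point
    rounding.
    """
    if not 0.0 <= cv_deg <= 180.0 + 1e-9:
        raise ValueError(f"circular variance must lie in [0, 180] degrees, got {cv_deg}")
    return float(np.clip(1.0 - cv_deg / 180.0, 0.0, 1.0))


def alignment_metrics(angles_deg=None, weights=None, *, histogram=None) -> AlignmentMetrics:
    """Full axial summary (R2, circular variance, CI) of a sample or histogram."""
    r2, mean_deg = resultant_and_mean(angles_deg, weights, histogram=histogram)
    cv = circular_variance_deg(r2)
    ci = coherency_index(cv)
    if histogram is not None:
        n = int(np.count_nonzero(histogram.weights))
    else:
        n = int(np.atleast_1d(np.asarray(angles_deg)).size)
    return AlignmentMetrics(
        mean_axial_direction_deg=mean_deg,
        resultant_length_R2=r2,
        circular_variance_deg=cv,
        coherency_index_CI=ci,
        n=n,
    )
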