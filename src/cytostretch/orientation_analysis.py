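"""Local fiber-orientation estimation from fluorescence rasters.

Two estimators are provided, mirroring the two Fiji plugins commonly used for
actin-alignment quantification:

* a structure-tensor route (pixel-wise orientation, coherence and energy from
  the eigenstructure of the smoothed gradient outer product), and
* a Fourier route (angular distribution of spectral power).

The structure-tensor route is the default throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "OrientationField",
    "AngularHistogram",
    "structure_tensor_field",
    "fourier_directionality",
    "histogram_from_field",
]


@dataclass
class OrientationField:
    """Per-pixel fiber angle (deg, [0,180)), coherence in [0,1], and energy.

    ``theta_deg`` is the direction of least intensity variation (the minor
    eigenvector of the structure tensor), i.e. the fiber direction.
    ``coherence`` is the eigenvalue anisotropy (l1-l2)/(l1+l2), zero where the
    tensor vanishes; ``energy`` is the tensor trace l1+l2, so orientation
    estimates at zero-energy pixels carry no information.
    """

    theta_deg: np.ndarray
    coherence: np.ndarray
    energy: np.ndarray

    def __post_init__(self):
        if not (self.theta_deg.shape == self.coherence.shape == self.energy.shape):
            raise ValueError("field rasters must share one shape")


@dataclass
class AngularHistogram:
    """Normalized histogram of axial fiber angles over [0, 180] degrees."""

    bin_edges_deg: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges_deg, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if edges.size != w.size + 1 or np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges_deg must be a monotone partition with one "
                             "more edge than weights")
        if np.any(w < 0):
            raise ValueError("weights must be nonnegative")
        total = w.sum()
        if total > 0:
            w = w / total
        object.__setattr__(self, "bin_edges_deg", edges)
        object.__setattr__(self, "weights", w)

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:])

    def modal_angle_deg(self) -> float:
        # ties resolve to the lowest-angle bin
        return float(self.bin_centers_deg[int(np.argmax(self.weights))])

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "bin_start_deg": self.bin_edges_deg[:-1],
            "bin_end_deg": self.bin_edges_deg[1:],
            "weight": self.weights,
        }).to_csv(path, index=False)


def structure_tensor_field(
    image: np.ndarray,
    sigma_gradient_um: float = 0.65,
    sigma_window_um: float = 2.6,
    pixel_size_um: float = 0.65,
) -> OrientationField:
    """Pixel-wise orientation, coherence and energy from the structure tensor.

    Gradients are Gaussian derivatives at scale ``sigma_gradient_um``; the
    tensor components Jxx, Jxy, Jyy are then smoothed with a Gaussian window
    at scale ``sigma_window_um`` (both converted to pixels).  The fiber angle
    is the orientation of the minor eigenvector — intensity varies least along
    a fiber — reported in [0, 180) degrees in (x=column, y=row) coordinates.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 16:
        raise ValueError("image must be 2-D and at least 16x16 px")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite pixels")
    if sigma_gradient_um <= 0 or sigma_window_um <= 0 or pixel_size_um <= 0:
        raise ValueError("scales and pixel size must be positive")

    sg = sigma_gradient_um / pixel_size_um
    sw = sigma_window_um / pixel_size_um
    # axis 0 = rows = y, axis 1 = cols = x
    gy = ndimage.gaussian_filter(img, sg, order=(1, 0), mode="nearest")
    gx = ndimage.gaussian_filter(img, sg, order=(0, 1), mode="nearest")
    jxx = ndimage.gaussian_filter(gx * gx, sw, mode="nearest")
    jxy = ndimage.gaussian_filter(gx * gy, sw, mode="nearest")
    jyy = ndimage.gaussian_filter(gy * gy, sw, mode="nearest")

    trace = jxx + jyy
    # major eigenvector (gradient direction) at 0.5*atan2(2Jxy, Jxx-Jyy);
    # the fiber lies along the minor eigenvector, 90 deg away
    theta = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy) + np.pi / 2.0
    theta_deg = np.rad2deg(theta) % 180.0

    disc = np.sqrt((jxx - jyy) ** 2 + 4.0 * jxy**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        coherence = np.where(trace > 0, disc / trace, 0.0)
    coherence = np.clip(coherence, 0.0, 1.0)
    return OrientationField(theta_deg=theta_deg, coherence=coherence, energy=trace)


def fourier_directionality(image: np.ndarray, n_bins: int = 90) -> AngularHistogram:
    """Angular histogram of fiber orientations from the 2-D power spectrum.

    The image is Hann-windowed, the DC component excluded, and spectral power
    binned by the polar angle of the frequency coordinates.  Because the
    spectrum of a line concentrates perpendicular to the line, the spectral
    angles are rotated by 90 degrees to give fiber angles.  Weights sum to 1.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2 or min(img.shape) < 32:
        raise ValueError("image must be 2-D and at least 32x32 px")
    if n_bins < 8:
        raise ValueError("n_bins must be >= 8")

    rows, cols = img.shape
    win = np.outer(np.hanning(rows), np.hanning(cols))
    spec = np.abs(np.fft.fftshift(np.fft.fft2((img - img.mean()) * win))) ** 2

    fy, fx = np.meshgrid(
        np.fft.fftshift(np.fft.fftfreq(rows)),
        np.fft.fftshift(np.fft.fftfreq(cols)),
        indexing="ij",
    )
    radius = np.hypot(fx, fy)
    valid = radius > 0  # exclude DC
    # spectral angle -> fiber angle: a ridge along theta has its wave vector
    # at theta + 90, so rotate spectral angles by 90 deg (mod 180)
    ang = (np.rad2deg(np.arctan2(fy, fx)) + 90.0) % 180.0

    edges = np.linspace(0.0, 180.0, n_bins + 1)
    idx = np.clip(np.digitize(ang[valid], edges) - 1, 0, n_bins - 1)
    weights = np.bincount(idx, weights=spec[valid], minlength=n_bins)
    return AngularHistogram(bin_edges_deg=edges, weights=weights)


def histogram_from_field(
    field: OrientationField,
    n_bins: int = 90,
    energy_percentile_mask: float = 50.0,
) -> AngularHistogram:
    """Coherence- and energy-weighted angular histogram of an orientation field.

    Pixels with energy below the given percentile are excluded (the
    tensor-native analogue of thresholding before orientation extraction);
    each remaining pixel contributes weight coherence*energy to its angle bin.
    """
    if not 0 <= energy_percentile_mask < 100:
        raise ValueError("energy percentile must lie in [0, 100)")
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    cut = np.percentile(field.energy, energy_percentile_mask)
    keep = field.energy > cut if energy_percentile_mask > 0 else field.energy >= 0
    if not np.any(keep):
        raise ValueError("energy mask removed all pixels")
    w = field.coherence[keep] * field.energy[keep]
    theta = field.theta_deg[keep] % 180.0
    edges = np.linspace(0.0, 180.0, n_bins + 1)
    idx = np.clip(np.digitize(theta, edges) - 1, 0, n_bins - 1)
    weights = np.bincount(idx, weights=w, minlength=n_bins)
    if weights.sum() <= 0:
        raise ValueError("all masked pixels carry zero weight")
    return AngularHistogram(bin_edges_deg=edges, weights=weights)
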