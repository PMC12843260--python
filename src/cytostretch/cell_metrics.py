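"""F-actin intensity and nuclei-density quantification.

Implements the per-image measurement chain used for the condition
comparisons: morphological background subtraction, Otsu thresholding, mean
foreground intensity normalized to the control batch, and nuclei counting
with an area gate of 50-500 um^2 (excluding debris below and merged /
overlapping nuclei above the gate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure, morphology
from skimage.filters import threshold_otsu

__all__ = [
    "IntensityMetrics",
    "DensityMetrics",
    "subtract_background",
    "mean_foreground_intensity",
    "normalize_intensity",
    "segment_nuclei",
    "relative_density",
]


@dataclass(frozen=True)
class IntensityMetrics:
    mean_foreground_intensity: float
    normalized_intensity_Inorm: float


@dataclass(frozen=True)
class DensityMetrics:
    nuclei_count: int
    nuclei_per_mm2: float
    relative_density: float


def subtract_background(
    image: np.ndarray, radius_um: float = 25.0, pixel_size_um: float = 0.65
) -> np.ndarray:
    """Remove smooth background by grayscale opening with a disk.

    The opening (erosion then dilation) with a disk larger than any fiber
    estimates the background; the result is image minus background, floored
    at zero.  The disk radius must exceed one pixel and should be much larger
    than the fiber width.
    """
    img = np.asarray(image, dtype=float)
    radius_px = int(round(radius_um / pixel_size_um))
    if radius_px < 1:
        raise ValueError("background radius below one pixel")
    footprint = morphology.disk(radius_px, decomposition="sequence")
    background = morphology.opening(img, footprint)
    return np.clip(img - background, 0.0, None)


def mean_foreground_intensity(image: np.ndarray, threshold_method: str = "otsu") -> float:
    """Mean intensity of pixels strictly above an Otsu threshold.

    The threshold is computed on the supplied (background-subtracted) image;
    only Otsu is supported so that thresholding is consistent across samples.
    """
    img = np.asarray(image, dtype=float)
    if img.std() == 0:
        raise ValueError("image has zero variance; no threshold exists")
    if threshold_method != "otsu":
        raise ValueError(f"unsupported threshold method {threshold_method!r}")
    thresh = threshold_otsu(img)
    fg = img[img > thresh]
    if fg.size == 0:
        raise ValueError("empty foreground after thresholding")
    return float(fg.mean())


def normalize_intensity(i_condition: float, i_control: float) -> float:
    """Normalized intensity Inorm = I_condition / I_control."""
    if i_control <= 0:
        raise ValueError("control mean intensity must be positive")
    return i_condition / i_control


def segment_nuclei(
    image: np.ndarray,
    pixel_size_um: float,
    min_area_um2: float = 50.0,
    max_area_um2: float = 500.0,
) -> tuple[int, np.ndarray, np.ndarray]:
    """Count nuclei by Otsu thresholding, labeling and an area gate.

    Connected components (8-connectivity) of the thresholded nuclei channel
    are measured in um^2; components outside [min_area_um2, max_area_um2]
    (boundaries inclusive) are discarded — small debris below, merged or
    overlapping nuclei above.  Returns the retained count, the gated label
    raster, and the retained areas.
    """
    img = np.asarray(image, dtype=float)
    if pixel_size_um <= 0:
        raise ValueError("pixel_size_um must be positive")
    if img.std() == 0:
        raise ValueError("constant nuclei channel; segmentation undefined")
    mask = img > threshold_otsu(img)
    labels = measure.label(mask, connectivity=2)
    px_area = pixel_size_um**2
    areas_px = np.bincount(labels.ravel())[1:]  # skip background label 0
    areas_um2 = areas_px * px_area
    keep = (areas_um2 >= min_area_um2) & (areas_um2 <= max_area_um2)
    keep_labels = np.flatnonzero(keep) + 1
    gated = np.where(np.isin(labels, keep_labels), labels, 0)
    return int(keep.sum()), gated, areas_um2[keep]


def relative_density(
    count_condition: float, count_control: float,
    area_condition_mm2: float = 1.0, area_control_mm2: float = 1.0,
) -> float:
    """Ratio of per-area nuclei counts, condition over control."""
    if count_control <= 0:
        raise ValueError("control nuclei count must be positive")
    if area_condition_mm2 <= 0 or area_control_mm2 <= 0:
        raise ValueError("areas must be positive")
    return (count_condition / area_condition_mm2) / (count_control / area_control_mm2)
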