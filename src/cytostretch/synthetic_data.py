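"""Synthetic two-channel fluorescence micrographs with known ground truth.

The generator emulates the statistical structure of confocal images of
phalloidin-stained F-actin (oriented fibers) and DAPI-stained nuclei
(elliptical blobs) from mesenchymal stem cells under cyclic stretch.  Fiber
axial angles are drawn from a doubled-angle von Mises model so that the
population coherency index is controlled exactly; nuclei counts and areas are
controlled so that density and intensity ratios between experimental
conditions are known by construction.

Angle convention: an angle of 0 degrees is a horizontal fiber (along image
columns), increasing counterclockwise in (x=column, y=row) coordinates;
angles are axial, i.e. taken modulo 180.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "OrientationDistribution",
    "FiberFieldSpec",
    "NucleiFieldSpec",
    "ConditionPreset",
    "GroundTruth",
    "SyntheticImage",
    "CONDITION_PRESETS",
    "sample_axial_angles",
    "render_fibers",
    "render_nuclei",
    "generate_condition",
    "write_synthetic",
    "read_image",
]


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #

@dataclass(frozen=True)
class OrientationDistribution:
    """Axial orientation law for fiber angles in [0, 180) degrees.

    ``axial_von_mises`` means the doubled angles 2*theta follow a von Mises
    law with mean 2*mu_deg and concentration kappa; kappa = 0 reduces to the
    uniform law.  The population mean resultant length on doubled angles is
    the Bessel ratio I1(kappa)/I0(kappa), which equals the population
    coherency index under the doubled-angle circular-variance definition.
    """

    kind: str = "uniform"  # "uniform" | "axial_von_mises"
    mu_deg: float = 90.0
    kappa: float = 0.0

    def __post_init__(self):
        if self.kind not in ("uniform", "axial_von_mises"):
            raise ValueError(f"unknown orientation kind {self.kind!r}")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        object.__setattr__(self, "mu_deg", float(self.mu_deg) % 180.0)


@dataclass(frozen=True)
class FiberFieldSpec:
    """Geometry and photometry of the synthetic F-actin channel."""

    image_shape_px: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.65
    n_fibers: int = 300
    fiber_length_um: tuple[float, float] = (40.0, 10.0)  # mean, sd
    fiber_width_um: float = 1.5  # full width (FWHM of the Gaussian profile)
    fiber_amplitude: float = 1000.0
    background_level: float = 100.0
    noise_sd: float = 50.0

    def __post_init__(self):
        if min(self.image_shape_px) < 1 or self.pixel_size_um <= 0:
            raise ValueError("image shape and pixel size must be positive")
        if self.fiber_length_um[0] <= 0 or self.fiber_width_um <= 0:
            raise ValueError("fiber dimensions must be positive")
        if not (self.fiber_amplitude > self.background_level >= 0):
            raise ValueError("require amplitude > background >= 0")
        if self.noise_sd < 0 or self.n_fibers < 0:
            raise ValueError("noise_sd and n_fibers must be nonnegative")


@dataclass(frozen=True)
class NucleiFieldSpec:
    """Geometry and photometry of the synthetic nuclei (DAPI) channel."""

    image_shape_px: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.65
    n_nuclei: int = 80
    area_um2: tuple[float, float] = (160.0, 40.0)  # mean, sd of ellipse area
    eccentricity_range: tuple[float, float] = (0.0, 0.8)
    amplitude: float = 800.0
    background_level: float = 50.0
    noise_sd: float = 40.0

    def __post_init__(self):
        mean_area = self.area_um2[0]
        if not 0 < mean_area <= 5000:
            raise ValueError("mean nucleus area must lie in (0, 5000] um^2")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        lo, hi = self.eccentricity_range
        if not (0 <= lo <= hi < 1):
            raise ValueError("eccentricity range must lie in [0, 1)")
        if not (self.amplitude > self.background_level >= 0) or self.noise_sd < 0:
            raise ValueError("require amplitude > background >= 0 and noise_sd >= 0")


@dataclass(frozen=True)
class ConditionPreset:
    """Named generator settings for one experimental group.

    Multipliers are expressed relative to the unstimulated control; the
    control preset has unit multipliers and a near-random orientation law.
    """

    name: str
    orientation: OrientationDistribution
    intensity_multiplier: float = 1.0
    nuclei_multiplier: float = 1.0

    def __post_init__(self):
        if self.intensity_multiplier <= 0 or self.nuclei_multiplier <= 0:
            raise ValueError("preset multipliers must be > 0")


# Concentrations solve I1(k)/I0(k) = R for the coherency indices of the three
# experimental groups (R = 0.25, 0.85, 0.60); intensity and nuclei multipliers
# mirror the reported per-condition ratios.
CONDITION_PRESETS: dict[str, ConditionPreset] = {
    "control": ConditionPreset(
        name="control",
        orientation=OrientationDistribution("axial_von_mises", mu_deg=90.0, kappa=0.515),
        intensity_multiplier=1.0,
        nuclei_multiplier=1.0,
    ),
    "stretch_0p5Hz_10pct": ConditionPreset(
        name="stretch_0p5Hz_10pct",
        orientation=OrientationDistribution("axial_von_mises", mu_deg=90.0, kappa=3.64),
        intensity_multiplier=1.5,
        nuclei_multiplier=1.5,
    ),
    "stretch_2p5Hz_1pct": ConditionPreset(
        name="stretch_2p5Hz_1pct",
        orientation=OrientationDistribution("axial_von_mises", mu_deg=90.0, kappa=1.52),
        intensity_multiplier=1.2,
        nuclei_multiplier=1.3,
    ),
}


@dataclass
class GroundTruth:
    fiber_angles_deg: np.ndarray = field(default_factory=lambda: np.empty(0))
    nuclei_centroids_px: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    nuclei_areas_um2: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class SyntheticImage:
    """Two-channel synthetic micrograph plus generation record."""

    actin_channel: np.ndarray
    nuclei_channel: np.ndarray
    pixel_size_um: float
    ground_truth: GroundTruth | None = None
    seed: int | None = None
    preset: str | None = None

    def __post_init__(self):
        if self.actin_channel.shape != self.nuclei_channel.shape:
            raise ValueError("channels must share one shape")


# --------------------------------------------------------------------------- #
# sampling and rendering
# --------------------------------------------------------------------------- #

def sample_axial_angles(dist: OrientationDistribution, n: int, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. axial angles in [0, 180) degrees.

    For the axial von Mises law the doubled angles 2*theta are drawn from
    von Mises(2*mu, kappa) and halved; kappa = 0 (or kind='uniform') yields
    the uniform law on [0, 180).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if dist.kind == "uniform" or dist.kappa == 0:
        return rng.uniform(0.0, 180.0, size=n)
    doubled = rng.vonmises(np.deg2rad(2.0 * dist.mu_deg), dist.kappa, size=n)
    return (np.rad2deg(doubled) / 2.0) % 180.0


def _gaussian_ridge_sigma_px(spec: FiberFieldSpec) -> float:
    # full width interpreted as FWHM of the transverse Gaussian profile
    return spec.fiber_width_um / spec.pixel_size_um / 2.355


def render_fibers(spec: FiberFieldSpec, angles_deg, seed) -> np.ndarray:
    """Render fibers as anti-aliased ridge segments on a noisy background.

    Each fiber is a line segment with a Gaussian transverse intensity profile
    (FWHM = ``fiber_width_um``), centered at a uniformly random position, with
    length drawn from the spec's normal law.  Fibers add; background and
    Gaussian read noise are added last and the result is clipped at zero.
    """
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if angles.size == 0:
        raise ValueError("angles must be nonempty (use n_fibers=0 spec path instead)")
    rng = np.random.default_rng(seed)
    rows, cols = spec.image_shape_px
    img = np.zeros((rows, cols), dtype=float)
    sigma = _gaussian_ridge_sigma_px(spec)
    pad = 3.0 * sigma + 1.0
    diag_px = float(np.hypot(rows, cols))
    mean_l, sd_l = spec.fiber_length_um

    lengths_px = rng.normal(mean_l, sd_l, size=angles.size) / spec.pixel_size_um
    lengths_px = np.clip(lengths_px, 2.0, None)
    if np.any(lengths_px > diag_px):
        warnings.warn("fiber longer than image diagonal; truncating", stacklevel=2)
        lengths_px = np.minimum(lengths_px, diag_px)
    centers = rng.uniform([0, 0], [cols, rows], size=(angles.size, 2))  # (x, y)

    theta = np.deg2rad(angles)
    dvec = np.stack([np.cos(theta), np.sin(theta)], axis=1)
    p0 = centers - 0.5 * lengths_px[:, None] * dvec
    p1 = centers + 0.5 * lengths_px[:, None] * dvec

    for a, b in zip(p0, p1):
        x_lo = int(max(0, np.floor(min(a[0], b[0]) - pad)))
        x_hi = int(min(cols, np.ceil(max(a[0], b[0]) + pad) + 1))
        y_lo = int(max(0, np.floor(min(a[1], b[1]) - pad)))
        y_hi = int(min(rows, np.ceil(max(a[1], b[1]) + pad) + 1))
        if x_lo >= x_hi or y_lo >= y_hi:
            continue
        xs = np.arange(x_lo, x_hi, dtype=float)
        ys = np.arange(y_lo, y_hi, dtype=float)
        px, py = np.meshgrid(xs, ys)
        v = b - a
        vv = float(v @ v)
        t = np.clip(((px - a[0]) * v[0] + (py - a[1]) * v[1]) / vv, 0.0, 1.0)
        dx = px - (a[0] + t * v[0])
        dy = py - (a[1] + t * v[1])
        d2 = dx * dx + dy * dy
        img[y_lo:y_hi, x_lo:x_hi] += spec.fiber_amplitude * np.exp(-d2 / (2.0 * sigma**2))

    img += spec.background_level
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def render_background_only(spec: FiberFieldSpec, seed) -> np.ndarray:
    """Fiber-free raster: background plus noise, clipped at zero."""
    rng = np.random.default_rng(seed)
    img = np.full(spec.image_shape_px, spec.background_level, dtype=float)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(img, 0.0, None)


def render_nuclei(spec: NucleiFieldSpec, seed) -> tuple[np.ndarray, GroundTruth]:
    """Render non-overlapping filled ellipses emulating DAPI-stained nuclei.

    Placement is best-effort: each nucleus gets up to 100 rejection retries
    (circle-overlap test on the major semi-axes, fully inside the frame); if a
    position cannot be found the nucleus is dropped with a warning and the
    ground truth records the realized count.  Realized areas are measured on
    the rendered noise-free mask in um^2.
    """
    rng = np.random.default_rng(seed)
    rows, cols = spec.image_shape_px
    px_area = spec.pixel_size_um**2
    mask_img = np.zeros((rows, cols), dtype=bool)

    centroids: list[tuple[float, float]] = []
    areas: list[float] = []
    placed: list[tuple[float, float, float]] = []  # (cx, cy, a_px)

    for _ in range(spec.n_nuclei):
        area_um2 = max(rng.normal(*spec.area_um2), 1.0)
        ecc = rng.uniform(*spec.eccentricity_range)
        phi = rng.uniform(0.0, np.pi)
        flat = np.sqrt(1.0 - ecc**2)
        a_px = np.sqrt(area_um2 / px_area / (np.pi * flat))
        b_px = a_px * flat

        ok = False
        for _try in range(100):
            cx = rng.uniform(a_px + 1, cols - a_px - 1)
            cy = rng.uniform(a_px + 1, rows - a_px - 1)
            if all((cx - ox) ** 2 + (cy - oy) ** 2 > (a_px + oa + 2.0) ** 2
                   for ox, oy, oa in placed):
                ok = True
                break
        if not ok:
            warnings.warn("could not place all requested nuclei; placing fewer",
                          stacklevel=2)
            continue

        x_lo = int(max(0, np.floor(cx - a_px - 1)))
        x_hi = int(min(cols, np.ceil(cx + a_px + 2)))
        y_lo = int(max(0, np.floor(cy - a_px - 1)))
        y_hi = int(min(rows, np.ceil(cy + a_px + 2)))
        xs, ys = np.meshgrid(np.arange(x_lo, x_hi), np.arange(y_lo, y_hi))
        dx = xs - cx
        dy = ys - cy
        u = (dx * np.cos(phi) + dy * np.sin(phi)) / a_px
        v = (-dx * np.sin(phi) + dy * np.cos(phi)) / b_px
        ell = u * u + v * v <= 1.0
        realized_px = int(ell.sum())
        if realized_px == 0:
            continue
        mask_img[y_lo:y_hi, x_lo:x_hi] |= ell
        placed.append((cx, cy, a_px))
        centroids.append((cx, cy))
        areas.append(realized_px * px_area)

    img = np.full((rows, cols), spec.background_level, dtype=float)
    img[mask_img] += spec.amplitude
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)

    gt = GroundTruth(
        nuclei_centroids_px=np.asarray(centroids, dtype=float).reshape(-1, 2),
        nuclei_areas_um2=np.asarray(areas, dtype=float),
    )
    return img, gt


def generate_condition(
    preset: ConditionPreset | str,
    base_actin: FiberFieldSpec | None = None,
    base_nuclei: NucleiFieldSpec | None = None,
    seed: int = 0,
) -> SyntheticImage:
    """Generate one two-channel image for a named experimental condition.

    The preset's orientation law replaces the base law, its intensity
    multiplier scales the fiber amplitude, and its nuclei multiplier scales
    the nucleus count (rounded).  All randomness derives from ``seed``.
    """
    if isinstance(preset, str):
        try:
            preset = CONDITION_PRESETS[preset]
        except KeyError:
            raise KeyError(
                f"unknown preset {preset!r}; valid presets: "
                f"{sorted(CONDITION_PRESETS)}"
            ) from None
    base_actin = base_actin or FiberFieldSpec()
    base_nuclei = base_nuclei or NucleiFieldSpec()

    actin_spec = replace(
        base_actin,
        fiber_amplitude=base_actin.fiber_amplitude * preset.intensity_multiplier,
    )
    nuclei_spec = replace(
        base_nuclei,
        n_nuclei=int(round(base_nuclei.n_nuclei * preset.nuclei_multiplier)),
    )

    ss = np.random.SeedSequence(seed)
    s_angles, s_fibers, s_nuclei = ss.spawn(3)
    angles = sample_axial_angles(preset.orientation, actin_spec.n_fibers, s_angles)
    actin = render_fibers(actin_spec, angles, s_fibers)
    nuclei, gt = render_nuclei(nuclei_spec, s_nuclei)
    gt.fiber_angles_deg = angles
    return SyntheticImage(
        actin_channel=actin,
        nuclei_channel=nuclei,
        pixel_size_um=actin_spec.pixel_size_um,
        ground_truth=gt,
        seed=seed,
        preset=preset.name,
    )


# --------------------------------------------------------------------------- #
# file I/O
# --------------------------------------------------------------------------- #

def _quantize_u16(arr: np.ndarray) -> np.ndarray:
    return np.round(np.clip(arr, 0, 65535)).astype(np.uint16)


def write_synthetic(image: SyntheticImage, path) -> Path:
    """Write an image set: 16-bit TIFF per channel, ground-truth CSVs, sidecar.

    Pixel values are rounded to the nearest integer and clipped to the 16-bit
    range on write; a subsequent :func:`read_image` round-trips those stored
    values exactly.
    """
    outdir = Path(path)
    outdir.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(outdir / "actin.tif", _quantize_u16(image.actin_channel))
    tifffile.imwrite(outdir / "nuclei.tif", _quantize_u16(image.nuclei_channel))
    sidecar = {
        "seed": image.seed,
        "preset": image.preset,
        "pixel_size_um": image.pixel_size_um,
    }
    (outdir / "sidecar.json").write_text(json.dumps(sidecar, indent=1))
    gt = image.ground_truth
    if gt is not None:
        pd.DataFrame({"angle_deg": gt.fiber_angles_deg}).to_csv(
            outdir / "fiber_angles.csv", index=False)
        pd.DataFrame({
            "cx_px": gt.nuclei_centroids_px[:, 0],
            "cy_px": gt.nuclei_centroids_px[:, 1],
            "area_um2": gt.nuclei_areas_um2,
        }).to_csv(outdir / "nuclei.csv", index=False)
    return outdir


def read_image(path, pixel_size_um: float | None = None) -> SyntheticImage:
    """Read a written image set, or a single TIFF/PNG raster.

    A directory written by :func:`write_synthetic` supplies the pixel size
    from its JSON sidecar.  A bare raster file requires ``pixel_size_um``.
    Integer images are promoted to float with values preserved.  Ground truth
    is never reconstructed on read.
    """
    p = Path(path)
    if p.is_dir():
        sidecar_path = p / "sidecar.json"
        if sidecar_path.exists():
            sidecar = json.loads(sidecar_path.read_text())
            px = sidecar.get("pixel_size_um", pixel_size_um)
            preset = sidecar.get("preset")
            seed = sidecar.get("seed")
        else:
            px, preset, seed = pixel_size_um, None, None
        if px is None or px <= 0:
            raise ValueError("pixel_size_um required (positive) when sidecar is absent")
        actin = tifffile.imread(p / "actin.tif").astype(float)
        nuclei = tifffile.imread(p / "nuclei.tif").astype(float)
        return SyntheticImage(actin, nuclei, float(px), None, seed, preset)

    if pixel_size_um is None or pixel_size_um <= 0:
        raise ValueError("pixel_size_um required (positive) for a bare raster file")
    if p.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(p)
    else:
        arr = iio.imread(p)
    if arr.ndim == 3:  # collapse RGB(A) to luminance-free mean
        arr = arr[..., :3].mean(axis=-1)
    arr = arr.astype(float)
    blank = np.zeros_like(arr)
    return SyntheticImage(arr, blank, float(pixel_size_um))
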