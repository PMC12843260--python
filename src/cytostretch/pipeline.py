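"""End-to-end orchestration: generate conditions, quantify, model, report.

The imaging experiment renders n synthetic images per condition preset, runs
the structure-tensor quantification chain on each (orientation histogram ->
coherency index; background subtraction -> normalized intensity; nuclei
segmentation -> relative density), and aggregates a per-condition report with
all ratios expressed relative to the control batch.  The membrane experiment
solves the Mooney-Rivlin plane-stress problem for each configured end
displacement and reports central-region strain uniformity.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import alignment_stats, cell_metrics, membrane_mechanics, orientation_analysis
from .synthetic_data import (
    CONDITION_PRESETS,
    FiberFieldSpec,
    NucleiFieldSpec,
    generate_condition,
)

__all__ = [
    "ExperimentConfig",
    "ConditionReport",
    "analyze_image",
    "run_imaging_experiment",
    "run_membrane_experiment",
    "run_group_stats",
    "significance_stars",
]

log = logging.getLogger("cytostretch")

REPORT_COLUMNS = ["condition", "CI_mean", "CI_sd", "Inorm_mean", "Inorm_sd",
                  "density_mean", "density_sd"]


@dataclass
class ExperimentConfig:
    """Full configuration of an imaging + membrane experiment run."""

    presets: tuple[str, ...] = ("control", "stretch_0p5Hz_10pct", "stretch_2p5Hz_1pct")
    n_images: int = 3
    seed: int = 0
    image_shape_px: tuple[int, int] = (1024, 1024)
    pixel_size_um: float = 0.65
    sigma_gradient_um: float = 0.65
    sigma_window_um: float = 2.6
    n_bins: int = 90
    energy_percentile_mask: float = 50.0
    background_radius_um: float = 25.0
    # membrane model
    length_mm: float = 30.0
    width_mm: float = 10.0
    thickness_mm: float = 1.0
    nx: int = 60
    ny: int = 20
    C10: float = 0.12
    C01: float = 0.03
    displacements_mm: tuple[float, ...] = (3.0, 0.3)
    n_load_steps: int = 10
    newton_tol: float = 1e-8
    outdir: str = "cytostretch_out"

    def __post_init__(self):
        unknown = [p for p in self.presets if p not in CONDITION_PRESETS]
        if unknown:
            raise ValueError(f"unregistered presets {unknown}; "
                             f"valid: {sorted(CONDITION_PRESETS)}")
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("presets", "image_shape_px", "displacements_mm"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class ConditionReport:
    condition: str
    n_images: int
    CI_mean: float
    CI_sd: float
    Inorm_mean: float
    Inorm_sd: float
    density_mean: float
    density_sd: float


@dataclass
class ImageMetrics:
    condition: str
    seed: int
    CI: float
    mean_fg_intensity: float
    nuclei_count: int


def analyze_image(image, config: ExperimentConfig) -> ImageMetrics:
    """Per-image quantification: CI (tensor route), intensity, nuclei count."""
    fieldm = orientation_analysis.structure_tensor_field(
        image.actin_channel,
        sigma_gradient_um=config.sigma_gradient_um,
        sigma_window_um=config.sigma_window_um,
        pixel_size_um=image.pixel_size_um,
    )
    hist = orientation_analysis.histogram_from_field(
        fieldm, n_bins=config.n_bins,
        energy_percentile_mask=config.energy_percentile_mask,
    )
    metrics = alignment_stats.alignment_metrics(histogram=hist)
    sub = cell_metrics.subtract_background(
        image.actin_channel, config.background_radius_um, image.pixel_size_um)
    intensity = cell_metrics.mean_foreground_intensity(sub)
    count, _, _ = cell_metrics.segment_nuclei(
        image.nuclei_channel, image.pixel_size_um)
    return ImageMetrics(
        condition=image.preset or "unknown",
        seed=image.seed if image.seed is not None else -1,
        CI=metrics.coherency_index_CI,
        mean_fg_intensity=intensity,
        nuclei_count=count,
    )


def run_imaging_experiment(
    config: ExperimentConfig, seed: int | None = None, write: bool = True
) -> tuple[list[ConditionReport], pd.DataFrame]:
    """Generate and quantify n images per preset; aggregate a condition report.

    Intensity and density ratios use the ratio of batch means (control mean in
    the denominator), so the control row is 1 by definition; per-image ratios
    provide the spread.  With ``write=True`` the report CSV, the per-image
    metrics CSV, and a JSON log (seeds, parameters, config hash) are written
    to ``config.outdir``.
    """
    seed = config.seed if seed is None else seed
    if "control" not in config.presets:
        raise ValueError("the control preset is required for normalization")
    base_actin = FiberFieldSpec(image_shape_px=config.image_shape_px,
                                pixel_size_um=config.pixel_size_um)
    base_nuclei = NucleiFieldSpec(image_shape_px=config.image_shape_px,
                                  pixel_size_um=config.pixel_size_um)

    rows = []
    t_start = time.perf_counter()
    for preset in config.presets:
        for i in range(config.n_images):
            img_seed = int(seed) + i + 1
            try:
                img = generate_condition(preset, base_actin, base_nuclei,
                                         seed=img_seed)
                m = analyze_image(img, config)
            except Exception as exc:
                raise RuntimeError(
                    f"imaging stage failed for condition {preset!r}, "
                    f"seed {img_seed}: {exc}") from exc
            rows.append(m)
            log.info("analyzed %s seed=%d CI=%.3f", preset, img_seed, m.CI)
    per_image = pd.DataFrame([vars(m) for m in rows])

    ctrl = per_image[per_image.condition == "control"]
    i_ctrl = ctrl.mean_fg_intensity.mean()
    n_ctrl = ctrl.nuclei_count.mean()
    reports = []
    for preset in config.presets:
        sel = per_image[per_image.condition == preset]
        inorm = sel.mean_fg_intensity / i_ctrl
        dens = sel.nuclei_count / n_ctrl
        reports.append(ConditionReport(
            condition=preset,
            n_images=len(sel),
            CI_mean=float(sel.CI.mean()),
            CI_sd=float(sel.CI.std(ddof=1)) if len(sel) > 1 else 0.0,
            Inorm_mean=float(sel.mean_fg_intensity.mean() / i_ctrl),
            Inorm_sd=float(inorm.std(ddof=1)) if len(sel) > 1 else 0.0,
            density_mean=float(sel.nuclei_count.mean() / n_ctrl),
            density_sd=float(dens.std(ddof=1)) if len(sel) > 1 else 0.0,
        ))

    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report_df = pd.DataFrame([vars(r) for r in reports])
        report_df = report_df[["condition", "n_images"] + REPORT_COLUMNS[1:]]
        report_df.to_csv(outdir / "condition_report.csv", index=False)
        per_image.to_csv(outdir / "per_image_metrics.csv", index=False)
        (outdir / "run_log.json").write_text(json.dumps({
            "config": asdict(config),
            "config_hash": config.config_hash(),
            "seed": seed,
            "elapsed_s": time.perf_counter() - t_start,
        }, indent=1, default=str))
    return reports, per_image


def run_membrane_experiment(config: ExperimentConfig, write: bool = True) -> dict:
    """Solve the membrane for each configured end displacement.

    Returns {displacement_mm: (StrainField, UniformityReport)}; with
    ``write=True`` each solution is exported as legacy VTK plus a combined
    uniformity CSV in ``config.outdir``.
    """
    mesh = membrane_mechanics.build_membrane_mesh(
        config.length_mm, config.width_mm, config.thickness_mm,
        config.nx, config.ny)
    mat = membrane_mechanics.MooneyRivlinMaterial(config.C10, config.C01)
    results = {}
    rows = []
    for disp in config.displacements_mm:
        bc = membrane_mechanics.uniaxial_stretch_bc(mesh, disp)
        fieldm = membrane_mechanics.solve_plane_stress(
            mesh, mat, bc, n_load_steps=config.n_load_steps,
            newton_tol=config.newton_tol)
        rep = membrane_mechanics.central_region_uniformity(fieldm)
        results[disp] = (fieldm, rep)
        rows.append({"displacement_mm": disp,
                     "nominal_strain": disp / config.length_mm,
                     **vars(rep)})
        log.info("membrane disp=%.2f mm: central strain %.4f +/- %.4f",
                 disp, rep.mean_max_principal_engineering_strain,
                 rep.sd_max_principal_engineering_strain)
    if write:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for disp, (fieldm, _) in results.items():
            membrane_mechanics.write_vtk(
                fieldm, outdir / f"membrane_disp_{disp:g}mm.vtk")
        pd.DataFrame(rows).to_csv(outdir / "uniformity_report.csv", index=False)
    return results


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def run_group_stats(batches: dict[str, np.ndarray]) -> pd.DataFrame:
    """One-way ANOVA across groups plus pairwise two-sided t-tests.

    Pairwise p-values are reported unadjusted, with an additional Bonferroni
    column.  Groups with zero within-group variance take an exact-equality
    fast path (p = 1 if the means agree exactly, else p = 0).
    """
    names = list(batches)
    arrays = [np.asarray(batches[n], dtype=float) for n in names]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 replicates each")

    rows = []
    if all(a.std() == 0 for a in arrays):
        means = [a.mean() for a in arrays]
        p_anova = 1.0 if len(set(means)) == 1 else 0.0
        f_stat = 0.0 if p_anova == 1.0 else np.inf
    else:
        f_stat, p_anova = stats.f_oneway(*arrays)
    rows.append({"comparison": "ANOVA:" + "|".join(names),
                 "statistic": float(f_stat), "p_value": float(p_anova),
                 "p_bonferroni": float(p_anova),
                 "stars": significance_stars(p_anova)})

    pairs = [(i, j) for i in range(len(names)) for j in range(i + 1, len(names))]
    for i, j in pairs:
        a, b = arrays[i], arrays[j]
        if a.std() == 0 and b.std() == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
            t = 0.0 if p == 1.0 else np.inf
        else:
            t, p = stats.ttest_ind(a, b)
        rows.append({"comparison": f"t:{names[i]}|{names[j]}",
                     "statistic": float(t), "p_value": float(p),
                     "p_bonferroni": float(min(1.0, p * len(pairs))),
                     "stars": significance_stars(p)})
    return pd.DataFrame(rows)
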