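"""Relative gene-expression quantification by the delta-delta-Ct method.

Per condition, delta Ct = mean Ct(target) - mean Ct(reference gene, GAPDH by
default); delta-delta Ct = delta Ct(stretched) - delta Ct(control); fold
change = 2^(-delta-delta Ct).  Replicate standard deviations are propagated
in quadrature and reported alongside.  Primer efficiency from a standard-curve
slope is informational: the 100%-efficiency assumption of 2^-ddCt is retained.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CtRecord",
    "FoldChangeResult",
    "EfficiencyResult",
    "delta_delta_ct",
    "efficiency_from_slope",
    "read_ct_csv",
    "fold_changes_to_csv",
]

DEFAULT_REFERENCE_GENE = "GAPDH"


@dataclass(frozen=True)
class CtRecord:
    sample_id: str
    gene: str
    condition: str  # "control" | "stretched"
    ct: float
    reference_gene: str = DEFAULT_REFERENCE_GENE

    def __post_init__(self):
        if not 0 < self.ct < 45:
            raise ValueError(f"Ct {self.ct} outside the plausible (0, 45) range")


@dataclass(frozen=True)
class FoldChangeResult:
    gene: str
    delta_ct_condition: float
    delta_ct_control: float
    delta_delta_ct: float
    fold_change: float
    fold_change_sd: float


@dataclass(frozen=True)
class EfficiencyResult:
    gene: str
    slope: float
    efficiency_percent: float


def _group(records, gene, condition):
    return np.array([r.ct for r in records
                     if r.gene == gene and r.condition == condition])


def delta_delta_ct(
    records: list[CtRecord],
    reference_gene: str = DEFAULT_REFERENCE_GENE,
    control_condition: str = "control",
    treated_condition: str = "stretched",
) -> list[FoldChangeResult]:
    """Fold changes 2^(-ddCt) for every target gene in a Ct record set.

    The reference gene must be measured in both conditions; each target gene
    needs at least one replicate per condition.  Replicate SDs of target and
    reference are combined in quadrature per condition, and the two condition
    SDs again in quadrature, then mapped through the exponential to a fold-
    change SD.
    """
    genes = sorted({r.gene for r in records if r.gene != reference_gene})
    if not genes:
        raise ValueError("no target genes in record set")
    results = []
    for cond in (control_condition, treated_condition):
        if _group(records, reference_gene, cond).size == 0:
            raise ValueError(
                f"reference gene {reference_gene!r} missing in condition {cond!r}")
    ref_ctrl = _group(records, reference_gene, control_condition)
    ref_trt = _group(records, reference_gene, treated_condition)
    for gene in genes:
        tgt_ctrl = _group(records, gene, control_condition)
        tgt_trt = _group(records, gene, treated_condition)
        if tgt_ctrl.size == 0 or tgt_trt.size == 0:
            raise ValueError(f"gene {gene!r} lacks replicates in one condition")
        d_ctrl = tgt_ctrl.mean() - ref_ctrl.mean()
        d_trt = tgt_trt.mean() - ref_trt.mean()
        ddct = d_trt - d_ctrl
        fold = 2.0 ** (-ddct)
        sd_ddct = np.sqrt(
            tgt_trt.std(ddof=1 if tgt_trt.size > 1 else 0) ** 2
            + ref_trt.std(ddof=1 if ref_trt.size > 1 else 0) ** 2
            + tgt_ctrl.std(ddof=1 if tgt_ctrl.size > 1 else 0) ** 2
            + ref_ctrl.std(ddof=1 if ref_ctrl.size > 1 else 0) ** 2
        )
        fold_sd = fold * np.log(2.0) * sd_ddct  # first-order propagation
        results.append(FoldChangeResult(
            gene=gene,
            delta_ct_condition=float(d_trt),
            delta_ct_control=float(d_ctrl),
            delta_delta_ct=float(ddct),
            fold_change=float(fold),
            fold_change_sd=float(fold_sd),
        ))
    return results


def efficiency_from_slope(slope: float, gene: str = "") -> EfficiencyResult:
    """Amplification efficiency (%) from a standard-curve slope.

    slope is in Ct per log10(dilution) and must be negative;
    efficiency = (10^(-1/slope) - 1) * 100, so a slope of -3.3219 (perfect
    per-cycle doubling) gives 100%.
    """
    if slope >= 0:
        raise ValueError("standard-curve slope must be negative")
    eff = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    return EfficiencyResult(gene=gene, slope=slope, efficiency_percent=float(eff))


def read_ct_csv(path, reference_gene: str = DEFAULT_REFERENCE_GENE) -> list[CtRecord]:
    """Read Ct records from a CSV with columns sample_id, gene, condition, ct."""
    df = pd.read_csv(path)
    required = {"sample_id", "gene", "condition", "ct"}
    if not required.issubset(df.columns):
        raise ValueError(f"Ct CSV must have columns {sorted(required)}")
    return [
        CtRecord(str(r.sample_id), str(r.gene), str(r.condition), float(r.ct),
                 reference_gene)
        for r in df.itertuples()
    ]


def fold_changes_to_csv(results: list[FoldChangeResult], path) -> None:
    pd.DataFrame([vars(r) for r in results]).to_csv(path, index=False)
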