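"""Per-case immune metrics.

Compartment densities (cells/mm², counts normalised to the tumor-cluster
area of the core), replicate-core averaging, the log10 floor transform for
zero counts, the CD8:FOXP3 ratio, and the PD-L1 Combined Positive Score
(CPS) with its ≥1 positivity call.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cells import IMMUNE_PHENOTYPES
from .zones import ZONES

CPS_CAP = 100.0
CPS_POSITIVE_THRESHOLD = 1.0
#: zero counts are floored to this fraction of the smallest non-zero value
LOG_FLOOR_FRACTION = 0.9


@dataclass(frozen=True)
class CpsResult:
    case_id: str
    cps: float
    positive: bool
    n_cores: int


def density(count: float, tumor_area_mm2: float) -> float:
    """Immune-cell density: count normalised to tumor-cluster area (mm²)."""
    if tumor_area_mm2 <= 0:
        raise ValueError(
            f"tumor area must be positive, got {tumor_area_mm2} mm²"
        )
    return count / tumor_area_mm2


def aggregate_replicates(per_core_values) -> float:
    """Arithmetic mean over evaluable replicate cores of one case."""
    values = [v for v in per_core_values if v is not None and np.isfinite(v)]
    if not values:
        raise ValueError("no evaluable core: case is unevaluable")
    return float(np.mean(values))


def log_floor_transform(case_values: pd.Series) -> pd.Series:
    """log10-transform case values, flooring zeros first.

    Zeros are replaced by ``LOG_FLOOR_FRACTION`` × the smallest non-zero
    value across the cases evaluated, so zero-count cases remain strictly
    below every observed case on the log scale.
    """
    values = pd.Series(case_values, dtype=float)
    if (values < 0).any():
        raise ValueError("negative values cannot be log-transformed")
    nonzero = values[values > 0]
    if nonzero.empty:
        raise ValueError("all values are zero: log floor undefined")
    floor = LOG_FLOOR_FRACTION * nonzero.min()
    return np.log10(values.mask(values == 0, floor))


def cd8_foxp3_ratio(core_counts: pd.DataFrame) -> float:
    """Case-level CD8:FOXP3 ratio.

    ``core_counts`` has one row per core with whole-core ``cd8`` and
    ``foxp3`` totals (all compartments combined). The per-core ratio
    CD8/FOXP3 is averaged across evaluable cores; cores without any FOXP3+
    cell are excluded rather than given an infinite or floored ratio.
    Returns NaN when no core is evaluable.
    """
    evaluable = core_counts[core_counts["foxp3"] > 0]
    if evaluable.empty:
        return float("nan")
    ratios = evaluable["cd8"] / evaluable["foxp3"]
    return float(ratios.mean())


def cps(core_cells: pd.DataFrame, cap: float = CPS_CAP) -> float:
    """Combined Positive Score for one core.

    100 × (PD-L1+ tumor cells + PD-L1+ lymphocytes + PD-L1+ macrophages)
    divided by the number of viable tumor cells, capped at ``cap``.
    Returns NaN (core unevaluable) when the core has no viable tumor cell.
    """
    viable_tumor = int(
        ((core_cells["cell_class"] == "tumor") & core_cells["viable"]).sum()
    )
    if viable_tumor == 0:
        return float("nan")
    eligible = core_cells["cps_class"].isin(("tumor_cell", "lymphocyte", "macrophage"))
    n_pos = int((eligible & core_cells["pdl1_positive"]).sum())
    return min(cap, 100.0 * n_pos / viable_tumor)


def case_cps(case_id: str, per_core_cps) -> CpsResult:
    """Average core CPS values into the case score and positivity call."""
    values = [v for v in per_core_cps if v is not None and not math.isnan(v)]
    if not values:
        raise ValueError(f"case {case_id!r}: no CPS-evaluable core")
    score = float(np.mean(values))
    return CpsResult(
        case_id=case_id,
        cps=score,
        positive=score >= CPS_POSITIVE_THRESHOLD,
        n_cores=len(values),
    )


def core_metric_row(
    zone_count_table: pd.DataFrame, tumor_area_mm2: float
) -> dict[str, float]:
    """Flatten one core's zoned counts into density columns.

    Keys are ``density_<phenotype>_<zone>`` in cells/mm² plus the raw
    whole-core ``count_<phenotype>`` totals.
    """
    row: dict[str, float] = {"tumor_area_mm2": tumor_area_mm2}
    for ph in IMMUNE_PHENOTYPES:
        total = 0
        for zone in ZONES:
            n = (
                int(zone_count_table.loc[ph, zone])
                if ph in zone_count_table.index
                else 0
            )
            row[f"density_{ph}_{zone}"] = density(n, tumor_area_mm2)
            total += n
        row[f"count_{ph}"] = total
    return row


def case_metrics_table(core_rows: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-core metric rows into the per-case metrics table.

    ``core_rows`` carries one row per evaluable core with ``case_id``,
    ``core_id``, the density/count columns of :func:`core_metric_row` and
    a ``cps`` column. Densities and CPS are averaged across replicate
    cores; the CD8:FOXP3 ratio is computed per core from whole-core counts
    and averaged over FOXP3-evaluable cores.
    """
    records = []
    density_cols = [c for c in core_rows.columns if c.startswith("density_")]
    for case_id, grp in core_rows.groupby("case_id", sort=True):
        rec: dict[str, object] = {"case_id": case_id, "n_cores": len(grp)}
        for col in density_cols:
            rec[col] = aggregate_replicates(grp[col])
        rec["cd8_foxp3_ratio"] = cd8_foxp3_ratio(
            grp.rename(columns={"count_CD8": "cd8", "count_FOXP3": "foxp3"})
        )
        cps_values = [v for v in grp["cps"] if not math.isnan(v)]
        if cps_values:
            res = case_cps(str(case_id), cps_values)
            rec["cps"] = res.cps
            rec["cps_positive"] = res.positive
        else:
            rec["cps"] = float("nan")
            rec["cps_positive"] = pd.NA
        records.append(rec)
    return pd.DataFrame.from_records(records)
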