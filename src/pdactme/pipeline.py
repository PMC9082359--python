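"""End-to-end orchestration: geometry → compartments → metrics → classify → stats.

The pipeline consumes a cell table (all cores), optional exclusion
polygons per core, a molecular annotation table and a clinical table, and
produces the per-case metrics table plus the structured group-comparison
report. Every run can write its intermediates and a manifest recording
the configuration hash, seed and per-stage row counts; reruns on
identical inputs produce byte-identical reports.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .classify import ClassifierThresholds, classify_table
from .geometry import build_tumor_clusters
from .metrics import case_metrics_table, core_metric_row, cps
from .stats import compare_cohort
from .zones import ZoneThresholds, counts_from_zoned, zone_cells


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable pipeline parameters with their published defaults."""

    intra_max: float = 10.0
    peri_max: float = 50.0
    merge_radius: float = 15.0
    min_cells: int = 5
    density_denominator: str = "tumor_area"  # or "zone_area"
    cps_cap: float = 100.0
    hrdetect_germline: float = 0.9
    hrdetect_somatic: float = 0.9
    hrdetect_low_cellularity: float = 0.7
    msisensor_threshold: float = 20.0
    fisher_alternative: str = "two-sided"
    groups: tuple[str, str] = ("HR_d", "HR_MMR_intact")
    survival_exclude: tuple[str, ...] = ()
    adjust_p_values: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.intra_max < self.peri_max:
            raise ValueError(
                f"need 0 < intra_max ({self.intra_max}) < peri_max ({self.peri_max})"
            )
        if self.merge_radius <= 0:
            raise ValueError("merge_radius must be positive")
        if self.density_denominator not in ("tumor_area", "zone_area"):
            raise ValueError(
                f"unknown density_denominator {self.density_denominator!r}"
            )
        if self.cps_cap <= 0:
            raise ValueError("cps_cap must be positive")

    @property
    def thresholds(self) -> ZoneThresholds:
        return ZoneThresholds(self.intra_max, self.peri_max)

    @property
    def classifier_thresholds(self) -> ClassifierThresholds:
        return ClassifierThresholds(
            hrdetect_germline=self.hrdetect_germline,
            hrdetect_somatic=self.hrdetect_somatic,
            hrdetect_low_cellularity=self.hrdetect_low_cellularity,
            msisensor=self.msisensor_threshold,
        )

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["groups"] = list(self.groups)
        data["survival_exclude"] = list(self.survival_exclude)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["groups"] = tuple(data.get("groups", ("HR_d", "HR_MMR_intact")))
        data["survival_exclude"] = tuple(data.get("survival_exclude", ()))
        return cls(**data)

    def config_hash(self) -> str:
        data = asdict(self)
        data["groups"] = list(self.groups)
        data["survival_exclude"] = list(self.survival_exclude)
        canon = json.dumps(data, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def analyze_cores(
    cells: pd.DataFrame,
    config: PipelineConfig = PipelineConfig(),
    exclusions: dict[str, list] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Run geometry, zoning and per-core metrics over every core.

    Returns (per-core metric rows, zoned cell table, cluster sets).
    Cores without tumor clusters or with zero post-exclusion tumor area
    are dropped with a warning (the density denominator is undefined).
    """
    exclusions = exclusions or {}
    core_rows = []
    zoned_frames = []
    cluster_sets = {}
    for core_id, core_cells in cells.groupby("core_id", sort=True):
        excl = exclusions.get(str(core_id))
        clusters = build_tumor_clusters(
            core_cells,
            merge_radius=config.merge_radius,
            min_cells=config.min_cells,
            exclusions=excl,
        )
        if clusters.is_empty or clusters.total_area_mm2 <= 0:
            warnings.warn(
                f"core {core_id!r} dropped: no evaluable tumor-cluster area",
                stacklevel=2,
            )
            continue
        cluster_sets[str(core_id)] = clusters
        zoned = zone_cells(core_cells, clusters, config.thresholds, excl)
        counts = counts_from_zoned(zoned)
        zoned_frames.append(zoned)
        row = core_metric_row(counts, clusters.total_area_mm2)
        row["core_id"] = str(core_id)
        row["case_id"] = str(core_cells["case_id"].iloc[0])
        row["cps"] = cps(core_cells, cap=config.cps_cap)
        core_rows.append(row)
    core_df = pd.DataFrame(core_rows)
    zoned_df = (
        pd.concat(zoned_frames, ignore_index=True)
        if zoned_frames
        else pd.DataFrame()
    )
    return core_df, zoned_df, cluster_sets


def run_pipeline(
    cells: pd.DataFrame,
    annotations: list,
    clinical: pd.DataFrame | None = None,
    config: PipelineConfig = PipelineConfig(),
    exclusions: dict[str, list] | None = None,
    outdir=None,
) -> dict:
    """Execute all stages and return the structured report.

    When ``outdir`` is given, writes the zoned-cell CSV, cluster GeoJSON,
    per-case metrics TSV, label TSV, report JSON and a manifest with the
    configuration hash and per-stage row counts.
    """
    core_df, zoned_df, cluster_sets = analyze_cores(cells, config, exclusions)
    if core_df.empty:
        raise ValueError("pipeline aborted at stage geometry: no evaluable core")
    case_metrics = case_metrics_table(core_df)
    labels, counts = classify_table(annotations, config.classifier_thresholds)
    result = compare_cohort(
        case_metrics,
        labels,
        survival=clinical,
        groups=config.groups,
        survival_exclude=config.survival_exclude,
        adjust=config.adjust_p_values,
    )
    report = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_cases": int(case_metrics["case_id"].nunique()),
        "n_cores": int(len(core_df)),
        "subgroup_counts": counts,
        "comparison": result.to_dict(),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pio.write_tsv(zoned_df, outdir / "zoned_cells.tsv")
        pio.write_polygons_geojson(cluster_sets, outdir / "tumor_clusters.geojson")
        pio.write_tsv(case_metrics, outdir / "case_metrics.tsv")
        pio.write_tsv(labels, outdir / "subgroup_labels.tsv")
        pio.write_report(report, outdir / "report.json")
        manifest = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "rows": {
                "cells_in": int(len(cells)),
                "cores_evaluable": int(len(core_df)),
                "zoned_cells": int(len(zoned_df)),
                "cases": int(len(case_metrics)),
                "annotations": int(len(annotations)),
                "clinical": 0 if clinical is None else int(len(clinical)),
            },
        }
        pio.write_report(manifest, outdir / "manifest.json")
    return report
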