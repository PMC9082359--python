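"""File formats binding the pipeline stages.

Cell tables travel as comma-separated UTF-8 CSV with "." decimals and
true/false booleans; cluster and exclusion polygons as GeoJSON with
coordinates in µm and a ``core_id`` feature property; molecular
annotations, clinical tables and per-case metrics as TSV; reports and
manifests as JSON with sorted keys (byte-stable across reruns).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .cells import validate_cell_table
from .classify import MMR_GENES, MolecularAnnotation, annotations_from_frame
from .geometry import TumorClusterSet


def read_cell_table(path) -> pd.DataFrame:
    """Read and validate a cell-table CSV."""
    path = Path(path)
    df = pd.read_csv(path, dtype={"core_id": str, "case_id": str})
    if df.empty:
        raise ValueError(f"{path}: empty cell table")
    return validate_cell_table(df)


def write_cell_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in ("pdl1_positive", "viable"):
        out[col] = out[col].map({True: "true", False: "false"})
    out.to_csv(path, index=False)


def write_polygons_geojson(cluster_sets: dict[str, TumorClusterSet], path) -> None:
    """Write cluster polygons of several cores as a GeoJSON FeatureCollection."""
    features = []
    for core_id in sorted(cluster_sets):
        cs = cluster_sets[core_id]
        for poly in cs.polygons:
            features.append(
                {
                    "type": "Feature",
                    "properties": {"core_id": core_id},
                    "geometry": mapping(poly),
                }
            )
    doc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def read_polygons_geojson(path) -> dict[str, list]:
    """Read polygons grouped by their ``core_id`` property."""
    doc = json.loads(Path(path).read_text())
    out: dict[str, list] = {}
    for feat in doc.get("features", []):
        core_id = str(feat.get("properties", {}).get("core_id", ""))
        out.setdefault(core_id, []).append(shape(feat["geometry"]))
    return out


def annotations_to_frame(annotations: list[MolecularAnnotation]) -> pd.DataFrame:
    rows = []
    for a in annotations:
        row = {
            "case_id": a.case_id,
            "germline_hr_gene": a.germline_hr_gene or "",
            "somatic_hr_inactivation": "true" if a.somatic_hr_inactivation else "false",
            "hrdetect": "" if a.hrdetect is None else a.hrdetect,
            "low_cellularity": "true" if a.low_cellularity_override else "false",
            "germline_mmr_gene": a.germline_mmr_gene or "",
            "msisensor": "" if a.msisensor is None else a.msisensor,
        }
        for protein in MMR_GENES:
            state = a.mmr_ihc.get(protein, "not_assessed")
            row[protein.lower()] = "" if state == "not_assessed" else state
        rows.append(row)
    return pd.DataFrame(rows)


def write_annotations(annotations: list[MolecularAnnotation], path) -> None:
    annotations_to_frame(annotations).to_csv(path, sep="\t", index=False)


def read_annotations(path) -> list[MolecularAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return annotations_from_frame(df)


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"case_id": str, "group": str})
    for col in ("case_id", "time_months", "event", "group"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing column {col!r}")
    df["event"] = df["event"].map(
        lambda v: str(v).strip().lower() in ("true", "1", "yes")
    )
    return df


def write_report(report: dict, path) -> None:
    """JSON report with sorted keys: identical inputs give identical bytes."""
    Path(path).write_text(json.dumps(report, sort_keys=True, indent=2, default=float))
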