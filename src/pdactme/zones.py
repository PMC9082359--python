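"""Compartment assignment by distance banding.

Every immune cell is assigned to one of three compartments by its signed
distance to the tumor-cluster perimeter: intra-tumoral within 10 µm
(including cells inside clusters), peri-tumoral between 10 and 50 µm, and
stromal beyond 50 µm. Band boundaries are closed on the inner side
(d ≤ 10 is intra; 10 < d ≤ 50 is peri), a measure-zero convention fixed
for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.ops import unary_union

from .geometry import TumorClusterSet, signed_distances

ZONES = ("intra_tumoral", "peri_tumoral", "stromal")


@dataclass(frozen=True)
class ZoneThresholds:
    """Distance bands in µm: intra ≤ intra_max < peri ≤ peri_max < stromal."""

    intra_max: float = 10.0
    peri_max: float = 50.0

    def __post_init__(self) -> None:
        if not 0 < self.intra_max < self.peri_max:
            raise ValueError(
                f"invalid thresholds: need 0 < intra_max ({self.intra_max}) "
                f"< peri_max ({self.peri_max})"
            )


def assign_zone(distance: float, thresholds: ZoneThresholds = ZoneThresholds()) -> str:
    """Classify a signed distance (µm) into a compartment."""
    if not np.isfinite(distance):
        raise ValueError(f"non-finite distance {distance}")
    if distance <= thresholds.intra_max:
        return "intra_tumoral"
    if distance <= thresholds.peri_max:
        return "peri_tumoral"
    return "stromal"


def assign_zones(
    distances: np.ndarray, thresholds: ZoneThresholds = ZoneThresholds()
) -> np.ndarray:
    """Vectorised :func:`assign_zone`."""
    d = np.asarray(distances, dtype=float)
    if not np.isfinite(d).all():
        raise ValueError("non-finite distance")
    out = np.where(
        d <= thresholds.intra_max,
        "intra_tumoral",
        np.where(d <= thresholds.peri_max, "peri_tumoral", "stromal"),
    )
    return out


def zone_cells(
    cells: pd.DataFrame,
    clusters: TumorClusterSet,
    thresholds: ZoneThresholds = ZoneThresholds(),
    exclusions: list | None = None,
) -> pd.DataFrame:
    """Attach ``distance_um`` and ``zone`` to every non-tumor cell of a core.

    Cells falling inside an exclusion polygon are omitted. Raises
    :class:`~pdactme.geometry.NoTumorClustersError` when the core has no
    tumor clusters (counts are unassignable without a perimeter).
    """
    immune = cells[cells["cell_class"] != "tumor"].copy()
    if exclusions:
        excl = unary_union(exclusions)
        pts = shapely.points(immune[["x_um", "y_um"]].to_numpy(dtype=float))
        immune = immune[~shapely.covers(excl, pts)]
    if immune.empty:
        immune["distance_um"] = pd.Series(dtype=float)
        immune["zone"] = pd.Series(dtype=str)
        return immune
    d = signed_distances(immune[["x_um", "y_um"]].to_numpy(dtype=float), clusters)
    immune["distance_um"] = d
    immune["zone"] = assign_zones(d, thresholds)
    return immune


def zone_areas_mm2(
    clusters: TumorClusterSet,
    region,
    thresholds: ZoneThresholds = ZoneThresholds(),
) -> dict[str, float]:
    """Compartment areas (mm²) within an analysed region polygon.

    The intra-tumoral compartment is the cluster union dilated by
    ``intra_max`` (clusters plus the inner band), peri-tumoral the annulus
    out to ``peri_max``, stromal the rest of the region. Used as the
    per-zone density denominator option and for intensity recovery on
    synthetic cores.
    """
    if clusters.is_empty:
        raise ValueError("zone areas undefined without tumor clusters")
    union = clusters.union
    intra = union.buffer(thresholds.intra_max).intersection(region)
    peri = (
        union.buffer(thresholds.peri_max)
        .difference(union.buffer(thresholds.intra_max))
        .intersection(region)
    )
    stromal = region.difference(union.buffer(thresholds.peri_max))
    return {
        "intra_tumoral": intra.area / 1e6,
        "peri_tumoral": peri.area / 1e6,
        "stromal": stromal.area / 1e6,
    }


def zone_counts(
    cells: pd.DataFrame,
    clusters: TumorClusterSet,
    thresholds: ZoneThresholds = ZoneThresholds(),
    exclusions: list | None = None,
) -> pd.DataFrame:
    """Count eligible immune cells per (cell_class, zone) for one core.

    Returns a DataFrame indexed by cell_class with one integer column per
    zone; every eligible cell is counted in exactly one zone.
    """
    zoned = zone_cells(cells, clusters, thresholds, exclusions)
    return counts_from_zoned(zoned)


def counts_from_zoned(zoned: pd.DataFrame) -> pd.DataFrame:
    """Tabulate an already-zoned cell table into per-(class, zone) counts."""
    classes = sorted(zoned["cell_class"].unique())
    table = pd.DataFrame(0, index=classes, columns=list(ZONES), dtype=int)
    if not zoned.empty:
        grouped = zoned.groupby(["cell_class", "zone"]).size()
        for (cls, zone), n in grouped.items():
            table.loc[cls, zone] = int(n)
    table.index.name = "cell_class"
    return table
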