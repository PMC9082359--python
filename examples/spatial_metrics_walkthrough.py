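"""Spatial metrics on one hand-built tissue core.

Builds a toy core with a compact tumor nest and a handful of immune
cells, reconstructs the tumor-cluster polygon, zones every immune cell
by its distance to the cluster perimeter (<=10 um intra-tumoral,
10-50 um peri-tumoral, >50 um stromal), and prints compartment counts,
densities and the PD-L1 Combined Positive Score.
"""

import pandas as pd

from pdactme import build_tumor_clusters, cps, zone_cells, zone_counts
from pdactme.cells import DEFAULT_CPS_CLASS


def cell(x, y, cls, pdl1=False):
    return {
        "core_id": "demo", "case_id": "demo", "x_um": x, "y_um": y,
        "cell_class": cls, "pdl1_positive": pdl1,
        "cps_class": DEFAULT_CPS_CLASS[cls], "viable": True,
    }


rows = [cell(10 * i, 10 * j, "tumor") for i in range(5) for j in range(5)]
rows += [
    cell(20, 20, "CD8"),          # deep inside the nest
    cell(45, 20, "CD8"),          # just outside, within 10 um of the rim
    cell(80, 20, "CD8"),          # 10-50 um band
    cell(150, 20, "CD8"),         # stromal
    cell(60, 60, "FOXP3"),
    cell(-30, -30, "CD68", pdl1=True),
]
cells = pd.DataFrame(rows)

clusters = build_tumor_clusters(cells, merge_radius=15, min_cells=5)
print(f"tumor clusters: {clusters.n_clusters}, "
      f"area = {clusters.total_area_mm2:.5f} mm^2")

zoned = zone_cells(cells, clusters)
print("\nper-cell zoning (distance to cluster perimeter, um):")
print(zoned[["cell_class", "distance_um", "zone"]].round(1).to_string(index=False))

counts = zone_counts(cells, clusters)
print("\ncounts per (phenotype, zone):")
print(counts.to_string())

dens = counts / clusters.total_area_mm2
print("\ndensities (cells/mm^2 of tumor-cluster area):")
print(dens.round(1).to_string())

print(f"\nCPS for this core: {cps(cells):.1f} "
      "(PD-L1+ eligible cells per 100 viable tumor cells)")
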