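import numpy as np
import pandas as pd
import pytest

from pdactme.cells import DEFAULT_CPS_CLASS


def make_cells(rows, core_id="core1", case_id="case1"):
    """Build a cell table from (x, y, cell_class[, pdl1]) tuples."""
    records = []
    for row in rows:
        x, y, cls = row[0], row[1], row[2]
        pdl1 = bool(row[3]) if len(row) > 3 else False
        records.append(
            {
                "core_id": core_id,
                "case_id": case_id,
                "x_um": float(x),
                "y_um": float(y),
                "cell_class": cls,
                "pdl1_positive": pdl1,
                "cps_class": DEFAULT_CPS_CLASS[cls],
                "viable": True,
            }
        )
    return pd.DataFrame(records)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def brute_force_signed_distance(xy, clusters):
    """Independent signed-distance oracle: exact point-to-segment minima
    over every boundary ring, sign by matplotlib's point-in-polygon test."""
    from matplotlib.path import Path

    xy = np.asarray(xy, dtype=float)
    d_min = np.full(len(xy), np.inf)
    for poly in clusters.polygons:
        rings = [poly.exterior] + list(poly.interiors)
        for ring in rings:
            coords = np.asarray(ring.coords)
            a = coords[:-1]
            b = coords[1:]
            ab = b - a  # (m, 2)
            denom = (ab**2).sum(axis=1)
            denom[denom == 0] = 1.0
            for i, p in enumerate(xy):
                ap = p - a
                t = np.clip((ap * ab).sum(axis=1) / denom, 0.0, 1.0)
                proj = a + t[:, None] * ab
                d = np.sqrt(((p - proj) ** 2).sum(axis=1)).min()
                d_min[i] = min(d_min[i], d)
    inside = np.zeros(len(xy), dtype=bool)
    for poly in clusters.polygons:
        path = Path(np.asarray(poly.exterior.coords))
        in_ext = path.contains_points(xy)
        for interior in poly.interiors:
            hole = Path(np.asarray(interior.coords))
            in_ext &= ~hole.contains_points(xy)
        inside |= in_ext
    return np.where(inside, -d_min, d_min)
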