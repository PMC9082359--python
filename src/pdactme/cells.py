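"""Cell-table schema and validation.

The canonical in-memory container for detected cells is a pandas DataFrame
with one row per cell and the columns in :data:`CELL_COLUMNS`. Coordinates
are planar Cartesian micrometers with an arbitrary per-core origin (y-up).

Columns
-------
core_id : str
    Identifier of the tissue core the cell was detected on.
case_id : str
    Identifier of the patient case (several replicate cores per case).
x_um, y_um : float
    Cell centroid coordinates in micrometers.
cell_class : str
    One of ``tumor``, ``CD8``, ``FOXP3``, ``CD68``, ``other``.
pdl1_positive : bool
    PD-L1 membrane positivity call for the cell.
cps_class : str
    Eligibility class for the Combined Positive Score: ``tumor_cell``,
    ``lymphocyte``, ``macrophage`` or ``other`` (CPS-ineligible).
viable : bool
    Whether the cell counts as viable (CPS denominator uses viable tumor
    cells only).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CELL_CLASSES = ("tumor", "CD8", "FOXP3", "CD68", "other")
CPS_CLASSES = ("tumor_cell", "lymphocyte", "macrophage", "other")

#: phenotypes counted in compartment densities
IMMUNE_PHENOTYPES = ("CD8", "FOXP3", "CD68")

CELL_COLUMNS = (
    "core_id",
    "case_id",
    "x_um",
    "y_um",
    "cell_class",
    "pdl1_positive",
    "cps_class",
    "viable",
)

#: default mapping from phenotype to CPS-eligibility class
DEFAULT_CPS_CLASS = {
    "tumor": "tumor_cell",
    "CD8": "lymphocyte",
    "FOXP3": "lymphocyte",
    "CD68": "macrophage",
    "other": "other",
}


def validate_cell_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a cell table in place and return it.

    Raises
    ------
    ValueError
        Naming the offending column or row when a required column is
        missing, a coordinate is non-finite, or a class value is outside
        the closed vocabulary.
    """
    for col in CELL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cell table is missing required column {col!r}")
    for col in ("x_um", "y_um"):
        values = pd.to_numeric(df[col], errors="coerce").to_numpy(dtype=float)
        bad = ~np.isfinite(values)
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"non-finite coordinate in column {col!r} at row {row}"
            )
        df[col] = values
    bad_class = ~df["cell_class"].isin(CELL_CLASSES)
    if bad_class.any():
        row = int(np.flatnonzero(bad_class.to_numpy())[0])
        value = df["cell_class"].iloc[row]
        raise ValueError(
            f"unknown cell_class {value!r} at row {row}; "
            f"expected one of {CELL_CLASSES}"
        )
    bad_cps = ~df["cps_class"].isin(CPS_CLASSES)
    if bad_cps.any():
        row = int(np.flatnonzero(bad_cps.to_numpy())[0])
        value = df["cps_class"].iloc[row]
        raise ValueError(
            f"unknown cps_class {value!r} at row {row}; "
            f"expected one of {CPS_CLASSES}"
        )
    tumor_bad = (df["cell_class"] == "tumor") & (df["cps_class"] != "tumor_cell")
    if tumor_bad.any():
        row = int(np.flatnonzero(tumor_bad.to_numpy())[0])
        raise ValueError(f"tumor cell with cps_class != 'tumor_cell' at row {row}")
    for col in ("pdl1_positive", "viable"):
        df[col] = df[col].map(_parse_bool)
    return df


def _parse_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in ("true", "1", "yes")
    return bool(value)


def empty_cell_table() -> pd.DataFrame:
    """Return an empty cell table with the canonical columns and dtypes."""
    return pd.DataFrame(
        {
            "core_id": pd.Series(dtype=str),
            "case_id": pd.Series(dtype=str),
            "x_um": pd.Series(dtype=float),
            "y_um": pd.Series(dtype=float),
            "cell_class": pd.Series(dtype=str),
            "pdl1_positive": pd.Series(dtype=bool),
            "cps_class": pd.Series(dtype=str),
            "viable": pd.Series(dtype=bool),
        }
    )
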