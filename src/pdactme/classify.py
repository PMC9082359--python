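"""Rule-based HR-d / MMR-d / HR-MMR-intact subgroup assignment.

Each case is labelled from its germline HR-gene status (BRCA1/BRCA2/PALB2),
somatic HR-gene inactivation, HRDetect score, mismatch-repair protein IHC
(MLH1/MSH2/MSH6/PMS2) and MSIsensor score:

* MMR-deficient (checked first): any assessed MMR protein lost on IHC, or
  MSIsensor ≥ 20. A germline MMR-gene mutation alone does not suffice.
* HR-deficient, germline path: a germline BRCA1/BRCA2/PALB2 mutation with
  HRDetect ≥ 0.9, or with no HRDetect score available. A germline carrier
  scoring below 0.9 is HR-intact, unless the case is flagged as low tumor
  cellularity and scores > 0.7 (cellularity can mask structural events).
* HR-deficient, somatic path: no germline mutation but HRDetect > 0.9
  together with evidence of somatic HR-gene inactivation.
* Everything else, including cases that could not be molecularly
  evaluated, is HR/MMR-intact.

The HRDetect cut-offs differ deliberately between paths: inclusive ≥ 0.9
for germline carriers, strict > 0.9 for the somatic-only path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

HR_GENES = ("BRCA1", "BRCA2", "PALB2")
MMR_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")
IHC_STATES = ("retained", "lost", "not_assessed")

LABELS = ("HR_d", "MMR_d", "HR_MMR_intact")

REFERENCE_ANNOTATIONS = "reference_molecular_annotations.tsv"


@dataclass(frozen=True)
class ClassifierThresholds:
    """HRDetect / MSIsensor decision thresholds."""

    hrdetect_germline: float = 0.9   # inclusive
    hrdetect_somatic: float = 0.9    # exclusive
    hrdetect_low_cellularity: float = 0.7  # exclusive, germline path only
    msisensor: float = 20.0          # inclusive


@dataclass(frozen=True)
class MolecularAnnotation:
    """Molecular inputs for one case (scores are consumed, not computed)."""

    case_id: str
    germline_hr_gene: str | None = None
    somatic_hr_inactivation: bool = False
    hrdetect: float | None = None
    low_cellularity_override: bool = False
    germline_mmr_gene: str | None = None
    mmr_ihc: dict[str, str] = field(default_factory=dict)
    msisensor: float | None = None

    def __post_init__(self) -> None:
        if self.germline_hr_gene is not None and self.germline_hr_gene not in HR_GENES:
            raise ValueError(f"unknown HR gene {self.germline_hr_gene!r}")
        if (
            self.germline_mmr_gene is not None
            and self.germline_mmr_gene not in MMR_GENES
        ):
            raise ValueError(f"unknown MMR gene {self.germline_mmr_gene!r}")
        if self.hrdetect is not None and not 0 <= self.hrdetect <= 1:
            raise ValueError(f"HRDetect score {self.hrdetect} outside [0, 1]")
        if self.msisensor is not None and self.msisensor < 0:
            raise ValueError(f"MSIsensor score {self.msisensor} negative")
        for protein, state in self.mmr_ihc.items():
            if protein not in MMR_GENES:
                raise ValueError(f"unknown MMR protein {protein!r}")
            if state not in IHC_STATES:
                raise ValueError(f"unknown IHC state {state!r}")


@dataclass(frozen=True)
class SubgroupLabel:
    case_id: str
    label: str
    rule_fired: str


def mmr_status(
    ann: MolecularAnnotation, thresholds: ClassifierThresholds = ClassifierThresholds()
) -> bool:
    """True iff the case is MMR-deficient by IHC loss or MSIsensor."""
    assessed = {p: s for p, s in ann.mmr_ihc.items() if s != "not_assessed"}
    if not assessed and ann.msisensor is None:
        warnings.warn(
            f"case {ann.case_id!r}: MMR status unevaluated (no IHC, no MSIsensor)",
            stacklevel=2,
        )
        return False
    if any(state == "lost" for state in assessed.values()):
        return True
    if ann.msisensor is not None and ann.msisensor >= thresholds.msisensor:
        return True
    return False


def classify_case(
    ann: MolecularAnnotation, thresholds: ClassifierThresholds = ClassifierThresholds()
) -> SubgroupLabel:
    """Assign one case to HR_d, MMR_d or HR_MMR_intact."""
    if mmr_status(ann, thresholds):
        return SubgroupLabel(ann.case_id, "MMR_d", "mmr_ihc_loss_or_msisensor")
    if ann.germline_hr_gene is not None:
        if ann.hrdetect is None:
            return SubgroupLabel(ann.case_id, "HR_d", "germline_no_hrdetect")
        if ann.hrdetect >= thresholds.hrdetect_germline:
            return SubgroupLabel(ann.case_id, "HR_d", "germline_hrdetect_high")
        if (
            ann.low_cellularity_override
            and ann.hrdetect > thresholds.hrdetect_low_cellularity
        ):
            return SubgroupLabel(
                ann.case_id, "HR_d", "germline_low_cellularity_override"
            )
        return SubgroupLabel(ann.case_id, "HR_MMR_intact", "germline_hrdetect_low")
    if (
        ann.hrdetect is not None
        and ann.hrdetect > thresholds.hrdetect_somatic
        and ann.somatic_hr_inactivation
    ):
        return SubgroupLabel(ann.case_id, "HR_d", "somatic_hrdetect_high")
    return SubgroupLabel(ann.case_id, "HR_MMR_intact", "default_intact")


def classify_table(
    annotations: list[MolecularAnnotation],
    thresholds: ClassifierThresholds = ClassifierThresholds(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify a list of cases; returns (per-case labels, subgroup counts)."""
    case_ids = [a.case_id for a in annotations]
    if len(set(case_ids)) != len(case_ids):
        dupes = sorted({c for c in case_ids if case_ids.count(c) > 1})
        raise ValueError(f"duplicate case_id(s): {dupes}")
    labels = [classify_case(a, thresholds) for a in annotations]
    frame = pd.DataFrame(
        {
            "case_id": [l.case_id for l in labels],
            "label": [l.label for l in labels],
            "rule_fired": [l.rule_fired for l in labels],
        }
    )
    counts = {lab: int((frame["label"] == lab).sum()) for lab in LABELS}
    return frame, counts


def annotations_from_frame(df: pd.DataFrame) -> list[MolecularAnnotation]:
    """Build annotations from a TSV-style table (one row per case).

    Expected columns: case_id, germline_hr_gene, somatic_hr_inactivation,
    hrdetect, low_cellularity, germline_mmr_gene, mlh1, msh2, msh6, pms2,
    msisensor. Empty strings / NaN mean "not available".
    """

    def opt_str(v):
        return None if pd.isna(v) or v == "" else str(v)

    def opt_float(v):
        return None if pd.isna(v) or v == "" else float(v)

    def as_bool(v):
        if isinstance(v, str):
            return v.strip().lower() in ("true", "1", "yes")
        return bool(v) and not pd.isna(v)

    anns = []
    for _, row in df.iterrows():
        ihc = {}
        for protein in MMR_GENES:
            state = opt_str(row.get(protein.lower()))
            ihc[protein] = state if state is not None else "not_assessed"
        anns.append(
            MolecularAnnotation(
                case_id=str(row["case_id"]),
                germline_hr_gene=opt_str(row.get("germline_hr_gene")),
                somatic_hr_inactivation=as_bool(row.get("somatic_hr_inactivation")),
                hrdetect=opt_float(row.get("hrdetect")),
                low_cellularity_override=as_bool(row.get("low_cellularity")),
                germline_mmr_gene=opt_str(row.get("germline_mmr_gene")),
                mmr_ihc=ihc,
                msisensor=opt_float(row.get("msisensor")),
            )
        )
    return anns


def load_reference_annotations() -> list[MolecularAnnotation]:
    """Load the bundled 26-case HR-d/MMR-d reference annotation table.

    These are the published molecular annotations of the HR-deficient and
    MMR-deficient pancreatic cancer cases the classifier rules were
    designed around (germline variant carriers, somatic-only cases, the
    low-cellularity PALB2 case, and one MSH2/MSH6-deficient case).
    """
    with resources.files("pdactme.data").joinpath(REFERENCE_ANNOTATIONS).open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    return annotations_from_frame(df)
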