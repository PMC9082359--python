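"""Group-comparison and survival statistics.

Continuous metrics are compared between subgroups with the two-sided
Wilcoxon rank-sum test (exact enumeration for small tie-free samples,
tie-corrected normal approximation otherwise), proportions with Fisher's
exact test, and overall survival with Kaplan-Meier curves and the
two-group log-rank test. P-values are reported unadjusted; a
Benjamini-Hochberg option exists for reuse outside the original design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .cells import IMMUNE_PHENOTYPES
from .zones import ZONES

#: exact Wilcoxon enumeration is used up to this combined sample size
EXACT_WILCOXON_MAX_N = 20


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts with rows = groups and columns = outcome yes/no."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("contingency table is empty")


@dataclass
class KmResult:
    medians: dict[str, float]
    p_value: float
    n: dict[str, int]
    events: dict[str, int]


def wilcoxon_compare(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value for two samples.

    Uses exact enumeration when the combined sample size is at most
    ``EXACT_WILCOXON_MAX_N`` and there are no ties, and the tie-corrected
    normal approximation otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= EXACT_WILCOXON_MAX_N and not has_ties:
        method = "exact"
    else:
        method = "asymptotic"
    return float(sps.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def fisher_exact(table: ContingencyTable2x2, alternative: str = "two-sided") -> float:
    """Fisher's exact p-value for a 2x2 table.

    Two-sided by default: sums hypergeometric probabilities of all tables
    with the observed margins whose probability does not exceed the
    observed table's. Degenerate margins give p = 1.0 with a warning.
    """
    t = table
    if (t.a + t.b == 0) or (t.c + t.d == 0) or (t.a + t.c == 0) or (t.b + t.d == 0):
        warnings.warn("degenerate 2x2 margins: Fisher test undefined, p = 1.0",
                      stacklevel=2)
        return 1.0
    res = sps.fisher_exact([[t.a, t.b], [t.c, t.d]], alternative=alternative)
    return float(res.pvalue)


def km_logrank(
    records: pd.DataFrame,
    groups: tuple[str, str],
    exclude_cases: tuple[str, ...] = (),
) -> KmResult:
    """Kaplan-Meier medians per group plus the two-group log-rank p-value.

    ``records`` has columns case_id, time_months, event, group. The median
    is the earliest time at which the survival curve drops to 0.5 or
    below; NaN when the curve never reaches 0.5. Cases listed in
    ``exclude_cases`` are dropped before fitting.
    """
    df = records[~records["case_id"].isin(exclude_cases)]
    medians: dict[str, float] = {}
    n: dict[str, int] = {}
    events: dict[str, int] = {}
    per_group = {}
    for g in groups:
        sub = df[df["group"] == g]
        if sub.empty:
            raise ValueError(f"survival group {g!r} has no records")
        per_group[g] = sub
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_months"], event_observed=sub["event"])
        medians[g] = float(kmf.median_survival_time_)
        n[g] = int(len(sub))
        events[g] = int(sub["event"].sum())
    res = logrank_test(
        per_group[groups[0]]["time_months"],
        per_group[groups[1]]["time_months"],
        event_observed_A=per_group[groups[0]]["event"],
        event_observed_B=per_group[groups[1]]["event"],
    )
    return KmResult(medians=medians, p_value=float(res.p_value), n=n, events=events)


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    # sample SD (n-1), matching mean ± SD presentation
    v = values[np.isfinite(values)]
    if v.size == 0:
        return float("nan"), float("nan")
    sd = float(np.std(v, ddof=1)) if v.size > 1 else float("nan")
    return float(np.mean(v)), sd


@dataclass
class CohortResult:
    """Structured group-comparison report."""

    groups: tuple[str, str]
    density_comparisons: pd.DataFrame = field(default_factory=pd.DataFrame)
    ratio_comparison: dict = field(default_factory=dict)
    cps_comparison: dict = field(default_factory=dict)
    survival: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "groups": list(self.groups),
            "density_comparisons": self.density_comparisons.to_dict("records"),
            "ratio_comparison": self.ratio_comparison,
            "cps_comparison": self.cps_comparison,
            "survival": self.survival,
        }


def compare_cohort(
    metrics: pd.DataFrame,
    labels: pd.DataFrame,
    survival: pd.DataFrame | None = None,
    groups: tuple[str, str] = ("HR_d", "HR_MMR_intact"),
    survival_exclude: tuple[str, ...] = (),
    adjust: bool = False,
) -> CohortResult:
    """Full two-group comparison of per-case immune metrics.

    For every (phenotype, zone) density: group mean ± SD and the Wilcoxon
    p-value on the raw densities. Adds the CD8:FOXP3 ratio comparison, the
    PD-L1 CPS mean comparison with the Fisher test on CPS ≥ 1 positivity,
    and, when survival records are given, Kaplan-Meier medians with the
    log-rank p-value. Comparisons with an empty group are marked not
    evaluable instead of aborting. ``adjust=True`` appends
    Benjamini-Hochberg-adjusted q-values for the density comparisons.
    """
    merged = metrics.merge(labels[["case_id", "label"]], on="case_id", how="left")
    ga = merged[merged["label"] == groups[0]]
    gb = merged[merged["label"] == groups[1]]

    rows = []
    for ph in IMMUNE_PHENOTYPES:
        for zone in ZONES:
            col = f"density_{ph}_{zone}"
            if col not in merged.columns:
                continue
            va = ga[col].dropna().to_numpy(dtype=float)
            vb = gb[col].dropna().to_numpy(dtype=float)
            mean_a, sd_a = _mean_sd(va)
            mean_b, sd_b = _mean_sd(vb)
            evaluable = va.size > 0 and vb.size > 0
            rows.append(
                {
                    "phenotype": ph,
                    "zone": zone,
                    f"mean_{groups[0]}": mean_a,
                    f"sd_{groups[0]}": sd_a,
                    f"mean_{groups[1]}": mean_b,
                    f"sd_{groups[1]}": sd_b,
                    "p_value": wilcoxon_compare(va, vb) if evaluable else float("nan"),
                    "evaluable": evaluable,
                }
            )
    density_df = pd.DataFrame(rows)
    if adjust and not density_df.empty:
        mask = density_df["evaluable"].to_numpy()
        q = np.full(len(density_df), np.nan)
        if mask.any():
            q[mask] = multipletests(
                density_df.loc[mask, "p_value"], method="fdr_bh"
            )[1]
        density_df["q_value"] = q

    def scalar_comparison(col: str) -> dict:
        va = ga[col].dropna().to_numpy(dtype=float)
        vb = gb[col].dropna().to_numpy(dtype=float)
        if va.size == 0 or vb.size == 0:
            return {"evaluable": False}
        mean_a, sd_a = _mean_sd(va)
        mean_b, sd_b = _mean_sd(vb)
        return {
            "evaluable": True,
            f"mean_{groups[0]}": mean_a,
            f"sd_{groups[0]}": sd_a,
            f"mean_{groups[1]}": mean_b,
            f"sd_{groups[1]}": sd_b,
            "p_value": wilcoxon_compare(va, vb),
        }

    ratio = (
        scalar_comparison("cd8_foxp3_ratio")
        if "cd8_foxp3_ratio" in merged.columns
        else {"evaluable": False}
    )

    cps_cmp: dict = {"evaluable": False}
    if "cps" in merged.columns:
        cps_cmp = scalar_comparison("cps")
        pa = ga["cps_positive"].dropna()
        pb = gb["cps_positive"].dropna()
        if len(pa) and len(pb):
            table = ContingencyTable2x2(
                a=int(pa.sum()), b=int((~pa.astype(bool)).sum()),
                c=int(pb.sum()), d=int((~pb.astype(bool)).sum()),
            )
            cps_cmp["positivity_table"] = [[table.a, table.b], [table.c, table.d]]
            cps_cmp["positivity_p_value"] = fisher_exact(table)

    surv: dict = {"evaluable": False}
    if survival is not None and not survival.empty:
        try:
            km = km_logrank(survival, groups, exclude_cases=survival_exclude)
            surv = {
                "evaluable": True,
                "medians": km.medians,
                "logrank_p_value": km.p_value,
                "n": km.n,
                "events": km.events,
            }
        except ValueError as exc:
            surv = {"evaluable": False, "reason": str(exc)}

    return CohortResult(
        groups=groups,
        density_comparisons=density_df,
        ratio_comparison=ratio,
        cps_comparison=cps_cmp,
        survival=surv,
    )
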