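"""Wilcoxon, Fisher, Kaplan-Meier/log-rank and the cohort report."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pdactme.stats import (
    ContingencyTable2x2,
    compare_cohort,
    fisher_exact,
    km_logrank,
    wilcoxon_compare,
)


def brute_fisher_two_sided(a, b, c, d):
    """Independent oracle: enumerate all tables with the observed margins
    and sum hypergeometric probabilities <= the observed table's."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    kmin = max(0, col1 - (n - row1))
    kmax = min(row1, col1)
    ks = np.arange(kmin, kmax + 1)
    pmf = sps.hypergeom.pmf(ks, n, row1, col1)
    p_obs = sps.hypergeom.pmf(a, n, row1, col1)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


def brute_wilcoxon_two_sided(x, y):
    """Exact two-sided rank-sum p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    ranks = sps.rankdata(pooled)
    u_obs = ranks[:n].sum() - n * (n + 1) / 2
    us = []
    for idx in itertools.combinations(range(n + m), n):
        u = ranks[list(idx)].sum() - n * (n + 1) / 2
        us.append(u)
    us = np.asarray(us)
    p_low = np.mean(us <= u_obs)
    p_high = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_identical_samples_give_p_one(self):
        assert wilcoxon_compare([1, 2, 3], [1, 2, 3]) == 1.0

    def test_fully_separated_small_samples_exact(self):
        # 2 of the C(6,3)=20 equally likely rank assignments are as extreme
        assert wilcoxon_compare([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_invariant_under_monotone_transform(self, rng):
        a = rng.normal(size=8)
        b = rng.normal(1.0, size=9)
        p1 = wilcoxon_compare(a, b)
        p2 = wilcoxon_compare(np.exp(a), np.exp(b))
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_compare([], [1.0])

    @pytest.mark.parametrize("n,m", [(3, 4), (5, 5), (6, 6), (4, 8)])
    def test_exact_branch_matches_full_enumeration(self, n, m, rng):
        x = rng.normal(size=n)
        y = rng.normal(0.8, size=m)
        assert wilcoxon_compare(x, y) == pytest.approx(
            brute_wilcoxon_two_sided(x, y), abs=1e-12
        )


class TestFisher:
    def test_headline_pdl1_table(self):
        # 6/25 vs 0/163 positivity
        p = fisher_exact(ContingencyTable2x2(6, 19, 0, 163))
        assert p == pytest.approx(3.13e-6, rel=0.01)

    def test_diagonal_singleton_table(self):
        assert fisher_exact(ContingencyTable2x2(1, 0, 0, 1)) == pytest.approx(1.0)

    def test_symmetry_under_row_and_column_swap(self):
        p1 = fisher_exact(ContingencyTable2x2(5, 2, 1, 9))
        p2 = fisher_exact(ContingencyTable2x2(9, 1, 2, 5))
        assert p1 == pytest.approx(p2)

    def test_degenerate_margin_warns_p_one(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert fisher_exact(ContingencyTable2x2(0, 0, 3, 4)) == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)

    def test_matches_enumeration_oracle_on_random_tables(self, rng):
        for _ in range(50):
            a, b, c, d = rng.integers(0, 12, size=4)
            if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
                continue
            p = fisher_exact(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            assert p == pytest.approx(
                brute_fisher_two_sided(int(a), int(b), int(c), int(d)), rel=1e-6
            )


class TestKaplanMeier:
    def test_median_of_ten_uncensored_times(self):
        rec = pd.DataFrame(
            {
                "case_id": [f"c{i}" for i in range(10)],
                "time_months": list(range(1, 11)),
                "event": [True] * 10,
                "group": ["g1"] * 10,
            }
        )
        rec2 = rec.copy()
        rec2["case_id"] = [f"d{i}" for i in range(10)]
        rec2["group"] = "g2"
        res = km_logrank(pd.concat([rec, rec2]), ("g1", "g2"))
        # S(5) = 0.5: first time survival drops to <= 1/2
        assert res.medians["g1"] == 5.0
        assert res.p_value == pytest.approx(1.0, abs=0.05)

    def test_all_censored_curve_never_reaches_half(self):
        rec = pd.DataFrame(
            {
                "case_id": ["a", "b", "c", "d"],
                "time_months": [60.0] * 4,
                "event": [False] * 4,
                "group": ["g1"] * 4,
            }
        )
        rec2 = rec.copy()
        rec2["case_id"] = ["e", "f", "g", "h"]
        rec2["group"] = "g2"
        rec2["event"] = True
        res = km_logrank(pd.concat([rec, rec2]), ("g1", "g2"))
        assert math.isinf(res.medians["g1"])

    def test_exclusion_list_removes_cases(self):
        rec = pd.DataFrame(
            {
                "case_id": ["a", "b", "c", "d"],
                "time_months": [5.0, 10.0, 15.0, 20.0],
                "event": [True] * 4,
                "group": ["g1", "g1", "g2", "g2"],
            }
        )
        res = km_logrank(rec, ("g1", "g2"), exclude_cases=("a",))
        assert res.n["g1"] == 1

    def test_empty_group_rejected(self):
        rec = pd.DataFrame(
            {
                "case_id": ["a"],
                "time_months": [5.0],
                "event": [True],
                "group": ["g1"],
            }
        )
        with pytest.raises(ValueError):
            km_logrank(rec, ("g1", "g2"))

    def test_logrank_null_p_values_average_one_half(self, rng):
        # identical survival distributions: p approximately uniform
        ps = []
        for _ in range(300):
            t1 = rng.exponential(20, 30)
            t2 = rng.exponential(20, 30)
            rec = pd.DataFrame(
                {
                    "case_id": [f"x{i}" for i in range(60)],
                    "time_months": np.concatenate([t1, t2]),
                    "event": [True] * 60,
                    "group": ["g1"] * 30 + ["g2"] * 30,
                }
            )
            ps.append(km_logrank(rec, ("g1", "g2")).p_value)
        assert np.mean(ps) == pytest.approx(0.5, abs=0.06)


class TestCompareCohort:
    @staticmethod
    def _toy_inputs(rng, n_a=8, n_b=8):
        cases = [f"a{i}" for i in range(n_a)] + [f"b{i}" for i in range(n_b)]
        metrics = pd.DataFrame({"case_id": cases})
        for ph in ("CD8", "FOXP3", "CD68"):
            for zone in ("intra_tumoral", "peri_tumoral", "stromal"):
                metrics[f"density_{ph}_{zone}"] = rng.uniform(0, 100, len(cases))
        metrics["cd8_foxp3_ratio"] = rng.uniform(0, 30, len(cases))
        metrics["cps"] = rng.uniform(0, 3, len(cases))
        metrics["cps_positive"] = metrics["cps"] >= 1
        labels = pd.DataFrame(
            {"case_id": cases, "label": ["HR_d"] * n_a + ["HR_MMR_intact"] * n_b}
        )
        survival = pd.DataFrame(
            {
                "case_id": cases,
                "time_months": rng.exponential(20, len(cases)),
                "event": True,
                "group": labels["label"],
            }
        )
        return metrics, labels, survival

    def test_report_covers_all_phenotype_zone_combinations(self, rng):
        metrics, labels, survival = self._toy_inputs(rng)
        res = compare_cohort(metrics, labels, survival)
        assert len(res.density_comparisons) == 9  # 3 phenotypes x 3 zones
        assert res.ratio_comparison["evaluable"]
        assert res.cps_comparison["evaluable"]
        assert "positivity_p_value" in res.cps_comparison
        assert res.survival["evaluable"]

    def test_empty_group_marked_not_evaluable(self, rng):
        metrics, labels, survival = self._toy_inputs(rng)
        labels["label"] = "HR_MMR_intact"  # one group vanishes
        survival["group"] = "HR_MMR_intact"
        res = compare_cohort(metrics, labels, survival)
        assert not res.density_comparisons["evaluable"].any()
        assert res.survival["evaluable"] is False

    def test_bh_adjustment_optional_column(self, rng):
        metrics, labels, survival = self._toy_inputs(rng)
        res = compare_cohort(metrics, labels, adjust=True)
        assert "q_value" in res.density_comparisons.columns
        assert (
            res.density_comparisons["q_value"]
            >= res.density_comparisons["p_value"] - 1e-12
        ).all()
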