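"""Demographic/clinical comparison machinery against hand computations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from padtrack.cohort_stats import (
    attrition_report,
    chi_square,
    chi_square_yates,
    dunn_pairwise,
    kruskal_wallis,
    subclinical_rate,
)
from padtrack.config import SimulationConfig
from padtrack.simulate import simulate_cohort


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        res = kruskal_wallis([np.array([1, 1, 2]), np.array([1, 2, 1])])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_all_values_identical_degenerate(self):
        res = kruskal_wallis([np.array([2.0, 2.0]), np.array([2.0, 2.0])])
        assert res.statistic == 0.0 and res.p == 1.0

    def test_tie_free_rank_arithmetic(self):
        res = kruskal_wallis([np.array([1, 2, 3]), np.array([4, 5, 6])])
        assert res.statistic == pytest.approx(3.857, abs=1e-3)
        assert res.df == 1

    def test_two_group_h_equals_squared_ranksum_z(self, rng):
        """Tie-free two-group identity: H = z^2 of the rank-sum test."""
        a, b = rng.normal(size=8), rng.normal(size=11) + 0.5
        h = kruskal_wallis([a, b]).statistic
        n1, n2 = len(a), len(b)
        ranks = stats.rankdata(np.concatenate([a, b]))
        w = ranks[:n1].sum()
        z = (w - n1 * (n1 + n2 + 1) / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert h == pytest.approx(z**2, abs=1e-10)

    def test_label_permutation_leaves_null_distribution_invariant(self, rng):
        """Monte-Carlo: H on permuted labels matches the chi-square null."""
        pooled = rng.normal(size=30)
        stats_h = []
        for _ in range(300):
            perm = rng.permutation(pooled)
            stats_h.append(kruskal_wallis([perm[:10], perm[10:20], perm[20:]]).statistic)
        # mean of chi2(2) is 2
        assert np.mean(stats_h) == pytest.approx(2.0, abs=0.35)


class TestDunn:
    def test_identical_groups_z_zero(self):
        out = dunn_pairwise([np.array([1, 2, 3]), np.array([1, 2, 3])])
        assert out["z"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=9)
        z_ab = dunn_pairwise([a, b])["z"].iloc[0]
        z_ba = dunn_pairwise([b, a])["z"].iloc[0]
        assert z_ab == pytest.approx(-z_ba, abs=1e-12)

    def test_three_group_pooled_rank_oracle(self):
        groups = [np.array([1.0, 3.0, 5.0]), np.array([2.0, 4.0, 6.0]), np.array([7.0, 8.0, 9.0])]
        out = dunn_pairwise(groups, labels=["a", "b", "c"])
        pooled = np.concatenate(groups)
        ranks = stats.rankdata(pooled)
        n = len(pooled)
        mr = [ranks[:3].mean(), ranks[3:6].mean(), ranks[6:].mean()]
        se = np.sqrt((n * (n + 1) / 12.0) * (2 / 3))
        expected = (mr[0] - mr[1]) / se
        assert out.set_index(["group_a", "group_b"]).loc[("a", "b"), "z"] == pytest.approx(
            expected, abs=1e-10
        )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            dunn_pairwise([np.array([1.0]), np.array([])])


class TestChiSquare:
    def test_attrition_tables_reproduce_study_statistics(self):
        # HR-MD vs C-well and HR-MD vs HR-well retention tables
        assert chi_square_yates([[31, 4], [46, 47]]).statistic == pytest.approx(14.6, abs=0.05)
        assert chi_square_yates([[31, 4], [47, 27]]).statistic == pytest.approx(6.2, abs=0.05)

    def test_proportional_table_floors_at_zero(self):
        res = chi_square_yates([[10, 10], [20, 20]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError):
            chi_square_yates([[0, 0], [5, 3]])

    @pytest.mark.parametrize("seed", range(6))
    def test_yates_never_exceeds_pearson(self, seed):
        rng = np.random.default_rng(seed)
        table = rng.integers(1, 40, size=(2, 2))
        yates = chi_square_yates(table).statistic
        pearson = chi_square(table).statistic
        assert yates <= pearson + 1e-12


class TestAttrition:
    def test_default_cohort_attrition_percents(self, default_cohort):
        report = attrition_report(default_cohort)
        assert report.attrition_percent["C-well"] == pytest.approx(50.5, abs=0.05)
        assert report.attrition_percent["HR-well"] == pytest.approx(36.5, abs=0.05)
        assert report.attrition_percent["HR-MD"] == pytest.approx(11.4, abs=0.05)
        pw = report.pairwise.set_index(["group_a", "group_b"])
        assert pw.loc[("C-well", "HR-MD"), "chi2"] == pytest.approx(14.6, abs=0.05)
        assert pw.loc[("HR-well", "HR-MD"), "chi2"] == pytest.approx(6.2, abs=0.05)
        assert pw.loc[("C-well", "HR-well"), "chi2"] == pytest.approx(2.8, abs=0.05)

    def test_pairwise_tables_sum_to_baseline_ns(self, default_cohort):
        report = attrition_report(default_cohort)
        base = default_cohort.group_sizes("t1")
        fu = default_cohort.group_sizes("t2")
        for _, row in report.pairwise.iterrows():
            total = base[row["group_a"]] + base[row["group_b"]]
            assert total == sum(base[g] for g in (row["group_a"], row["group_b"]))
            assert fu[row["group_a"]] <= base[row["group_a"]]

    def test_full_followup_gives_zero_attrition(self):
        cfg = SimulationConfig(group_sizes=(6, 5, 4), followup_counts=(6, 5, 4))
        report = attrition_report(simulate_cohort(cfg))
        assert all(p == 0.0 for p in report.attrition_percent.values())
        assert (report.pairwise["chi2"] == 0.0).all()

    def test_report_roundtrips_through_serialisation(self, default_cohort):
        report = attrition_report(default_cohort)
        d = report.to_dict()
        for g, pct in d["attrition_percent"].items():
            recomputed = 100.0 * (d["baseline_n"][g] - d["followup_n"][g]) / d["baseline_n"][g]
            assert pct == pytest.approx(recomputed, abs=1e-12)


class TestSubclinicalRate:
    def test_study_rates_from_counts(self):
        hrmd = [8] * 7 + [0] * 28  # 7 of 35 above threshold
        assert subclinical_rate(hrmd) == pytest.approx(0.20)
        well = [9] * 2 + [0] * 165  # 2 of 167
        assert subclinical_rate(well) == pytest.approx(2 / 167)

    def test_threshold_is_strict(self):
        assert subclinical_rate([7, 7, 7]) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            subclinical_rate([])
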