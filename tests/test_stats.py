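"""Ordered-trend, paired, multi-group, correlation and mediation tests."""

import numpy as np
import pandas as pd
import pytest

from lungwater.cohort import (
    DEFAULT_COHORT_CONFIG,
    GROUP_ORDER,
    CohortTable,
    synthesize_cohort,
)
from lungwater.stats import (
    jonckheere_terpstra,
    jt_statistic,
    kruskal_wallis_dunn,
    mediation_bootstrap,
    pearson_linreg,
    wilcoxon_signed_rank,
)
from lungwater.validation import (
    jt_exact_p_enumeration,
    wilcoxon_exact_p_enumeration,
)


class TestJonckheereTerpstra:
    def test_perfectly_ordered_groups(self):
        groups = [np.array([1.0, 2.0]), np.array([3.0, 4.0]), np.array([5.0, 6.0])]
        res = jonckheere_terpstra(groups, method="exact")
        assert res.statistic == 12.0  # all 12 between-group pairs concordant
        # J = 12 is the maximum, so the one-sided p is the smallest attainable
        _, p_enum, _ = jt_exact_p_enumeration(groups)
        assert res.p_one_sided == pytest.approx(p_enum, abs=1e-12)

    def test_reversed_ordering_gives_zero(self):
        assert jt_statistic(
            [np.array([5.0, 6.0]), np.array([3.0, 4.0]), np.array([1.0, 2.0])]
        ) == 0.0

    def test_all_ties_give_half_the_pairs(self):
        groups = [np.array([1.0, 1.0]), np.array([1.0]), np.array([1.0, 1.0])]
        # 2*1 + 2*2 + 1*2 = 8 between-group pairs
        assert jt_statistic(groups) == 4.0

    def test_exact_equals_full_enumeration(self):
        rng = np.random.default_rng(0)
        for _ in range(15):
            sizes = rng.integers(2, 4, size=3)
            vals = rng.standard_normal(int(sizes.sum()))
            groups = np.split(vals, np.cumsum(sizes)[:-1])
            res = jonckheere_terpstra(groups, method="exact")
            j, p1, p2 = jt_exact_p_enumeration(groups)
            assert res.statistic == pytest.approx(j)
            assert res.p_one_sided == pytest.approx(p1, abs=1e-12)
            assert res.p_two_sided == pytest.approx(p2, abs=1e-12)

    def test_antisymmetry_under_order_reversal(self):
        rng = np.random.default_rng(1)
        groups = [rng.standard_normal(4) for _ in range(3)]
        total_pairs = 4 * 4 * 3  # sum over pairs of n_g * n_h
        j = jt_statistic(groups)
        j_rev = jt_statistic(groups[::-1])
        assert j + j_rev == pytest.approx(total_pairs)

    def test_permutation_agrees_with_exact(self):
        rng = np.random.default_rng(2)
        groups = [rng.standard_normal(4) + i for i in range(3)]
        pe = jonckheere_terpstra(groups, method="exact").p_one_sided
        pp = jonckheere_terpstra(groups, method="permutation",
                                 n_perm=20000, seed=0).p_one_sided
        assert pp == pytest.approx(pe, abs=0.01)

    def test_permutation_type_one_error_calibrated(self):
        # null: identical distributions; rejection rate at alpha = 0.05
        # should sit in [0.03, 0.07] over 1000 simulations
        rej = 0
        n_sims = 1000
        for sim in range(n_sims):
            rng = np.random.default_rng(10_000 + sim)
            groups = [rng.standard_normal(6) for _ in range(4)]
            p = jonckheere_terpstra(groups, method="permutation",
                                    n_perm=1999, seed=sim).p_two_sided
            rej += p < 0.05
        assert 0.03 <= rej / n_sims <= 0.07

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra([np.array([1.0, 2.0])])

    def test_exact_with_ties_rejected(self):
        with pytest.raises(ValueError):
            jonckheere_terpstra(
                [np.array([1.0, 1.0]), np.array([2.0, 3.0])], method="exact"
            )


class TestWilcoxon:
    def test_all_positive_n5_exact(self):
        res = wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0, 4.0, 5.0]),
                                   alternative="greater")
        assert res.p_value == pytest.approx(1 / 32)

    def test_antisymmetric_differences_at_null_center(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        res = wilcoxon_signed_rank(d)
        # W+ equals half the total rank sum for a sign-symmetric sample
        assert res.statistic == pytest.approx(np.sum(np.arange(1, 7)) / 2)

    def test_small_n_refused(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]))

    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank(np.zeros(8))

    def test_zeros_dropped_before_ranking(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        res = wilcoxon_signed_rank(d, alternative="greater")
        assert res.n_zero_dropped == 2
        assert res.n_used == 5
        assert res.p_value == pytest.approx(1 / 32)

    @pytest.mark.parametrize("alternative", ["two-sided", "greater", "less"])
    def test_exact_p_matches_sign_enumeration(self, alternative):
        rng = np.random.default_rng(3)
        for _ in range(8):
            d = rng.standard_normal(10)
            res = wilcoxon_signed_rank(d, alternative=alternative)
            assert res.p_value == pytest.approx(
                wilcoxon_exact_p_enumeration(d, alternative), abs=1e-12
            )

    def test_paired_call_signature(self):
        rest = np.array([10.0, 11.0, 12.0, 13.0, 14.0, 15.0])
        stress = rest + np.array([1.0, 2.0, 1.5, 0.5, 2.5, 1.25])
        res = wilcoxon_signed_rank(rest, stress, alternative="greater")
        assert res.p_value == pytest.approx(1 / 64)


class TestKruskalDunn:
    def test_identically_distributed_groups_h_zero(self):
        g = [np.array([1.0, 2.0, 3.0, 4.0])] * 3
        res = kruskal_wallis_dunn(g)
        assert res.h_statistic == pytest.approx(0.0, abs=1e-12)

    def test_h_matches_hand_ranked_oracle(self):
        # disjoint ranges, n = 4 each: ranks are 1-4, 5-8, 9-12
        g = [np.array([1.0, 2.0, 3.0, 4.0]),
             np.array([10.0, 11.0, 12.0, 13.0]),
             np.array([20.0, 21.0, 22.0, 23.0])]
        n = 12
        mean_ranks = [2.5, 6.5, 10.5]
        h_hand = 12.0 / (n * (n + 1)) * sum(
            4 * (r - (n + 1) / 2) ** 2 for r in mean_ranks
        )
        res = kruskal_wallis_dunn(g)
        assert res.h_statistic == pytest.approx(h_hand, rel=1e-12)
        # extreme separation: every pairwise Dunn comparison ordered
        assert np.all(res.pairwise["z"] < 0)

    def test_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis_dunn([np.array([1.0, 2.0]), np.array([3.0, 4.0])])

    def test_holm_adjustment_monotone(self):
        rng = np.random.default_rng(4)
        g = [rng.standard_normal(6) + i for i in range(4)]
        res = kruskal_wallis_dunn(g)
        assert np.all(res.pairwise["p_adj"] >= res.pairwise["p_raw"] - 1e-15)


class TestPearsonLinreg:
    def test_perfect_line(self):
        res = pearson_linreg([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(1.0)

    def test_perfect_negative(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        res = pearson_linreg(x, -2.0 * x + 1.0)
        assert res.r == pytest.approx(-1.0)
        assert res.slope == pytest.approx(-2.0)

    def test_hand_computed_four_points(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        # manual product-moment computation: cov = 1.0, sx2 = 1.6667, sy2 = 1.6667
        r_hand = 1.0 / np.sqrt(5 / 3 * 5 / 3)
        res = pearson_linreg(x, y)
        assert res.r == pytest.approx(r_hand, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_linreg([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestMediation:
    def test_null_mediator_ci_spans_zero(self):
        rng = np.random.default_rng(5)
        n = 100
        x = rng.standard_normal(n)
        m = rng.standard_normal(n)  # independent of x
        y = x + 0.1 * rng.standard_normal(n)
        res = mediation_bootstrap(pd.DataFrame({"x": x, "m": m, "y": y}),
                                  "x", "m", "y", n_boot=2000, seed=0)
        assert res.ci_low <= 0.0 <= res.ci_high
        assert not res.significant

    def test_chain_recovery_over_seeds(self):
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            n = 200
            x = rng.standard_normal(n)
            m = x + 0.1 * rng.standard_normal(n)
            y = m + 0.1 * rng.standard_normal(n)
            res = mediation_bootstrap(pd.DataFrame({"x": x, "m": m, "y": y}),
                                      "x", "m", "y", n_boot=1000, seed=seed)
            assert 0.9 <= res.indirect_effect <= 1.1
            assert res.significant

    def test_matches_pingouin_point_estimates(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(6)
        n = 80
        x = rng.standard_normal(n)
        m = 0.7 * x + 0.5 * rng.standard_normal(n)
        y = 0.4 * x + 0.6 * m + 0.5 * rng.standard_normal(n)
        df = pd.DataFrame({"x": x, "m": m, "y": y})
        res = mediation_bootstrap(df, "x", "m", "y", n_boot=1000, seed=0)
        ref = pg.mediation_analysis(df, x="x", m="m", y="y", n_boot=200, seed=0)
        ref = ref.set_index("path")["coef"]
        assert res.indirect_effect == pytest.approx(ref["Indirect"], rel=1e-6)
        assert res.direct_effect == pytest.approx(ref["Direct"], rel=1e-6)

    def test_too_few_boot_rejected(self):
        df = pd.DataFrame({"x": np.arange(20.0), "m": np.arange(20.0) + 1,
                           "y": np.arange(20.0) + 2})
        with pytest.raises(ValueError):
            mediation_bootstrap(df, "x", "m", "y", n_boot=999)

    def test_bootstrap_deterministic_for_seed(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"x": rng.standard_normal(50),
                           "m": rng.standard_normal(50),
                           "y": rng.standard_normal(50)})
        a = mediation_bootstrap(df, "x", "m", "y", n_boot=1000, seed=3)
        b = mediation_bootstrap(df, "x", "m", "y", n_boot=1000, seed=3)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)


class TestSynthesizeCohort:
    def test_deterministic_for_seed(self):
        a = synthesize_cohort(seed=11)
        b = synthesize_cohort(seed=11)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_default_design_sizes_and_groups(self):
        ct = synthesize_cohort(seed=0)
        counts = ct.df["group"].value_counts()
        assert [counts[g] for g in GROUP_ORDER] == [11, 9, 14, 9]

    def test_medians_match_targets_at_n50(self):
        ct = synthesize_cohort(group_sizes=(50, 50, 50, 50), seed=1)
        for metric, rows in DEFAULT_COHORT_CONFIG.items():
            med = ct.df.groupby("group", observed=True)[metric].median()
            for g, (target, iqr) in zip(GROUP_ORDER, rows):
                assert med[g] == pytest.approx(target, abs=0.05 * iqr + 1e-9)

    def test_null_configuration_rarely_detects_trend(self):
        flat = {"pcr_atp": [(2.0, 0.4)] * 4}
        detected = 0
        for seed in range(100):
            ct = synthesize_cohort(flat, seed=seed)
            p = jonckheere_terpstra(ct, "pcr_atp").p_two_sided
            detected += p < 0.05
        assert detected <= 10  # no trend in >= 90% of seeds

    def test_graded_configuration_detects_trend(self):
        graded = {"m": [(0.0, 1.0), (1.0, 1.0), (2.0, 1.0), (3.0, 1.0)]}
        detected = 0
        for seed in range(40):
            ct = synthesize_cohort(graded, group_sizes=(50, 50, 50, 50),
                                   seed=seed)
            p = jonckheere_terpstra(ct, "m").p_one_sided
            detected += p < 0.05
        assert detected >= int(0.95 * 40)

    def test_csv_roundtrip(self, tmp_path):
        ct = synthesize_cohort(seed=2)
        path = tmp_path / "cohort.csv"
        ct.to_csv(path)
        back = CohortTable.from_csv(path)
        assert back.df["group"].dtype == ct.df["group"].dtype
        assert np.allclose(back.df["pcr_atp"], ct.df["pcr_atp"])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            synthesize_cohort({"m": [(0.0, 1.0)] * 3})
        with pytest.raises(ValueError):
            synthesize_cohort(group_sizes=(1, 9, 14, 9))
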