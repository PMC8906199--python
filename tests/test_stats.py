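"""Statistical kernels: exact values, library cross-checks, invariances."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from contourval.stats import (
    BoxplotSummary,
    ContingencyTable2x2,
    boxplot_summary,
    iqr_ratio,
    mcnemar,
    paired_location_test,
    paired_t,
    shapiro_wilk_p,
    wilcoxon_signed_rank,
)


class TestShapiroGate:
    def test_normal_sample_passes_gate(self):
        x = np.random.default_rng(0).standard_normal(30)
        assert shapiro_wilk_p(x) >= 0.05  # frozen fixture: p ~ 0.69

    def test_heavy_tailed_sample_fails_gate(self):
        x = np.random.default_rng(0).standard_normal(30) ** 3
        assert shapiro_wilk_p(x) < 0.05

    def test_constant_sequence_raises(self):
        with pytest.raises(ValueError):
            shapiro_wilk_p([1.0] * 10)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            shapiro_wilk_p([1.0, 2.0])


class TestWilcoxon:
    def test_enumerated_example(self):
        """d = (1,2,3,-4,5): W- = 4; 7 of the 32 sign assignments give a
        rank sum <= 4, so two-sided p = 14/32."""
        stat, p = wilcoxon_signed_rank([1, 2, 3, -4, 5])
        assert stat == 4.0
        assert p == pytest.approx(0.4375)

    def test_all_positive_extreme(self):
        stat, p = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert stat == 0.0
        assert p == pytest.approx(2 / 32)

    def test_zero_differences_dropped(self):
        stat, p = wilcoxon_signed_rank([0.0, 0.0, 1.0])
        assert stat == 0.0  # n_effective = 1
        assert p == 1.0     # 2 * (1/2) capped

    def test_all_zero_raises(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([0.0, 0.0])

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_scipy_exact_without_ties(self, seed):
        from scipy import stats as sps
        rng = np.random.default_rng(seed)
        d = rng.standard_normal(12)  # continuous -> no ties almost surely
        stat, p = wilcoxon_signed_rank(d)
        ref = sps.wilcoxon(d, alternative="two-sided", mode="exact")
        assert stat == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_handles_midrank_ties(self):
        # tied |d| -> half-integer midranks; p must stay a valid probability
        # and match direct enumeration over sign assignments
        d = np.array([1.0, 1.0, -1.0, 2.0, 2.0])
        stat, p = wilcoxon_signed_rank(d)
        from scipy.stats import rankdata
        ranks = rankdata(np.abs(d))
        total = 0
        n = len(d)
        w_obs = min(ranks[d > 0].sum(), ranks[d < 0].sum())
        for signs in range(2 ** n):
            w_plus = sum(r for k, r in enumerate(ranks) if (signs >> k) & 1)
            if w_plus <= w_obs:
                total += 1
        assert p == pytest.approx(min(1.0, 2 * total / 2 ** n))

    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_exact_close_to_normal_approximation_at_n25(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.standard_normal(25) + 0.3
        _, p_exact = wilcoxon_signed_rank(d, exact_max_n=25)
        _, p_approx = wilcoxon_signed_rank(d, exact_max_n=0)
        assert abs(p_exact - p_approx) <= 0.02


class TestPairedT:
    def test_symmetric_differences_give_t_zero(self):
        t, p = paired_t([-1.0, 1.0])
        assert t == 0.0 and p == 1.0

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            paired_t([1.0, 1.0, 1.0, 1.0])

    def test_matches_textbook_formula(self):
        from scipy import stats as sps
        d = np.random.default_rng(5).standard_normal(30) + 0.4
        t, p = paired_t(d)
        n = len(d)
        t_ref = d.mean() / (d.std(ddof=1) / math.sqrt(n))
        p_ref = 2 * sps.t.sf(abs(t_ref), n - 1)
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert p == pytest.approx(p_ref, abs=1e-12)


class TestPairedLocationTest:
    def test_equal_pairs_propagate_degenerate_error(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError, match="zero"):
            paired_location_test(x, x)

    def test_normal_differences_select_t_branch(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(30)
        x = y + rng.standard_normal(30) * 0.5 + 0.2
        res = paired_location_test(x, y)
        assert res.test_name == "paired_t"
        assert res.normality_p >= 0.05

    def test_skewed_differences_select_wilcoxon_branch(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(30)
        x = y + rng.standard_normal(30) ** 3
        res = paired_location_test(x, y)
        assert res.test_name == "wilcoxon_signed_rank"
        assert res.normality_p < 0.05

    @pytest.mark.parametrize("seed", [0, 7])
    def test_swap_antisymmetry(self, seed):
        """Swapping x and y flips the t statistic's sign and leaves p
        unchanged in both branches."""
        rng = np.random.default_rng(seed)
        y = rng.standard_normal(30)
        x = y + rng.standard_normal(30) * 0.4 + 0.3
        a = paired_location_test(x, y)
        b = paired_location_test(y, x)
        assert a.test_name == b.test_name
        assert a.p_value == pytest.approx(b.p_value)
        if a.test_name == "paired_t":
            assert a.statistic == pytest.approx(-b.statistic)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            paired_location_test([1, 2, 3], [1, 2])


class TestMcNemar:
    def test_study_regime_table(self):
        """Discordant cells (4, 8) over 96 pairs: both methods round to
        p = 0.39."""
        t = ContingencyTable2x2(3, 4, 8, 81)
        assert mcnemar(t, "exact") == pytest.approx(0.3877, abs=5e-5)
        assert mcnemar(t, "chi2_cc") == pytest.approx(0.3865, abs=5e-5)
        assert round(mcnemar(t, "exact"), 2) == 0.39
        assert round(mcnemar(t, "chi2_cc"), 2) == 0.39

    def test_binomial_tail_example(self):
        t = ContingencyTable2x2(0, 1, 9, 0)
        assert mcnemar(t, "exact") == pytest.approx(2 * 11 / 1024)

    def test_balanced_discordance_gives_one(self):
        for k in (1, 5, 20):
            assert mcnemar(ContingencyTable2x2(0, k, k, 0), "exact") == 1.0

    def test_no_discordance(self):
        t = ContingencyTable2x2(10, 0, 0, 50)
        assert mcnemar(t, "exact") == 1.0
        with pytest.raises(ValueError):
            mcnemar(t, "chi2_cc")

    def test_symmetric_in_b_and_c(self):
        a = ContingencyTable2x2(3, 4, 8, 81)
        b = ContingencyTable2x2(3, 8, 4, 81)
        for method in ("exact", "chi2_cc"):
            assert mcnemar(a, method) == pytest.approx(mcnemar(b, method))

    def test_monotone_in_discordance_imbalance(self):
        """At fixed b + c, the exact p never increases as |b - c| grows."""
        n = 12
        ps = [mcnemar(ContingencyTable2x2(0, b, n - b, 0), "exact")
              for b in range(n // 2, -1, -1)]
        assert all(p1 >= p2 - 1e-15 for p1, p2 in zip(ps, ps[1:]))

    @pytest.mark.parametrize("cells", [(3, 4, 8, 81), (0, 1, 9, 0), (2, 7, 7, 5)])
    def test_cross_check_against_statsmodels(self, cells):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        t = ContingencyTable2x2(*cells)
        b, c = t.discordant
        table = [[t.n_nn, t.n_ny], [t.n_yn, t.n_yy]]
        assert mcnemar(t, "exact") == pytest.approx(
            float(sm.mcnemar(table, exact=True).pvalue), abs=1e-12)
        if b + c > 0 and b != c:
            assert mcnemar(t, "chi2_cc") == pytest.approx(
                float(sm.mcnemar(table, exact=False, correction=True).pvalue),
                abs=1e-12)


class TestDispersionSummaries:
    def test_iqr_ratio_identity_and_scale(self):
        rng = np.random.default_rng(1)
        y = rng.standard_normal(50)
        assert iqr_ratio(y, y) == pytest.approx(1.0)
        assert iqr_ratio(2 * y, y) == pytest.approx(2.0)

    def test_iqr_ratio_matches_quantile_formula(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal(31), rng.standard_normal(27) * 1.7
        want = (np.quantile(x, 0.75) - np.quantile(x, 0.25)) / (
            np.quantile(y, 0.75) - np.quantile(y, 0.25))
        assert iqr_ratio(x, y) == pytest.approx(want, abs=1e-12)

    def test_iqr_zero_reference_raises(self):
        with pytest.raises(ValueError):
            iqr_ratio([1.0, 2, 3, 4], [5.0, 5, 5, 5])

    def test_boxplot_constant_vector(self):
        s = boxplot_summary([3.0] * 8)
        assert s.median == s.q1 == s.q3 == s.p5 == s.p95 == 3.0
        assert s.outliers == ()

    def test_boxplot_1_to_100(self):
        s = boxplot_summary(np.arange(1.0, 101.0))
        assert s.median == 50.5
        assert s.p5 <= s.q1 <= s.median <= s.q3 <= s.p95

    def test_boxplot_outlier_flagging(self):
        x = np.random.default_rng(3).standard_normal(30)
        s = boxplot_summary(x)
        # points outside the 5th-95th band: at most ~10% plus interpolation edge
        assert len(s.outliers) <= 4
        assert all(v < s.p5 or v > s.p95 for v in s.outliers)
        for level, attr in [(0.05, "p5"), (0.25, "q1"), (0.5, "median"),
                            (0.75, "q3"), (0.95, "p95")]:
            assert getattr(s, attr) == pytest.approx(np.quantile(x, level))


@settings(max_examples=50, deadline=None, derandomize=True)
@given(b=st.integers(0, 30), c=st.integers(0, 30))
def test_mcnemar_exact_is_probability(b, c):
    p = mcnemar(ContingencyTable2x2(0, b, c, 0), "exact")
    assert 0.0 <= p <= 1.0
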