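"""ICC(2,1), Wilcoxon signed-rank, PPV and sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cortigap.errors import UndefinedMetricError
from cortigap.reliability_stats import (
    PairedJointTable,
    icc_strength_label,
    icc_two_way_random_absolute,
    joint_level_report,
    ppv,
    sensitivity,
    wilcoxon_signed_rank,
)


def longhand_icc_a1(Y: np.ndarray):
    """Two-way ANOVA by explicit sums of squares (independent arithmetic)."""
    n, k = Y.shape
    grand = Y.mean()
    msr = k * ((Y.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    msc = n * ((Y.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    sse = ((Y - Y.mean(axis=1, keepdims=True) - Y.mean(axis=0, keepdims=True) + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_perfect_agreement_is_one(self):
        a = np.array([3.0, 7.0, 1.0, 9.0, 4.0])
        icc, lo, hi = icc_two_way_random_absolute(PairedJointTable(a, a.copy()))
        assert icc == pytest.approx(1.0)

    def test_matches_longhand_anova_on_4x2_table(self):
        A = np.array([9.0, 1.0, 8.0, 2.0])
        B = np.array([2.0, 5.0, 6.0, 8.0])
        icc, _, _ = icc_two_way_random_absolute(PairedJointTable(A, B))
        assert icc == pytest.approx(longhand_icc_a1(np.column_stack([A, B])), abs=1e-10)

    def test_matches_pingouin_including_confidence_interval(self):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(9)
        a = rng.normal(20, 6, 12)
        b = a + rng.normal(0, 3, 12)
        icc, lo, hi = icc_two_way_random_absolute(PairedJointTable(a, b))
        df = pd.DataFrame(
            {"targets": list(range(12)) * 2, "raters": ["a"] * 12 + ["b"] * 12, "scores": np.r_[a, b]}
        )
        row = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="scores")
        row = row[row["Type"] == "ICC2"].iloc[0] if (row["Type"] == "ICC2").any() else row.iloc[1]
        assert icc == pytest.approx(float(row["ICC"]), abs=1e-8)
        ci = row["CI95"] if "CI95" in row.index else row["CI95%"]
        assert lo == pytest.approx(float(ci[0]), abs=5e-3)
        assert hi == pytest.approx(float(ci[1]), abs=5e-3)

    def test_shuffled_scores_give_near_zero_icc(self):
        rng = np.random.default_rng(42)
        a = rng.normal(10, 5, 10)
        b = rng.permutation(a)
        icc, _, _ = icc_two_way_random_absolute(PairedJointTable(a, b))
        assert abs(icc) < 0.35

    def test_column_exchange_symmetry(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=8), rng.normal(size=8)
        i1, _, _ = icc_two_way_random_absolute(PairedJointTable(a, b))
        i2, _, _ = icc_two_way_random_absolute(PairedJointTable(b, a))
        assert i1 == pytest.approx(i2, abs=1e-12)

    def test_zero_between_joint_variance_is_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            icc, lo, hi = icc_two_way_random_absolute(
                PairedJointTable(np.full(4, 2.0), np.full(4, 2.0))
            )
        assert np.isnan(icc)

    def test_strength_labels(self):
        assert icc_strength_label(0.91) == "almost perfect"
        assert icc_strength_label(0.52) == "moderate"
        assert icc_strength_label(0.21) == "fair"


def enumerate_exact_p(diffs: np.ndarray) -> float:
    """Two-sided signed-rank p by full enumeration of the 2^n sign flips."""
    d = diffs[diffs != 0]
    n = d.size
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    ws = []
    for bits in range(2**n):
        signs = [(bits >> i) & 1 for i in range(n)]
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    ws = np.asarray(ws)
    p_low = (ws <= w_obs).mean()
    p_high = (ws >= w_obs).mean()
    return min(1.0, 2 * min(p_low, p_high))


class TestWilcoxon:
    def test_equal_columns_give_p_one_with_warning(self):
        a = np.arange(6.0)
        with pytest.warns(UserWarning, match="zero"):
            assert wilcoxon_signed_rank(PairedJointTable(a, a.copy())) == 1.0

    def test_six_positive_differences_exact_p(self):
        a = np.arange(1.0, 7.0) + np.array([1, 2, 3, 4, 5, 6.0])
        b = np.arange(1.0, 7.0)
        assert wilcoxon_signed_rank(PairedJointTable(a, b)) == pytest.approx(2 / 64)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("n", [6, 9, 12])
    def test_exact_p_matches_full_enumeration(self, seed, n):
        rng = np.random.default_rng(seed)
        d = rng.normal(0.3, 1.0, n)
        d = np.where(np.abs(d) < 1e-6, 0.5, d)
        p = wilcoxon_signed_rank(PairedJointTable(d, np.zeros(n)))
        assert p == pytest.approx(enumerate_exact_p(d), abs=1e-12)

    def test_antisymmetric_differences_sit_at_null_median(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        p = wilcoxon_signed_rank(PairedJointTable(d, np.zeros(6)))
        assert p == pytest.approx(1.0, abs=0.1)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(7)
        a = rng.normal(10, 2, 40)
        b = a + rng.normal(0.5, 1.0, 40)
        p = wilcoxon_signed_rank(PairedJointTable(a, b))
        assert 0.0 < p < 1.0


class TestLesionLevel:
    @pytest.mark.parametrize("matched,n,expected", [(10, 20, 50.0), (20, 20, 100.0), (0, 5, 0.0)])
    def test_ppv_examples(self, matched, n, expected):
        assert ppv(matched, n) == pytest.approx(expected)

    @pytest.mark.parametrize("matched,n,expected", [(10, 20, 50.0), (0, 7, 0.0)])
    def test_sensitivity_examples(self, matched, n, expected):
        assert sensitivity(matched, n) == pytest.approx(expected)

    def test_zero_denominator_is_undefined(self):
        with pytest.raises(UndefinedMetricError):
            ppv(0, 0)
        with pytest.raises(UndefinedMetricError):
            sensitivity(0, 0)

    @given(n=st.integers(1, 1000), m=st.integers(0, 1000))
    @settings(max_examples=200, deadline=None)
    def test_bounds_on_fuzzed_counts(self, n, m):
        if m > n:
            with pytest.raises(ValueError):
                ppv(m, n)
        else:
            v = ppv(m, n)
            s = sensitivity(m, n)
            assert 0.0 <= v <= 100.0
            assert v == pytest.approx(s)  # equal denominators, same count


def test_joint_level_report_assembles_all_fields():
    rng = np.random.default_rng(11)
    a = rng.poisson(20, 10).astype(float)
    b = a + rng.integers(-3, 4, 10)
    rep = joint_level_report(PairedJointTable(a, b, metric="count"))
    d = rep.to_dict()
    for key in ("icc", "icc_ci_low", "icc_ci_high", "wilcoxon_p", "A_mean", "B_sd", "icc_label"):
        assert key in d
    assert -1.0 <= rep.icc <= 1.0
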