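"""Correlation, intraclass correlation and paired-test validation statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psamris import (
    classify_correlation,
    icc_two_way,
    paired_t,
    pearson,
)


class TestPearson:
    def test_perfect_correlation(self):
        res = pearson([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == pytest.approx(1.0)
        assert res.strength == "large"

    def test_perfect_anticorrelation(self):
        assert pearson([1, 2, 3], [3, 2, 1]).r == pytest.approx(-1.0)

    def test_fisher_z_interval(self, rng):
        x = rng.normal(size=17)
        y = 0.8 * x + rng.normal(size=17)
        res = pearson(x, y)
        z = math.atanh(res.r)
        half = 1.96 / math.sqrt(17 - 3)
        assert res.ci95[0] == pytest.approx(math.tanh(z - half))
        assert res.ci95[1] == pytest.approx(math.tanh(z + half))
        assert res.ci95[0] < res.r < res.ci95[1]

    def test_p_matches_t_formula(self, rng):
        from scipy import stats

        x = rng.normal(size=12)
        y = x + rng.normal(size=12, scale=2.0)
        res = pearson(x, y)
        t = res.r * math.sqrt((res.n - 2) / (1 - res.r ** 2))
        p = 2 * stats.t.sf(abs(t), res.n - 2)
        assert res.p == pytest.approx(p)

    def test_p_matches_permutation_oracle(self):
        """The parametric two-sided p agrees with a permutation null to two
        decimals at a moderate correlation and study-sized n."""
        rng = np.random.default_rng(7)
        n = 17
        x = rng.normal(size=n)
        y = 0.55 * x + rng.normal(size=n)
        res = pearson(x, y)

        n_perm = 100_000
        xc = (x - x.mean()) / x.std()
        yc = (y - y.mean()) / y.std()
        perm = np.argsort(rng.random((n_perm, n)), axis=1)
        r_null = (xc[perm] * yc).mean(axis=1)
        r_obs = (xc * yc).mean()
        p_perm = (np.abs(r_null) >= abs(r_obs) - 1e-12).mean()
        assert res.p == pytest.approx(p_perm, abs=0.01)

    def test_invariance_and_symmetry(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        assert pearson(x, y).r == pytest.approx(pearson(y, x).r)
        assert pearson(3 * x + 5, y).r == pytest.approx(pearson(x, y).r)

    def test_preconditions(self):
        with pytest.raises(ValueError, match="n >= 3"):
            pearson([1, 2], [3, 4])
        with pytest.raises(ValueError, match="variance"):
            pearson([1, 1, 1], [1, 2, 3])
        with pytest.raises(ValueError, match="finite"):
            pearson([1, 2, math.nan], [1, 2, 3])


class TestCohenStrata:
    @pytest.mark.parametrize("r, strength", [
        (0.75, "large"), (0.5, "large"), (-0.6, "large"),
        (0.3, "medium"), (0.49, "medium"),
        (0.1, "small"), (0.29, "small"),
        (0.05, "negligible"), (0.0, "negligible"),
    ])
    def test_bands(self, r, strength):
        assert classify_correlation(r) == strength

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_correlation(1.5)


class TestICC:
    def test_identical_raters(self):
        grid = [[1, 1], [4, 4], [2, 2], [5, 5]]
        res = icc_two_way(grid)
        assert res.sicc == pytest.approx(1.0)
        assert res.aicc == pytest.approx(1.0)

    def test_constant_offset_consistency(self):
        base = np.array([1.0, 4.0, 2.0, 5.0, 3.0])
        grid = np.column_stack([base, base + 2])
        res = icc_two_way(grid)
        assert res.sicc == pytest.approx(1.0)
        assert res.aicc == pytest.approx(1.0)
        # the agreement form charges the offset to disagreement
        assert icc_two_way(grid, form="agreement").sicc < 1.0

    def test_matches_hand_anova_oracle(self, rng):
        grid = rng.integers(0, 10, size=(6, 2)).astype(float)
        res = icc_two_way(grid)
        # brute-force ANOVA from sums of squares
        n, k = grid.shape
        grand = grid.mean()
        ss_rows = k * sum((row.mean() - grand) ** 2 for row in grid)
        ss_cols = n * sum((col.mean() - grand) ** 2 for col in grid.T)
        ss_err = ((grid - grand) ** 2).sum() - ss_rows - ss_cols
        ms_rows = ss_rows / (n - 1)
        ms_err = ss_err / ((n - 1) * (k - 1))
        assert res.ms_rows == pytest.approx(ms_rows)
        assert res.ms_error == pytest.approx(ms_err)
        assert res.sicc == pytest.approx((ms_rows - ms_err)
                                         / (ms_rows + (k - 1) * ms_err))
        assert res.aicc == pytest.approx((ms_rows - ms_err) / ms_rows)

    def test_matches_pingouin_icc3(self, rng):
        """Independent cross-check against the reference implementation."""
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        grid = rng.normal(10, 3, size=(8, 3))
        n, k = grid.shape
        long = pd.DataFrame({
            "target": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "score": grid.ravel(),
        })
        table = pingouin.intraclass_corr(long, targets="target", raters="rater",
                                         ratings="score").set_index("Type")
        res = icc_two_way(grid)
        assert res.sicc == pytest.approx(table.loc["ICC(C,1)", "ICC"], abs=1e-9)
        assert res.aicc == pytest.approx(table.loc["ICC(C,k)", "ICC"], abs=1e-9)
        agr = icc_two_way(grid, form="agreement")
        assert agr.sicc == pytest.approx(table.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert agr.aicc == pytest.approx(table.loc["ICC(A,k)", "ICC"], abs=1e-9)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.lists(st.integers(0, 20), min_size=2, max_size=4),
                    min_size=3, max_size=10))
    def test_spearman_brown_identity(self, rows):
        k = len(rows[0])
        if any(len(r) != k for r in rows):
            return
        grid = np.array(rows, dtype=float)
        res = icc_two_way(grid)
        if math.isnan(res.sicc) or res.sicc <= 0:
            return
        stepped_up = k * res.sicc / (1 + (k - 1) * res.sicc)
        assert res.aicc == pytest.approx(stepped_up, rel=1e-9)
        assert res.aicc >= res.sicc
        assert res.aicc <= 1.0

    def test_incomplete_grid_rejected(self):
        with pytest.raises(ValueError, match="incomplete"):
            icc_two_way([[1, math.nan], [2, 3]])
        with pytest.raises(ValueError):
            icc_two_way([[1, 2]])


class TestPairedT:
    def test_identical_samples(self):
        res = paired_t([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0
        assert res.p == 1.0
        assert res.df == 2

    def test_hand_computation(self):
        res = paired_t([2, 4, 6], [1, 2, 3])  # differences 1, 2, 3
        assert res.t == pytest.approx(2 / (1 / math.sqrt(3)), rel=1e-6)
        assert res.df == 2
        assert res.mean_diff == pytest.approx(2.0)

    def test_swap_negates_t_preserves_p(self, rng):
        x = rng.normal(size=10)
        y = x + rng.normal(size=10)
        a = paired_t(x, y)
        b = paired_t(y, x)
        assert b.t == pytest.approx(-a.t)
        assert b.p == pytest.approx(a.p)

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            paired_t([2, 3, 4], [1, 2, 3])

    def test_null_p_values_uniform(self):
        """Kolmogorov-Smirnov check of p-value uniformity under the null."""
        from scipy import stats

        rng = np.random.default_rng(123)
        n_rep, n = 10_000, 15
        a = rng.normal(size=(n_rep, n))
        b = rng.normal(size=(n_rep, n))
        pvals = np.array([paired_t(a[i], b[i]).p for i in range(n_rep)])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01
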