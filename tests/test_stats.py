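"""Statistics layer: ANOVA oracles, Storey q-values, clustering, Tukey and
correlation checks against independent implementations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from proteoturn.errors import StatsPreconditionError
from proteoturn.stats import (
    cluster_interaction_profiles,
    correlate_log2fc,
    one_way_anova,
    one_way_anova_matrix,
    storey_pi0,
    storey_qvalues,
    tukey_hsd,
    two_way_anova,
    two_way_anova_matrix,
)


class TestOneWayAnova:
    def test_permuted_identical_groups_flat(self):
        F, p = one_way_anova([[1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        assert F == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_all_constant_defined_as_p_one(self):
        F, p = one_way_anova([[2.0, 2.0], [2.0, 2.0, 2.0]])
        assert (F, p) == (0.0, 1.0)

    def test_two_groups_f_equals_t_squared(self, rng):
        for _ in range(50):
            a = rng.normal(size=rng.integers(2, 8))
            b = rng.normal(1, 2, size=rng.integers(2, 8))
            F, p = one_way_anova([a, b])
            t = sps.ttest_ind(a, b, equal_var=True)
            assert F == pytest.approx(t.statistic**2, rel=1e-10)
            assert p == pytest.approx(t.pvalue, rel=1e-10)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(i, 1, 6) for i in range(3)]
        F, p = one_way_anova(groups)
        ref = sps.f_oneway(*groups)
        assert F == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_matches_permutation_oracle(self, rng):
        """F-test p agrees with a 10,000-draw label-permutation p."""
        groups = [rng.normal(0, 1, 10) for _ in range(3)]
        F_obs, p_obs = one_way_anova(groups)
        pooled = np.concatenate(groups)
        perms = np.stack(
            [rng.permutation(pooled) for _ in range(10_000)]
        )
        F_perm, _ = one_way_anova_matrix(
            [perms[:, :10], perms[:, 10:20], perms[:, 20:]]
        )
        p_perm = (F_perm >= F_obs).mean()
        assert p_obs == pytest.approx(p_perm, abs=0.03)

    def test_small_group_rejected(self):
        with pytest.raises(StatsPreconditionError):
            one_way_anova([[1.0], [2.0, 3.0]])


class TestTwoWayAnova:
    def test_equal_cell_means_all_flat(self):
        x = np.tile(np.array([1.0, 2.0, 3.0]), (3, 2, 1))
        res = two_way_anova(x)
        assert res.p_a == res.p_b == res.p_ab == pytest.approx(1.0)

    def test_matches_statsmodels_anova_lm(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        x = rng.normal(size=(3, 2, 4))
        res = two_way_anova(x)
        rows = [
            (f"a{i}", f"b{j}", x[i, j, r])
            for i in range(3)
            for j in range(2)
            for r in range(4)
        ]
        df = pd.DataFrame(rows, columns=["A", "B", "y"])
        fit = ols("y ~ C(A) * C(B)", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert res.f_a == pytest.approx(tab.loc["C(A)", "F"], rel=1e-10)
        assert res.f_b == pytest.approx(tab.loc["C(B)", "F"], rel=1e-10)
        assert res.f_ab == pytest.approx(tab.loc["C(A):C(B)", "F"], rel=1e-10)
        assert res.p_ab == pytest.approx(tab.loc["C(A):C(B)", "PR(>F)"], rel=1e-10)

    def test_null_interaction_p_uniform(self, rng):
        """Additive truth: interaction p passes a KS test against U(0,1)."""
        x = rng.normal(size=(2000, 3, 2, 3))
        res = two_way_anova_matrix(x)
        ks = sps.kstest(res["p_ab"], "uniform")
        assert ks.pvalue > 0.01

    def test_missing_cells_rejected(self):
        x = np.ones((3, 2, 3))
        x[0, 0, 0] = np.nan
        with pytest.raises(StatsPreconditionError, match="unbalanced"):
            two_way_anova(x)


class TestStorey:
    def test_all_ones_give_q_one(self):
        q = storey_qvalues(np.ones(20))
        assert np.allclose(q, 1.0)

    def test_pi0_one_reduces_to_bh(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=100)
        q = storey_qvalues(p, pi0=1.0)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.abs(q - bh).max() < 1e-10

    def test_pi0_near_one_under_global_null(self, rng):
        p = np.clip(rng.uniform(size=10_000), 1e-12, 1.0)
        assert 0.9 <= storey_pi0(p) <= 1.0

    def test_q_monotone_and_bounded(self, rng):
        p = np.clip(rng.beta(0.5, 3, size=500), 1e-12, 1.0)
        q = storey_qvalues(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        assert q.max() <= 1.0

    def test_small_m_falls_back_to_pi0_one(self):
        assert storey_pi0(np.array([0.2, 0.4, 0.9])) == 1.0

    def test_out_of_range_rejected(self):
        with pytest.raises(StatsPreconditionError):
            storey_qvalues(np.array([0.0, 0.5]))
        with pytest.raises(StatsPreconditionError):
            storey_qvalues(np.array([0.5, 1.5]))


class TestTukey:
    def test_identical_groups_p_one(self):
        res = tukey_hsd([[1.0, 2.0, 3.0]] * 3)
        assert (res["p_adj"] == 1.0).all()

    def test_dominates_unadjusted_pairwise_t(self, rng):
        """Adjusted p never drops below the unadjusted pairwise p computed
        from the same pooled within-group variance."""
        for _ in range(100):
            groups = [rng.normal(rng.normal(), 1, 4) for _ in range(3)]
            res = tukey_hsd(groups, labels=["a", "b", "c"])
            df_w = sum(len(g) - 1 for g in groups)
            mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df_w
            for row in res.itertuples():
                i = ["a", "b", "c"].index(row.group_a)
                j = ["a", "b", "c"].index(row.group_b)
                se = np.sqrt(mse * (1 / len(groups[i]) + 1 / len(groups[j])))
                t_p = 2 * sps.t.sf(abs(row.mean_diff) / se, df_w)
                assert row.p_adj >= t_p - 1e-12

    def test_two_groups_collapse_to_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 5), rng.normal(1, 1, 6)
        res = tukey_hsd([a, b])
        t_p = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert res["p_adj"].iloc[0] == pytest.approx(t_p, abs=1e-8)


class TestClustering:
    def planted(self, rng, n_per=10):
        base1 = np.array([1.0, 1.0, -1.0, -1.0, 0.0, 0.0])
        base2 = -base1
        rows, names = [], []
        for g, base in enumerate((base1, base2)):
            for i in range(n_per):
                rows.append(base + rng.normal(0, 0.05, 6))
                names.append(f"P{g}{i:02d}")
        return pd.DataFrame(rows, index=names)

    def test_recovers_planted_partition(self, rng):
        prof = self.planted(rng)
        out = cluster_interaction_profiles(prof, k=2)
        groups = out.groupby("cluster_id").groups
        sets = [set(str(i)[1] for i in idx) for idx in groups.values()]
        assert sets == [{"0"}, {"1"}] or sets == [{"1"}, {"0"}]

    def test_singletons_when_k_equals_n(self, rng):
        prof = self.planted(rng, n_per=3)
        out = cluster_interaction_profiles(prof, k=len(prof))
        assert out["cluster_id"].nunique() == len(prof)

    def test_row_order_invariant(self, rng):
        prof = self.planted(rng)
        out1 = cluster_interaction_profiles(prof, k=2)
        out2 = cluster_interaction_profiles(prof.sample(frac=1, random_state=3), k=2)
        pd.testing.assert_frame_equal(out1, out2)

    def test_k_larger_than_n_rejected(self, rng):
        with pytest.raises(StatsPreconditionError):
            cluster_interaction_profiles(self.planted(rng, n_per=2), k=10)


class TestCorrelation:
    def test_perfect_positive_and_negative(self):
        x = pd.Series([1.0, 2.0, 3.0, 4.0], index=list("abcd"))
        res = correlate_log2fc(x, x * 2)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        res = correlate_log2fc(x, -x)
        assert res.r == pytest.approx(-1.0)
        assert res.r_squared == pytest.approx(1.0)

    def test_matches_definition_oracle(self, rng):
        x = pd.Series(rng.normal(size=1000))
        y = pd.Series(0.3 * x + rng.normal(size=1000))
        res = correlate_log2fc(x, y)
        xv, yv = x.to_numpy(), y.to_numpy()
        r_def = np.mean((xv - xv.mean()) * (yv - yv.mean())) / (xv.std() * yv.std())
        assert res.r == pytest.approx(r_def, abs=1e-12)

    def test_nonfinite_pairs_dropped_and_counted(self):
        x = pd.Series([1.0, 2.0, np.nan, 4.0, 5.0], index=list("abcde"))
        y = pd.Series([1.0, 2.0, 3.0, np.inf, 5.0], index=list("abcde"))
        res = correlate_log2fc(x, y)
        assert res.n == 3
        assert res.n_dropped == 2

    def test_zero_variance_rejected(self):
        x = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        y = pd.Series([1.0, 2.0, 3.0], index=list("abc"))
        with pytest.raises(StatsPreconditionError, match="zero variance"):
            correlate_log2fc(x, y)
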