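"""Cohort statistics: hand-worked oracles and independent library checks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import cardiodense as cd
from cardiodense.stats import anova_dunnett


def _two_group_df(a, b, names=("a", "b")):
    return pd.DataFrame(
        {"group": [names[0]] * len(a) + [names[1]] * len(b), "y": list(a) + list(b)}
    )


class TestTTest:
    def test_textbook_pair(self):
        """{1,2,3} vs {2,3,4}: |t| = 1.2247, p ~ 0.288."""
        diff, t, p = cd.student_t_two_sample(_two_group_df([1, 2, 3], [2, 3, 4]), "y")
        assert diff == pytest.approx(1.0)
        assert abs(t) == pytest.approx(1.2247, abs=1e-4)
        assert p == pytest.approx(0.288, abs=0.002)

    def test_identical_groups_p_one(self):
        diff, t, p = cd.student_t_two_sample(_two_group_df([1, 2, 3], [1, 2, 3]), "y")
        assert diff == 0.0 and p == 1.0

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError):
            cd.student_t_two_sample(_two_group_df([1.0], [2, 3, 4]), "y")

    def test_agrees_with_scipy_pooled_and_welch(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 2, 25)
        df = _two_group_df(a, b)
        for welch in (False, True):
            diff, t, p = cd.student_t_two_sample(df, "y", welch=welch)
            ref = sps.ttest_ind(b, a, equal_var=not welch)
            assert t == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)


class TestFisher:
    def test_symmetric_table_p_one(self):
        assert cd.fisher_exact_2x2([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_perfect_separation_closed_form(self):
        """[[10,0],[0,10]]: p = 2 / C(20,10) = 1.08e-5."""
        assert cd.fisher_exact_2x2([[10, 0], [0, 10]]) == pytest.approx(2 / 184756)

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            cd.fisher_exact_2x2([[1, -2], [3, 4]])

    def test_agrees_with_scipy_on_random_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            tab = rng.integers(0, 15, (2, 2))
            if tab.sum() == 0:
                continue
            assert cd.fisher_exact_2x2(tab) == pytest.approx(
                sps.fisher_exact(tab)[1], rel=1e-9
            )


class TestAncova:
    def test_noiseless_orthogonal_covariate_recovers_difference_exactly(self):
        n = 40
        z = np.arange(n, dtype=float)
        g = np.tile([0, 1], n // 2)
        y = 1.0 + 3.0 * g + 0.5 * z
        df = pd.DataFrame({"group": np.where(g == 1, "b", "a"), "age": z, "y": y})
        res = cd.compare_groups_ancova(df, "y")
        assert res.difference == pytest.approx(3.0, abs=1e-9)
        assert res.interaction_p == 1.0  # no spurious interaction on exact fits

    def test_duplicated_group_column_raises_rank_error(self):
        n = 20
        g = np.tile([0.0, 1.0], n // 2)
        df = pd.DataFrame({"group": np.where(g == 1, "b", "a"), "age": g, "y": g})
        with pytest.raises(ValueError, match="collinear"):
            cd.compare_groups_ancova(df, "y")

    def test_missing_rows_deleted_and_counted(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(
            {"group": ["a"] * 10 + ["b"] * 10, "age": rng.normal(12, 2, 20),
             "y": rng.normal(0, 1, 20)}
        )
        df.loc[3, "y"] = np.nan
        res = cd.compare_groups_ancova(df, "y")
        assert res.n_dropped == 1 and res.n_used == 19

    def test_agrees_with_statsmodels(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(5)
        n = 60
        g = rng.random(n) < 0.5
        age = rng.normal(13, 3, n)
        y = -17 + 2.5 * g + 0.3 * age + rng.normal(0, 3, n)
        df = pd.DataFrame({"group": np.where(g, "obese", "healthy"), "age": age, "y": y})
        res = cd.compare_groups_ancova(df, "y")
        fit = smf.ols("y ~ C(group) + age", data=df).fit()
        assert res.difference == pytest.approx(fit.params["C(group)[T.obese]"])
        assert res.se == pytest.approx(fit.bse["C(group)[T.obese]"])
        assert res.p == pytest.approx(fit.pvalues["C(group)[T.obese]"])

    def test_p_agrees_with_permutation_test(self):
        """Regression p matches a label-permutation p within Monte-Carlo error."""
        rng = np.random.default_rng(11)
        n = 40
        g = np.repeat([0, 1], n // 2)
        age = rng.normal(13, 3, n)
        y = 0.8 * g + rng.normal(0, 1.5, n)
        df = pd.DataFrame({"group": np.where(g == 1, "b", "a"), "age": age, "y": y})
        res = cd.compare_groups_ancova(df, "y")
        n_perm = 4000
        count = 0
        obs = abs(res.difference / res.se)
        for _ in range(n_perm):
            perm = df.copy()
            perm["group"] = rng.permutation(perm["group"].to_numpy())
            r = cd.compare_groups_ancova(perm, "y")
            count += abs(r.difference / r.se) >= obs
        p_perm = count / n_perm
        mc_err = 3 * np.sqrt(max(res.p * (1 - res.p), 1e-4) / n_perm)
        assert abs(p_perm - res.p) < max(0.02, mc_err + 0.01)


@pytest.fixture(scope="module")
def three_groups():
    rng = np.random.default_rng(1)
    return pd.DataFrame(
        {
            "cls": ["normal_geometry"] * 20 + ["g1"] * 15 + ["g2"] * 12,
            "y": np.concatenate(
                [rng.normal(0, 1, 20), rng.normal(0.8, 1, 15), rng.normal(0.3, 1, 12)]
            ),
        }
    )


class TestDunnett:

    def test_agrees_with_scipy_dunnett(self, three_groups):
        df = three_groups
        res = anova_dunnett(df, "y", class_col="cls", merge=(), n_mc=400_000, seed=2)
        ref = sps.dunnett(
            df.loc[df.cls == "g1", "y"].to_numpy(),
            df.loc[df.cls == "g2", "y"].to_numpy(),
            control=df.loc[df.cls == "normal_geometry", "y"].to_numpy(),
        )
        for c, p_ref in zip(res.contrasts, ref.pvalue):
            assert c.p_adjusted == pytest.approx(p_ref, abs=0.01)

    def test_integration_and_mc_methods_agree(self, three_groups):
        mc = anova_dunnett(three_groups, "y", class_col="cls", merge=(), n_mc=400_000, seed=4)
        quad = anova_dunnett(three_groups, "y", class_col="cls", merge=(), method="integration")
        for a, b in zip(mc.contrasts, quad.contrasts):
            assert a.p_adjusted == pytest.approx(b.p_adjusted, abs=0.01)

    def test_single_contrast_reduces_to_t_test(self, three_groups):
        df = three_groups[three_groups.cls != "g2"]
        res = anova_dunnett(df, "y", class_col="cls", merge=(), method="integration")
        ref = sps.ttest_ind(
            df.loc[df.cls == "g1", "y"], df.loc[df.cls == "normal_geometry", "y"]
        )
        assert res.contrasts[0].p_adjusted == pytest.approx(ref.pvalue, abs=1e-3)

    def test_adjusted_p_never_below_unadjusted(self, three_groups):
        res = anova_dunnett(three_groups, "y", class_col="cls", merge=(), seed=9)
        for c in res.contrasts:
            assert c.p_adjusted >= c.p_unadjusted

    def test_merge_pools_intermediate_classes(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "cls": ["normal_geometry"] * 15 + ["concentric_remodeling"] * 4
                + ["eccentric_hypertrophy"] * 5 + ["concentric_hypertrophy"] * 6,
                "y": rng.normal(0, 1, 30),
            }
        )
        res = anova_dunnett(df, "y", class_col="cls", method="integration")
        names = {c.group for c in res.contrasts}
        assert names == {
            "concentric_hypertrophy",
            "concentric_remodeling+eccentric_hypertrophy",
        }

    def test_huge_separation_drives_p_to_zero(self):
        df = pd.DataFrame(
            {
                "cls": ["normal_geometry"] * 10 + ["g1"] * 10 + ["g2"] * 10,
                "y": [0.0] * 10 + [100.0] * 10 + [-100.0] * 10,
            }
        )
        df["y"] += np.random.default_rng(0).normal(0, 1e-3, 30)
        res = anova_dunnett(df, "y", class_col="cls", merge=(), method="integration")
        for c in res.contrasts:
            assert c.p_adjusted < 1e-6

    def test_missing_reference_rejected(self, three_groups):
        with pytest.raises(ValueError, match="reference"):
            anova_dunnett(three_groups, "y", class_col="cls", reference="missing", merge=())


class TestAdjustedAssociation:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 200)
        y = 0.5 * x + rng.normal(0, 1, 200)
        df = pd.DataFrame({"x": x, "y": y})
        res = cd.adjusted_association(df, "y", "x", covariates=())
        ref_r, ref_p = sps.pearsonr(x, y)
        assert res.r == pytest.approx(ref_r)
        assert res.p == pytest.approx(ref_p, rel=1e-6)

    def test_exact_linear_relation_gives_unit_correlation(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 50)
        df = pd.DataFrame({"x": x, "y": -2.0 * x + 1.0})
        res = cd.adjusted_association(df, "y", "x", covariates=())
        assert res.r == pytest.approx(-1.0)
        assert res.p == 0.0

    def test_null_predictor_r_small_at_large_n(self):
        rng = np.random.default_rng(2)
        n = 10_000
        df = pd.DataFrame(
            {
                "sex": rng.choice(["F", "M"], n),
                "height": rng.normal(155, 12, n),
                "x": rng.normal(0, 1, n),
                "y": rng.normal(0, 1, n),
            }
        )
        res = cd.adjusted_association(df, "y", "x")
        assert abs(res.r) < 0.03

    def test_agrees_with_residual_method_in_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 120
        height = rng.normal(155, 12, n)
        sex = rng.random(n) < 0.5
        x = 0.2 * height + rng.normal(0, 3, n)
        y = -0.1 * height + 2 * sex + 0.4 * x + rng.normal(0, 4, n)
        df = pd.DataFrame(
            {"height": height, "sex": np.where(sex, "M", "F"), "x": x, "y": y}
        )
        res = cd.adjusted_association(df, "y", "x")
        Z = sm.add_constant(np.column_stack([sex.astype(float), height]))
        ry = sm.OLS(y, Z).fit().resid
        rx = sm.OLS(x, Z).fit().resid
        assert res.r == pytest.approx(sps.pearsonr(ry, rx)[0], abs=1e-9)

    def test_constant_predictor_rejected(self):
        df = pd.DataFrame({"x": [1.0] * 10, "y": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            cd.adjusted_association(df, "y", "x", covariates=())


class TestCoV:
    def test_identical_observers_zero(self):
        assert cd.cov_interobserver([10, 20], [10, 20]).cov_pct == 0.0

    def test_single_pair_hand_arithmetic(self):
        """(10, 12): SD = 2/sqrt(2) = 1.414, mean 11 -> 12.86%."""
        res = cd.cov_interobserver([10], [12])
        assert res.cov_pct == pytest.approx(100 * np.sqrt(2) / 11, abs=1e-6)
        assert res.cov_pct == pytest.approx(12.86, abs=0.01)
        assert res.reproducible

    def test_two_pair_hand_arithmetic(self):
        """(10,12), (20,18): numerator 2*sqrt(2), pair means 11 + 19 = 30."""
        res = cd.cov_interobserver([10, 20], [12, 18])
        assert res.cov_pct == pytest.approx(100 * 2 * np.sqrt(2) / 30, abs=1e-6)

    def test_reproducibility_flag_threshold(self):
        assert cd.cov_interobserver([10], [13]).reproducible  # 18.4% <= 20%
        assert not cd.cov_interobserver([10], [14]).reproducible  # 23.6% > 20%

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            cd.cov_interobserver([-1.0, 1.0], [-1.0, 1.0])

    @given(
        scale=st.floats(0.1, 10.0),
        shift=st.floats(0.5, 5.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_scale_invariance_and_shift_behaviour(self, scale, shift):
        """CoV is invariant to scaling; shifting changes only the denominator."""
        x1 = np.array([10.0, 14.0, 18.0])
        x2 = np.array([11.0, 13.0, 19.0])
        base = cd.cov_interobserver(x1, x2)
        scaled = cd.cov_interobserver(scale * x1, scale * x2)
        assert scaled.cov_pct == pytest.approx(base.cov_pct, rel=1e-9)
        shifted = cd.cov_interobserver(x1 + shift, x2 + shift)
        num = np.sum(np.abs(x1 - x2) / np.sqrt(2))
        den = abs(np.sum((x1 + x2) / 2 + shift))
        assert shifted.cov_pct == pytest.approx(100 * num / den, rel=1e-9)


class TestBlandAltman:
    def test_zero_differences(self):
        res = cd.bland_altman([1.0, 2.0], [1.0, 2.0])
        assert res.bias == res.loa_lower == res.loa_upper == 0.0

    def test_hand_arithmetic_pair(self):
        """Differences {-1, +1}: bias 0, SD sqrt(2), limits +/- 2.77."""
        res = cd.bland_altman([0.0, 0.0], [-1.0, 1.0])
        assert res.bias == 0.0
        assert res.sd_diff == pytest.approx(np.sqrt(2))
        assert res.loa_upper == pytest.approx(1.96 * np.sqrt(2), abs=1e-9)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            cd.bland_altman([1.0], [2.0])

    def test_limits_bracket_bias(self):
        rng = np.random.default_rng(0)
        res = cd.bland_altman(rng.normal(0, 1, 30), rng.normal(0.5, 1, 30))
        assert res.loa_lower <= res.bias <= res.loa_upper


class TestPercentDifference:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(8.2, 6.7, 22), (85, 67, 27), (94, 72, 31), (101, 84, 20), (5.0, 5.0, 0)],
    )
    def test_published_group_ratios(self, a, b, expected):
        assert cd.percent_group_difference(a, b) == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            cd.percent_group_difference(1.0, 0.0)
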