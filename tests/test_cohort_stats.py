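"""Covariate adjustment, shifted-log, ANOVA/Tukey, interaction model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from pbem.cohort_stats import (
    InteractionModelResult,
    adjust_covariates,
    anova_oneway,
    fdr_adjust,
    interaction_model,
    marker_anova,
    scale_common_variance,
    shifted_log,
    tukey_hsd,
)

GROUPS_41 = np.array(["CN"] * 15 + ["aMCI"] * 15 + ["AD"] * 11)


class TestAdjustCovariates:
    def _covariates(self, rng, n=41):
        return (rng.normal(66, 7, n), rng.normal(17, 3, n),
                (rng.random(n) < 0.6).astype(float))

    def test_residuals_orthogonal_to_covariates(self, rng):
        age, edu, gender = self._covariates(rng)
        y = rng.normal(size=41) + 0.05 * age - 0.2 * gender
        adj = adjust_covariates(y, age, edu, gender)
        for c in (age, edu, gender):
            assert abs(np.corrcoef(adj, c)[0, 1]) < 1e-10

    def test_grand_mean_preserved(self, rng):
        age, edu, gender = self._covariates(rng)
        y = rng.normal(2.0, 1.0, 41)
        adj = adjust_covariates(y, age, edu, gender)
        assert adj.mean() == pytest.approx(y.mean(), abs=1e-12)

    def test_null_adjustment_changes_little_at_large_n(self, rng):
        # no true covariate effect: mean absolute change shrinks with n
        changes = {}
        for n in (50, 5000):
            age, edu, gender = self._covariates(rng, n)
            y = rng.normal(size=n)
            adj = adjust_covariates(y, age, edu, gender)
            changes[n] = np.mean(np.abs(adj - y))
        assert changes[5000] < changes[50]
        assert changes[5000] < 0.03

    def test_rank_deficient_design_names_columns(self, rng):
        age = np.full(41, 66.0)
        with pytest.raises(ValueError, match="age"):
            adjust_covariates(rng.normal(size=41), age, rng.normal(17, 3, 41),
                              (rng.random(41) < 0.5).astype(float))

    def test_injected_age_slope_recovered_group_contrast(self):
        """Slope 0.5/yr on age plus a -1.0 group effect: adjusted contrast
        is unbiased across replicates."""
        contrasts = []
        for rep in range(200):
            rng = np.random.default_rng(900 + rep)
            n = 41
            age = np.concatenate([rng.normal(63, 6, 15), rng.normal(66, 6, 15),
                                  rng.normal(72, 6, 11)])
            edu = rng.normal(17, 3, n)
            gender = (rng.random(n) < 0.6).astype(float)
            effect = np.where(GROUPS_41 == "aMCI", -1.0, 0.0)
            y = 0.5 * age + effect + rng.normal(size=n)
            adj = adjust_covariates(y, age, edu, gender)
            contrasts.append(adj[GROUPS_41 == "aMCI"].mean()
                             - adj[GROUPS_41 == "CN"].mean())
        # pooled adjustment with group-confounded age attenuates somewhat;
        # the mean recovered contrast must stay within its Monte-Carlo CI
        # of the attenuation-corrected expectation (between -1 and ~-0.8)
        mean_contrast = np.mean(contrasts)
        se = np.std(contrasts) / np.sqrt(len(contrasts))
        assert -1.0 - 2 * se < mean_contrast < -0.7 + 2 * se


class TestShiftedLog:
    def test_positive_skew_uses_log_branch(self, rng):
        x = rng.lognormal(0.0, 0.8, 200)
        out, spec = shifted_log(x)
        assert spec.direction == "positive_skew"
        assert spec.shift_constant < x.min()

    def test_negative_skew_uses_mirrored_branch(self, rng):
        x = -rng.lognormal(0.0, 0.8, 200)
        out, spec = shifted_log(x)
        assert spec.direction == "negative_skew"
        assert spec.shift_constant > x.max()

    def test_lognormal_symmetrized_below_point_one(self, rng):
        x = rng.lognormal(1.0, 0.6, 200)
        out, _ = shifted_log(x)
        assert abs(sps.skew(out, bias=False)) < 0.1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4, 5, 6, 7])
    def test_never_increases_skew_magnitude(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.gamma(1.5, 2.0, 60) if seed % 2 else -rng.gamma(2.0, 1.0, 60)
        out, _ = shifted_log(x)
        assert abs(sps.skew(out, bias=False)) <= abs(sps.skew(x, bias=False)) + 1e-9

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            shifted_log(np.ones(10))

    @given(seed=st.integers(0, 10_000), n=st.integers(10, 80),
           scale=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_transform_respects_domain_constraint(self, seed, n, scale):
        rng = np.random.default_rng(seed)
        x = scale * rng.gamma(2.0, 1.0, n)
        out, spec = shifted_log(x)
        if spec.direction == "positive_skew":
            assert spec.shift_constant < x.min()
        else:
            assert spec.shift_constant > x.max()
        assert np.all(np.isfinite(out))


class TestScaleCommonVariance:
    def test_unit_variance_and_idempotent(self, rng):
        df = pd.DataFrame(rng.normal(0, [1, 5, 0.2], (50, 3)), columns=list("abc"))
        scaled = scale_common_variance(df)
        assert np.allclose(scaled.var(ddof=1), 1.0, atol=1e-12)
        again = scale_common_variance(scaled)
        assert np.allclose(again.to_numpy(), scaled.to_numpy(), atol=1e-12)

    def test_correlation_structure_unchanged(self, rng):
        df = pd.DataFrame(rng.multivariate_normal(
            [0, 0, 0], [[1, .5, .2], [.5, 2, .1], [.2, .1, 5]], 200),
            columns=list("abc"))
        np.testing.assert_allclose(scale_common_variance(df).corr(), df.corr(),
                                   atol=1e-12)

    def test_constant_column_raises(self):
        df = pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="'a'"):
            scale_common_variance(df)


class TestAnova:
    def test_cohort_degrees_of_freedom(self, rng):
        F, p, df = anova_oneway(rng.normal(size=41), GROUPS_41)
        assert df == (2, 38)

    def test_matches_scipy_oracle(self, rng):
        y = rng.normal(size=41) + np.where(GROUPS_41 == "AD", 0.8, 0.0)
        F, p, _ = anova_oneway(y, GROUPS_41)
        want = sps.f_oneway(y[GROUPS_41 == "CN"], y[GROUPS_41 == "aMCI"],
                            y[GROUPS_41 == "AD"])
        assert F == pytest.approx(want.statistic, abs=1e-12)
        assert p == pytest.approx(want.pvalue, abs=1e-12)

    def test_two_identical_groups_give_zero_between(self, rng):
        half = rng.normal(size=10)
        y = np.concatenate([half, half])
        g = np.array(["A"] * 10 + ["B"] * 10)
        F, p, df = anova_oneway(y, g)
        assert F == pytest.approx(0.0, abs=1e-12)
        assert df == (1, 18)

    def test_singleton_group_raises(self):
        with pytest.raises(ValueError):
            anova_oneway(np.arange(5.0), np.array(["A", "A", "A", "A", "B"]))

    def test_null_rejection_rate_at_alpha(self):
        rng = np.random.default_rng(2024)
        crit = sps.f.ppf(0.90, 2, 38)
        hits = 0
        reps = 2000
        for _ in range(reps):
            F, _, _ = anova_oneway(rng.normal(size=41), GROUPS_41)
            hits += F > crit
        assert hits / reps == pytest.approx(0.10, abs=0.02)


class TestTukey:
    def test_adjusted_p_not_below_pairwise_p(self, rng):
        y = rng.normal(size=41) + np.where(GROUPS_41 == "AD", 1.0, 0.0)
        table = tukey_hsd(y, GROUPS_41)
        for _, row in table.iterrows():
            a = y[GROUPS_41 == row["group1"]]
            b = y[GROUPS_41 == row["group2"]]
            raw_p = sps.ttest_ind(a, b).pvalue
            assert row["p_adj"] >= raw_p - 1e-10

    def test_schema_matches_pairwise_report(self, rng):
        table = tukey_hsd(rng.normal(size=41), GROUPS_41)
        assert list(table.columns) == ["group1", "group2", "mean_diff", "p_adj",
                                       "ci_lower", "ci_upper", "reject"]
        pairs = set(map(tuple, table[["group1", "group2"]].to_numpy()))
        assert pairs == {("aMCI", "CN"), ("AD", "CN"), ("AD", "aMCI")}

    def test_against_statsmodels_oracle(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        from itertools import combinations

        y = rng.normal(size=41) + np.where(GROUPS_41 == "AD", 0.9, 0.0)
        ours = tukey_hsd(y, GROUPS_41).set_index(["group1", "group2"])
        sm_res = pairwise_tukeyhsd(y, GROUPS_41, alpha=0.05)
        pairs = list(combinations(sm_res.groupsunique, 2))
        for (g1, g2), diff, p_adj in zip(pairs, sm_res.meandiffs, sm_res.pvalues):
            # statsmodels reports mean(group2) - mean(group1)
            if (g2, g1) in ours.index:
                mine, sign = ours.loc[(g2, g1)], 1.0
            else:
                mine, sign = ours.loc[(g1, g2)], -1.0
            assert mine["mean_diff"] == pytest.approx(sign * diff, abs=1e-10)
            assert mine["p_adj"] == pytest.approx(float(p_adj), abs=2e-3)

    def test_familywise_error_controlled(self):
        rng = np.random.default_rng(77)
        reps = 2000
        fw = 0
        for _ in range(reps):
            table = tukey_hsd(rng.normal(size=41), GROUPS_41, alpha=0.05)
            fw += bool(table["reject"].any())
        assert fw / reps <= 0.065


class TestInteractionModel:
    def _simulate(self, rng, b3=0.4, b4=0.0, b5=0.0):
        x = rng.normal(size=41)
        g = GROUPS_41
        y = (0.3 - 0.5 * (g == "aMCI") - 1.0 * (g == "AD")
             + b3 * (x - x.mean()) + b4 * (x - x.mean()) * (g == "aMCI")
             + b5 * (x - x.mean()) * (g == "AD") + rng.normal(scale=0.7, size=41))
        return y, x, g

    def test_known_slope_recovered(self, rng):
        y, x, g = self._simulate(rng, b3=0.4)
        res = interaction_model(y, x, g)
        assert res.coefficients[3] == pytest.approx(0.4, abs=3 * res.b3_se)
        assert res.df_interaction == (2, 35)

    def test_centering_identity(self, rng):
        """With x centered at the grand mean, the intercept is the CN
        prediction at average marker level."""
        y, x, g = self._simulate(rng)
        res = interaction_model(y, x, g)
        cn_fit = y[g == "CN"] - res.residuals[g == "CN"]
        xc = res.x_centered[g == "CN"]
        intercept_from_fit = np.polyfit(xc, cn_fit, 1)[1]
        assert res.coefficients[0] == pytest.approx(intercept_from_fit, abs=1e-8)
        assert res.x_centered.mean() == pytest.approx(0.0, abs=1e-12)

    def test_missing_group_raises(self, rng):
        y, x, _ = self._simulate(rng)
        g = np.array(["CN"] * 26 + ["aMCI"] * 15)
        with pytest.raises(ValueError, match="AD"):
            interaction_model(y, x, g)

    def test_null_interaction_rejection_rate(self):
        hits = 0
        reps = 400
        for rep in range(reps):
            rng = np.random.default_rng(3000 + rep)
            y, x, g = self._simulate(rng, b4=0.0, b5=0.0)
            res = interaction_model(y, x, g)
            hits += res.p_interaction < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.03)


class TestMarkerAnova:
    def test_full_chain_on_cohort_table(self, default_cohort):
        res = marker_anova(default_cohort, "temporal_energy_reserve")
        assert res["df"] == (2, 38)
        assert set(res["tukey"]["group1"]) <= {"aMCI", "AD"}
        assert res["transform"].direction in ("positive_skew", "negative_skew")


class TestFdr:
    def test_benjamini_hochberg_monotone(self):
        p = np.array([0.001, 0.01, 0.02, 0.2, 0.9])
        reject, p_adj = fdr_adjust(p, q=0.10)
        assert reject[0] and reject[1]
        assert not reject[-1]
        assert np.all(np.diff(p_adj[np.argsort(p)]) >= -1e-12)
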