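"""Severity rule, z-scoring, group tests, standardized-beta OLS, BH-FDR,
and the Greenhouse-Geisser repeated-measures ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sfcoupling.cohort_stats import (
    add_severity,
    apply_fdr,
    AssociationResult,
    classify_severity,
    compare_groups,
    covariate_sets,
    fdr_bh,
    linear_assoc,
    pearson_assoc,
    rm_anova_networks,
    zscore_battery,
)


class TestClassifySeverity:
    @pytest.mark.parametrize(
        "pwmh, dwmh, expected",
        [(3, 0, "severe"), (2, 1, "mild"), (0, 2, "severe"), (1, 1, "mild"), (3, 3, "severe")],
    )
    def test_rule(self, pwmh, dwmh, expected):
        assert classify_severity(pwmh, dwmh) == expected

    def test_zero_scores_fail_inclusion(self):
        with pytest.raises(ValueError, match="> 0"):
            classify_severity(0, 0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="0..3"):
            classify_severity(4, 1)


class TestZscoreBattery:
    def test_closed_form(self):
        df = pd.DataFrame({"t": [1.0, 2.0, 3.0]})
        out = zscore_battery(df, ["t"])
        assert np.allclose(out["t"], [-1, 0, 1])

    def test_missing_preserved(self):
        df = pd.DataFrame({"t": [1.0, np.nan, 3.0, 5.0]})
        out = zscore_battery(df, ["t"])
        assert out["t"].isna().tolist() == [False, True, False, False]
        obs = out["t"].dropna()
        assert obs.mean() == pytest.approx(0, abs=1e-12)
        assert obs.std(ddof=1) == pytest.approx(1, abs=1e-12)

    def test_idempotent_on_standardized_column(self, rng):
        x = rng.normal(size=40)
        x = (x - x.mean()) / x.std(ddof=1)
        df = pd.DataFrame({"t": x})
        assert np.allclose(zscore_battery(df, ["t"])["t"], x, atol=1e-12)

    def test_constant_column_names_test(self):
        df = pd.DataFrame({"span": [3.0, 3.0, 3.0]})
        with pytest.raises(ValueError, match="span"):
            zscore_battery(df, ["span"])


def _two_group_table(n1=20, n2=25, delta=0.0, seed=3):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "severity": ["mild"] * n1 + ["severe"] * n2,
            "x": np.concatenate([rng.normal(size=n1), rng.normal(delta, 1, n2)]),
        }
    )


class TestCompareGroups:
    def test_sex_proportions_with_continuity_correction(self):
        """161/374 vs 126/243 females: the Yates-corrected chi-square p."""
        table = pd.DataFrame(
            {
                "severity": ["mild"] * 374 + ["severe"] * 243,
                "sex_female": [1] * 161 + [0] * 213 + [1] * 126 + [0] * 117,
            }
        )
        res = compare_groups(table, ["sex_female"])
        assert res.loc[0, "test"] == "chi2"
        assert round(float(res.loc[0, "p"]), 3) == 0.039

    def test_identical_groups_t_zero_p_one(self):
        df = pd.DataFrame(
            {"severity": ["mild"] * 3 + ["severe"] * 3, "x": [1.0, 2.0, 3.0] * 2}
        )
        res = compare_groups(df, ["x"])
        assert res.loc[0, "statistic"] == pytest.approx(0.0, abs=1e-12)
        assert res.loc[0, "p"] == pytest.approx(1.0)

    def test_matches_pooled_t_closed_form(self):
        df = _two_group_table(delta=0.7)
        res = compare_groups(df, ["x"])
        x1 = df[df.severity == "mild"]["x"].to_numpy()
        x2 = df[df.severity == "severe"]["x"].to_numpy()
        n1, n2 = len(x1), len(x2)
        sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
        t = (x1.mean() - x2.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        p = 2 * stats.t.sf(abs(t), n1 + n2 - 2)
        assert res.loc[0, "statistic"] == pytest.approx(t, abs=1e-12)
        assert res.loc[0, "p"] == pytest.approx(p, abs=1e-12)

    def test_tiny_stratum_rejected(self):
        df = pd.DataFrame({"severity": ["mild", "severe", "severe"], "x": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="at least 2"):
            compare_groups(df, ["x"])


class TestCovariateSets:
    def test_cross_sectional_cognition_set(self):
        assert covariate_sets("coupling_cognition") == [
            "age",
            "sex",
            "education",
            "wmh_volume",
        ]

    def test_longitudinal_extends_cross_sectional(self):
        covs = covariate_sets("longitudinal")
        assert covs[:4] == ["age", "sex", "education", "wmh_volume"]
        assert covs[4:] == ["follow_up_duration", "baseline_score"]

    def test_full_adjustment_has_risk_factors(self):
        covs = covariate_sets("wmh_coupling_full")
        assert "hypertension" in covs and "drinking" in covs and "education" in covs

    def test_unknown_analysis(self):
        with pytest.raises(ValueError, match="unknown analysis"):
            covariate_sets("mediation")


class TestFdrBH:
    @pytest.mark.parametrize(
        "raw, adjusted",
        [
            ([0.006, 0.050], [0.012, 0.050]),
            ([0.036, 0.09], [0.072, 0.09]),
            ([0.3], [0.3]),
        ],
    )
    def test_worked_examples(self, raw, adjusted):
        assert np.allclose(fdr_bh(raw), adjusted)

    def test_matches_step_up_sort_oracle(self, rng):
        p = rng.uniform(size=10)
        # direct definition: sort, multiply by m/rank, enforce monotone from the top
        order = np.argsort(p)
        m = len(p)
        stepped = p[order] * m / np.arange(1, m + 1)
        for k in range(m - 2, -1, -1):
            stepped[k] = min(stepped[k], stepped[k + 1])
        expect = np.empty(m)
        expect[order] = np.minimum(stepped, 1.0)
        assert np.allclose(fdr_bh(p), expect, atol=1e-12)

    def test_adjusted_not_below_raw_and_order_preserving(self, rng):
        p = rng.uniform(size=25)
        q = fdr_bh(p)
        assert (q >= p - 1e-15).all()
        # monotone (weakly order-preserving): smaller raw p never gets a
        # larger adjusted p; plateaus of equal adjusted values are allowed
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_smallest_p_scales_by_family_size_when_it_stays_minimal(self):
        p = [0.001, 0.5, 0.6, 0.7, 0.8]
        q = fdr_bh(p)
        assert q[0] == pytest.approx(0.001 * 5)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.1, 1.2])

    def test_apply_fdr_families_are_per_stratum(self):
        mk = lambda stratum, p: AssociationResult(stratum, "y", "x", (), 0.0, p, 10)
        results = [mk("mild", 0.006), mk("mild", 0.050), mk("severe", 0.036), mk("severe", 0.09)]
        apply_fdr(results)
        assert [r.p_fdr for r in results] == pytest.approx([0.012, 0.050, 0.072, 0.09])


class TestLinearAssoc:
    def test_outcome_as_its_own_predictor(self, rng):
        df = pd.DataFrame({"y": rng.normal(size=30)})
        df["x"] = df["y"]
        res = linear_assoc(df, "y", "x")
        assert res.beta_std == pytest.approx(1.0, abs=1e-9)
        assert res.p_raw < 1e-20

    def test_standardized_beta_equals_pearson_without_covariates(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=50)})
        df["y"] = 0.4 * df["x"] + rng.normal(size=50)
        res = linear_assoc(df, "y", "x")
        r, p = pearson_assoc(df["x"], df["y"])
        assert res.beta_std == pytest.approx(r, abs=1e-12)
        assert res.p_raw == pytest.approx(p, rel=1e-9)

    def test_binary_categorical_covariate_coded(self, rng):
        n = 40
        df = pd.DataFrame(
            {
                "x": rng.normal(size=n),
                "sex": rng.choice(["female", "male"], size=n),
                "y": rng.normal(size=n),
            }
        )
        res = linear_assoc(df, "y", "x", ["sex"])
        assert np.isfinite(res.beta_std) and res.n == n

    def test_rank_deficient_design_lists_aliased(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=20)})
        df["y"] = rng.normal(size=20)
        df["x2"] = 2 * df["x"]
        with pytest.raises(ValueError, match="aliased"):
            linear_assoc(df, "y", "x", ["x2"])

    def test_complete_case_n_reported(self, rng):
        df = pd.DataFrame({"x": rng.normal(size=30), "y": rng.normal(size=30)})
        df.loc[:4, "x"] = np.nan
        res = linear_assoc(df, "y", "x")
        assert res.n == 25


class TestPearsonAssoc:
    def test_perfect_correlations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert pearson_assoc(x, x)[0] == pytest.approx(1.0)
        assert pearson_assoc(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_t_transform_oracle(self, rng):
        x = rng.normal(size=50)
        y = 0.3 * x + rng.normal(size=50)
        r, p = pearson_assoc(x, y)
        t = r * np.sqrt(48 / (1 - r**2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 48), rel=1e-9)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_assoc([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRmAnova:
    def test_no_within_subject_effect_gives_zero_F(self, rng):
        base = rng.normal(size=40)
        Y = np.tile(base[:, None], (1, 7))
        res = rm_anova_networks(Y)
        assert res.F == 0.0 and res.p == 1.0

    def test_two_conditions_equal_squared_paired_t(self, rng):
        a = rng.normal(size=25)
        b = a + 0.4 + rng.normal(scale=0.5, size=25)
        res = rm_anova_networks(np.column_stack([a, b]))
        t, _ = stats.ttest_rel(a, b)
        assert res.epsilon == pytest.approx(1.0)
        assert res.F == pytest.approx(t**2, rel=1e-9)

    def test_matches_sums_of_squares_oracle(self, rng):
        Y = rng.normal(size=(40, 7))
        Y[:, 3] += 0.5
        res = rm_anova_networks(Y)
        # oracle: explicit two-way decomposition from the definition
        N, k = Y.shape
        gm = Y.mean()
        ss_cond = N * sum((Y[:, j].mean() - gm) ** 2 for j in range(k))
        ss_sub = k * sum((Y[i].mean() - gm) ** 2 for i in range(N))
        ss_tot = ((Y - gm) ** 2).sum()
        ss_err = ss_tot - ss_cond - ss_sub
        F = (ss_cond / (k - 1)) / (ss_err / ((k - 1) * (N - 1)))
        assert res.F == pytest.approx(F, abs=1e-9)

    def test_agrees_with_independent_rm_anova_implementation(self, rng):
        pg = pytest.importorskip("pingouin")
        Y = rng.normal(size=(30, 5))
        Y[:, 0] += 0.3
        res = rm_anova_networks(pd.DataFrame(Y, columns=list("ABCDE")))
        long = pd.DataFrame(Y, columns=list("ABCDE")).reset_index().melt("index")
        aov = pg.rm_anova(
            data=long, dv="value", within="variable", subject="index", correction=True
        )
        assert res.F == pytest.approx(float(aov["F"].iloc[0]), rel=1e-9)
        assert res.epsilon == pytest.approx(float(aov["eps"].iloc[0]), rel=1e-6)
        assert res.p == pytest.approx(float(aov["p_GG_corr"].iloc[0]), rel=1e-6)

    def test_invariant_to_per_subject_constant(self, rng):
        Y = rng.normal(size=(20, 4))
        res0 = rm_anova_networks(Y)
        res1 = rm_anova_networks(Y + rng.normal(size=(20, 1)) * 10)
        assert res1.F == pytest.approx(res0.F, rel=1e-9)
        assert res1.epsilon == pytest.approx(res0.epsilon, rel=1e-9)

    def test_missing_cells_rejected(self, rng):
        Y = rng.normal(size=(10, 4))
        Y[3, 2] = np.nan
        with pytest.raises(ValueError, match="complete"):
            rm_anova_networks(Y)

    def test_posthoc_covers_all_pairs_with_adjusted_p(self, rng):
        Y = rng.normal(size=(30, 4))
        Y[:, 1] += 1.0
        res = rm_anova_networks(pd.DataFrame(Y, columns=list("ABCD")))
        assert len(res.posthoc) == 6
        assert ((res.posthoc["p_adj"] >= 0) & (res.posthoc["p_adj"] <= 1)).all()
        big = res.posthoc.query("network_a == 'A' and network_b == 'B'")
        assert big["p_adj"].iloc[0] < 0.01


class TestAddSeverity:
    def test_vectorized_consistency(self):
        df = pd.DataFrame({"pwmh": [3, 2, 0], "dwmh": [0, 1, 2]})
        out = add_severity(df)
        assert out["severity"].tolist() == ["severe", "mild", "severe"]
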