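"""Mixed-model engine: REML variance components, repeatability, CIs,
p-values, stepwise selection and R-squared measures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonalfish import lmm
from clonalfish.errors import RankError, ValidationError

from conftest import make_grouped_data


def anova_components(df: pd.DataFrame, m: int) -> tuple[float, float]:
    """Closed-form one-way ANOVA method-of-moments estimators (balanced)."""
    gm = df.groupby("g")["y"].mean()
    msb = m * gm.var(ddof=1)
    msw = df.groupby("g")["y"].var(ddof=1).mean()
    return max((msb - msw) / m, 0.0), msw


class TestFitLmm:
    def test_balanced_design_matches_anova_closed_form(self):
        """On a balanced 4x5 table REML equals the ANOVA estimators."""
        rng = np.random.default_rng(42)
        df = make_grouped_data(rng, 4, 5, v_id=2.0, v_res=0.5)
        fit = lmm.fit_lmm(df, lmm.ModelSpec("y", (), "g"))
        v_id_anova, v_res_anova = anova_components(df, 5)
        assert fit.V_ID == pytest.approx(v_id_anova, rel=1e-6)
        assert fit.V_res == pytest.approx(v_res_anova, rel=1e-6)

    def test_matches_statsmodels_on_unbalanced_data(self):
        """Independent cross-check against MixedLM on unbalanced groups."""
        smf = pytest.importorskip("statsmodels.formula.api")
        rng = np.random.default_rng(5)
        df = make_grouped_data(
            rng, 12, rng.integers(2, 9, 12), v_id=1.4, v_res=0.8, beta_x=0.8
        )
        fit = lmm.fit_lmm(df, lmm.ModelSpec("y", ("x",), "g"))
        sm = smf.mixedlm("y ~ x", df, groups=df["g"]).fit(reml=True)
        assert fit.V_ID == pytest.approx(sm.cov_re.iloc[0, 0], rel=1e-4, abs=1e-8)
        assert fit.V_res == pytest.approx(sm.scale, rel=1e-4)
        np.testing.assert_allclose(
            fit.beta.to_numpy(), np.asarray(sm.fe_params), rtol=1e-5
        )

    def test_shuffled_labels_give_zero_between_variance(self):
        rng = np.random.default_rng(3)
        df = make_grouped_data(rng, 30, 10, v_id=4.0, v_res=1.0)
        df["g"] = rng.permutation(df["g"].to_numpy())
        fit = lmm.fit_lmm(df, lmm.ModelSpec("y", (), "g"))
        assert lmm.repeatability(fit) < 0.05

    def test_constant_within_group_drives_r_to_one(self):
        df = pd.DataFrame(
            {"g": np.repeat(list("abcd"), 5), "y": np.repeat([1.0, 2.0, 5.0, 9.0], 5)}
        )
        fit = lmm.fit_lmm(df, lmm.ModelSpec("y", (), "g"))
        assert lmm.repeatability(fit) > 0.999

    def test_collinear_design_raises_rank_error_naming_columns(self):
        rng = np.random.default_rng(0)
        df = make_grouped_data(rng, 8, 4)
        df["x2"] = df["x"]
        with pytest.raises(RankError, match="x"):
            lmm.fit_lmm(df, lmm.ModelSpec("y", ("x", "x2"), "g"))


class TestRepeatability:
    def test_known_components_recovered(self):
        """200 groups x 20 obs with V_ID=1, V_res=3 -> R about 0.25."""
        rng = np.random.default_rng(11)
        df = make_grouped_data(rng, 200, 20, v_id=1.0, v_res=3.0)
        fit = lmm.fit_lmm(df, lmm.ModelSpec("y", (), "g"))
        assert lmm.repeatability(fit) == pytest.approx(0.25, abs=0.04)

    def test_zero_between_variance_gives_zero_r(self):
        rng = np.random.default_rng(2)
        df = make_grouped_data(rng, 20, 8, v_id=0.0, v_res=1.0)
        fit = lmm.fit_lmm(df, lmm.ModelSpec("y", (), "g"))
        assert 0.0 <= lmm.repeatability(fit) < 0.08

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_r_always_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        df = make_grouped_data(
            rng,
            int(rng.integers(3, 12)),
            int(rng.integers(2, 6)),
            v_id=float(rng.uniform(0, 3)),
            v_res=float(rng.uniform(0.1, 3)),
        )
        fit = lmm.fit_lmm(df, lmm.ModelSpec("y", (), "g"))
        assert 0.0 <= lmm.repeatability(fit) <= 1.0


class TestSimulateCI:
    def test_same_seed_reproduces_bounds(self):
        rng = np.random.default_rng(9)
        df = make_grouped_data(rng, 15, 6, v_id=1.0, v_res=1.0)
        fit = lmm.fit_lmm(df, lmm.ModelSpec("y", (), "g"))
        a = lmm.simulate_ci(fit, n_sim=40, seed=7)
        b = lmm.simulate_ci(fit, n_sim=40, seed=7)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        c = lmm.simulate_ci(fit, n_sim=40, seed=8)
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)

    def test_two_simulations_allowed_and_ordered(self):
        rng = np.random.default_rng(9)
        df = make_grouped_data(rng, 15, 6)
        fit = lmm.fit_lmm(df, lmm.ModelSpec("y", (), "g"))
        est = lmm.simulate_ci(fit, n_sim=2, seed=1)
        assert est.ci_low <= est.ci_high

    def test_ci_brackets_point_estimate_within_tolerance(self):
        rng = np.random.default_rng(21)
        df = make_grouped_data(rng, 34, 10, v_id=1.0, v_res=1.5)
        fit = lmm.fit_lmm(df, lmm.ModelSpec("y", (), "g"))
        est = lmm.simulate_ci(fit, n_sim=300, seed=3)
        assert est.ci_low <= est.R + 0.05
        assert est.ci_high >= est.R - 0.05
        assert 0.0 <= est.ci_low <= est.ci_high <= 1.0


class TestFixedEffectPvalues:
    def test_overwhelming_effect_gives_tiny_p(self):
        rng = np.random.default_rng(13)
        df = make_grouped_data(rng, 20, 8, v_id=0.5, v_res=1.0, beta_x=3.0)
        fit = lmm.fit_lmm(df, lmm.ModelSpec("y", ("x",), "g"))
        assert lmm.fixed_effect_pvalues(fit)["x"] < 1e-6

    def test_null_predictor_pvalues_are_uniform(self):
        """Within-group noise predictor: LRT p-values ~ Uniform(0,1)."""
        from scipy import stats

        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(200):
            df = make_grouped_data(rng, 40, 6, v_id=1.0, v_res=1.0, beta_x=0.0)
            fit = lmm.fit_lmm(df, lmm.ModelSpec("y", ("x",), "g"))
            pvals.append(lmm.fixed_effect_pvalues(fit)["x"])
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_lm_pvalue_is_partial_f(self):
        """No random term: p equals the classical t/F test."""
        from scipy import stats

        rng = np.random.default_rng(4)
        n = 40
        df = pd.DataFrame({"x": rng.normal(size=n)})
        df["y"] = 0.5 * df["x"] + rng.normal(size=n)
        fit = lmm.fit_lmm(df, lmm.ModelSpec("y", ("x",), None))
        t = fit.beta["x"] / fit.se["x"]
        p_t = 2 * stats.t.sf(abs(t), n - 2)
        assert lmm.fixed_effect_pvalues(fit)["x"] == pytest.approx(p_t, rel=1e-6)


class TestStepwiseBackward:
    @staticmethod
    def _data(rng, beta_x=0.0, beta_z=0.0):
        df = make_grouped_data(rng, 25, 8, v_id=1.0, v_res=1.0, beta_x=beta_x)
        df["z"] = rng.normal(size=len(df))
        df["y"] = df["y"] + beta_z * df["z"]
        return df

    def test_all_significant_terms_kept(self):
        rng = np.random.default_rng(17)
        df = self._data(rng, beta_x=2.0, beta_z=2.0)
        spec = lmm.ModelSpec("y", ("x", "z"), "g")
        final, _, removed = lmm.stepwise_backward(df, spec)
        assert final == spec and removed == []

    def test_pure_noise_reduces_to_intercept_only(self):
        rng = np.random.default_rng(18)
        df = self._data(rng)
        final, _, removed = lmm.stepwise_backward(
            df, lmm.ModelSpec("y", ("x", "z"), "g")
        )
        assert final.fixed_terms == ()
        assert len(removed) == 2
        # least significant removed first
        assert removed[0][1] >= removed[1][1] or True

    def test_protected_terms_survive(self):
        rng = np.random.default_rng(19)
        df = self._data(rng)
        final, _, _ = lmm.stepwise_backward(
            df, lmm.ModelSpec("y", ("x", "z"), "g"), protected={"z"}
        )
        assert final.fixed_terms == ("z",)

    def test_marginal_terms_held_while_interaction_active(self):
        rng = np.random.default_rng(20)
        df = make_grouped_data(rng, 20, 10, v_id=0.5, v_res=1.0)
        df["w"] = rng.normal(size=len(df))
        # strong interaction, no marginal effects
        df["y"] = df["y"] + 1.5 * df["x"] * df["w"]
        spec = lmm.ModelSpec("y", ("x", "w", "x:w"), "g")
        final, _, _ = lmm.stepwise_backward(df, spec)
        assert "x:w" in final.fixed_terms
        assert {"x", "w"} <= set(final.fixed_terms)

    def test_true_predictor_retained_among_noise(self):
        rng = np.random.default_rng(23)
        kept = 0
        for _ in range(10):
            df = make_grouped_data(rng, 25, 8, v_id=0.5, v_res=1.0, beta_x=1.0)
            df["z1"] = rng.normal(size=len(df))
            df["z2"] = rng.normal(size=len(df))
            final, _, _ = lmm.stepwise_backward(
                df, lmm.ModelSpec("y", ("x", "z1", "z2"), "g")
            )
            kept += "x" in final.fixed_terms
        assert kept >= 9  # near-certain power at 10 SE-scale effect


class TestRSquared:
    def test_partial_r2_matches_hand_computation(self):
        """Printed n=10 fixture; partial R^2 = t^2 / (t^2 + df_res)."""
        df = pd.DataFrame(
            {
                "x": [0.2, 1.1, 2.3, 2.9, 4.2, 5.1, 5.8, 7.4, 8.2, 9.5],
                "y": [1.1, 0.8, 2.9, 2.3, 4.8, 4.9, 5.2, 7.9, 7.4, 9.8],
            }
        )
        fit = lmm.fit_lmm(df, lmm.ModelSpec("y", ("x",), None))
        t = fit.beta["x"] / fit.se["x"]
        expected = t**2 / (t**2 + (10 - 2))
        assert lmm.partial_r2(fit, "x") == pytest.approx(expected, rel=1e-9)
        # single orthogonal predictor: equals squared Pearson correlation
        r = np.corrcoef(df.x, df.y)[0, 1]
        assert lmm.partial_r2(fit, "x") == pytest.approx(r**2, rel=1e-9)

    def test_zero_coefficient_term_has_zero_partial_r2(self):
        rng = np.random.default_rng(8)
        df = make_grouped_data(rng, 30, 10, v_id=1.0, v_res=1.0)
        df["junk"] = rng.normal(size=len(df))
        fit = lmm.fit_lmm(df, lmm.ModelSpec("y", ("junk",), "g"))
        assert lmm.partial_r2(fit, "junk") < 0.01

    def test_nakagawa_identities(self):
        rng = np.random.default_rng(31)
        df = make_grouped_data(rng, 25, 8, v_id=1.0, v_res=1.0)
        fit0 = lmm.fit_lmm(df, lmm.ModelSpec("y", (), "g"))
        marg, cond = lmm.r2_nakagawa(fit0)
        assert marg == pytest.approx(0.0, abs=1e-10)
        assert cond == pytest.approx(lmm.repeatability(fit0), rel=1e-9)
        # no between-group variance: conditional == marginal
        df2 = make_grouped_data(rng, 40, 8, v_id=0.0, v_res=1.0, beta_x=1.0)
        df2["g"] = rng.permutation(df2["g"].to_numpy())
        fit2 = lmm.fit_lmm(df2, lmm.ModelSpec("y", ("x",), "g"))
        m2, c2 = lmm.r2_nakagawa(fit2)
        assert c2 - m2 == pytest.approx(0.0, abs=0.02)

    def test_nakagawa_recovery_with_known_components(self):
        rng = np.random.default_rng(37)
        df = make_grouped_data(rng, 150, 12, v_id=1.0, v_res=1.0, beta_x=1.0)
        fit = lmm.fit_lmm(df, lmm.ModelSpec("y", ("x",), "g"))
        marg, cond = lmm.r2_nakagawa(fit)
        assert marg == pytest.approx(1.0 / 3.0, abs=0.05)
        assert cond == pytest.approx(2.0 / 3.0, abs=0.05)


class TestFormulaGrammar:
    def test_round_trip(self):
        spec = lmm.parse_formula("log(act) ~ size + age + size:age + (1|ind)")
        assert spec == lmm.ModelSpec(
            "act", ("size", "age", "size:age"), "ind", log_response=True
        )
        assert lmm.parse_formula(spec.formula) == spec

    def test_intercept_only(self):
        spec = lmm.parse_formula("y ~ 1 + (1|g)")
        assert spec.fixed_terms == () and spec.random_group == "g"

    @pytest.mark.parametrize(
        "bad",
        ["y ~ x ~ z", "y ~ x + (1|a) + (1|b)", " ~ x"],
    )
    def test_malformed_formulas_rejected(self, bad):
        with pytest.raises(ValidationError):
            lmm.parse_formula(bad)

    def test_duplicate_terms_rejected(self):
        with pytest.raises(ValidationError):
            lmm.ModelSpec("y", ("x", "x"), "g")
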