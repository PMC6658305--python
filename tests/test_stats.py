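import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from pvfever import stats as st
from pvfever.simulate import simulate_high_fever_outcomes


class TestWelch:
    def test_identical_samples_give_null_result(self):
        r = st.welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == 0.0 and r.p_value == pytest.approx(1.0)

    def test_hand_evaluated_example(self):
        """a = 1..5, b = 2..6: equal variances 2.5, pooled SE 1, so
        t = -1 with Satterthwaite df 8 and two-sided p = 2*P(T8 > 1)."""
        r = st.welch_t_test([1, 2, 3, 4, 5], [2, 3, 4, 5, 6])
        assert r.t_statistic == pytest.approx(-1.0)
        assert r.df == pytest.approx(8.0)
        assert r.p_value == pytest.approx(0.34659, abs=1e-4)
        assert r.mean_difference == pytest.approx(-1.0)

    def test_antisymmetry_and_scipy_agreement(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 20), rng.normal(0.5, 2, 35)
        r1 = st.welch_t_test(a, b)
        r2 = st.welch_t_test(b, a)
        assert r1.t_statistic == pytest.approx(-r2.t_statistic)
        assert r1.p_value == pytest.approx(r2.p_value)
        ref_t, ref_p = sps.ttest_ind(a, b, equal_var=False)
        assert r1.t_statistic == pytest.approx(float(ref_t))
        assert r1.p_value == pytest.approx(float(ref_p))

    def test_degenerate_and_tiny_samples(self):
        r = st.welch_t_test([2.0, 2.0], [2.0, 2.0])
        assert r.degenerate and r.p_value == 1.0
        with pytest.raises(ValueError):
            st.welch_t_test([1.0], [1.0, 2.0])

    def test_sign_matches_mean_difference(self):
        r = st.welch_t_test([5.0, 6, 7], [1.0, 2, 3])
        assert r.t_statistic > 0 and r.mean_difference > 0


class TestAnova:
    def test_two_groups_f_is_squared_pooled_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 20)
        r = st.oneway_anova_with_levene({"a": a, "b": b})
        t_pooled, _ = sps.ttest_ind(a, b, equal_var=True)
        assert r.f_statistic == pytest.approx(float(t_pooled) ** 2)
        assert r.df_between == 1 and r.df_within == 33

    def test_all_constant_groups_degenerate(self):
        r = st.oneway_anova_with_levene({"a": [2.0, 2.0], "b": [2.0, 2.0, 2.0]})
        assert r.degenerate and r.f_statistic == 0.0

    def test_levene_detects_programmed_heteroscedasticity(self):
        """Five groups with the variance spread of vaccine-specific fever
        data trip the Levene check decisively."""
        rng = np.random.default_rng(2)
        groups = {f"g{i}": rng.normal(38.5 + 0.1 * i, 0.3 + 0.15 * i, 800)
                  for i in range(5)}
        r = st.oneway_anova_with_levene(groups)
        assert r.levene_p < 0.001
        assert r.p_value < 0.001
        ref_stat, ref_p = sps.levene(*groups.values(), center="mean")
        assert r.levene_statistic == pytest.approx(float(ref_stat))

    def test_group_size_validation(self):
        with pytest.raises(ValueError):
            st.oneway_anova_with_levene({"a": [1.0], "b": [1.0, 2.0]})


class TestDunnettT3:
    def test_needs_three_groups(self):
        with pytest.raises(ValueError, match="welch_t_test"):
            st.dunnett_t3({"a": [1, 2, 3], "b": [2, 3, 4]})

    def test_partition_isolates_separated_extremes(self):
        rng = np.random.default_rng(3)
        groups = {"lo": rng.normal(0, 1, 60),
                  "mid": rng.normal(0.2, 1.5, 60),
                  "hi": rng.normal(6, 1, 60)}
        r = st.dunnett_t3(groups)
        assert r.partition[0] == ["hi"]
        assert sorted(r.partition[1]) == ["lo", "mid"]

    def test_adjusted_p_bounded_below_by_welch_p(self):
        rng = np.random.default_rng(4)
        groups = {k: rng.normal(m, s, 25) for k, m, s in
                  [("a", 0, 1), ("b", 0.4, 2), ("c", 0.8, 0.5), ("d", 1.5, 3)]}
        r = st.dunnett_t3(groups)
        assert (r.pairs["p_adjusted"] >= r.pairs["p_welch"] - 1e-12).all()
        assert r.n_comparisons == 6

    def test_adjusted_p_grows_with_number_of_groups(self):
        """For a fixed pair, the multiplicity penalty increases as more
        groups enter the family of comparisons."""
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 30), rng.normal(0.7, 1.4, 30)
        extras = [rng.normal(0.3 * i, 1, 30) for i in range(4)]
        p_prev = 0.0
        for k in range(3, 6):
            groups = {"a": a, "b": b}
            groups.update({f"x{i}": extras[i] for i in range(k - 2)})
            r = st.dunnett_t3(groups)
            row = r.pairs.set_index(["group_a", "group_b"]).loc[("a", "b")]
            assert row["p_adjusted"] >= p_prev - 1e-12
            p_prev = row["p_adjusted"]

    def test_quadrature_and_monte_carlo_agree(self):
        """The SMM survival function by numerical integration matches a
        seeded million-draw Monte Carlo to about 1e-3."""
        for t, m, df in [(2.5, 10, 30.5), (3.2, 6, 14.0), (1.2, 3, 8.0)]:
            q = st.smm_sf(t, m, df)
            mc = st.smm_sf_mc(t, m, df, n_draws=1_000_000, seed=11)
            assert q == pytest.approx(mc, abs=2e-3)

    def test_smm_limits(self):
        assert st.smm_sf(0.0, 10, 20.0) == 1.0
        assert st.smm_sf(50.0, 10, 200.0) < 1e-8


class TestVif:
    def test_orthogonal_predictors_have_unit_vif(self):
        x1 = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        x2 = np.array([1.0, 1, -1, -1, 1, 1, -1, -1])
        r = st.compute_vif(pd.DataFrame({"x1": x1, "x2": x2}))
        assert np.allclose(r.table["vif"], 1.0)
        assert not r.any_flagged

    def test_closed_form_at_known_correlation(self):
        """Exact sample correlation 0.6 gives VIF = 1/(1-0.36) = 1.5625 for
        both predictors (shared auxiliary R-squared)."""
        z1 = np.array([1.0, -1, 1, -1, 1, -1, 1, -1])
        z2 = np.array([1.0, 1, -1, -1, 1, 1, -1, -1])
        x2 = 0.6 * z1 + 0.8 * z2
        r = st.compute_vif(pd.DataFrame({"age": z1, "weight": x2}))
        assert r.table["vif"].tolist() == pytest.approx([1.5625, 1.5625])

    def test_exact_collinearity_flagged_as_infinite(self):
        x = np.arange(10.0)
        r = st.compute_vif(pd.DataFrame({"a": x, "b": 2 * x + 1, "c": np.sin(x)}))
        assert np.isinf(r.table.set_index("predictor").loc["a", "vif"])
        assert r.any_flagged

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError):
            st.compute_vif(pd.DataFrame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]}))


class TestLogistic:
    def test_odds_ratio_reconstruction_identities(self):
        orr, lo, hi = st.odds_ratio_from_coef(0.226, 0.025)
        assert round(orr, 3) == 1.254
        assert lo < orr < hi
        orr0, lo0, hi0 = st.odds_ratio_from_coef(0.0, 0.1)
        assert orr0 == 1.0
        assert lo0 * hi0 == pytest.approx(1.0)  # symmetric in log space

    def test_recovers_programmed_coefficients(self):
        d = simulate_high_fever_outcomes(20_000, beta_age=0.0, beta_weight=0.2, seed=5)
        fit = st.fit_high_fever_logistic(d)
        tab = fit.table.set_index("term")
        assert fit.converged
        assert tab.loc["weight_kg", "coef"] == pytest.approx(0.2, abs=0.06)
        assert abs(tab.loc["age_months", "coef"]) < 0.05
        for r in fit.table.itertuples(index=False):
            assert r.odds_ratio == pytest.approx(math.exp(r.coef))
            assert r.ci_low < r.odds_ratio < r.ci_high

    def test_score_equations_satisfied_at_convergence(self):
        d = simulate_high_fever_outcomes(3000, seed=6)
        fit = st.fit_high_fever_logistic(d)
        X = np.column_stack([np.ones(len(d)), d["age_months"], d["weight_kg"],
                             (d["sex"] == "male").astype(float)])
        beta = fit.table["coef"].to_numpy()
        p = 1.0 / (1.0 + np.exp(-X @ beta))
        grad = X.T @ (d["high_fever"].to_numpy() - p)
        assert np.linalg.norm(grad) < 1e-6

    def test_perfect_separation_raises_naming_predictor(self):
        d = pd.DataFrame({
            "age_months": [1.0, 2, 3, 10, 11, 12],
            "weight_kg": [5.0, 5.5, 6, 8, 8.5, 9],
            "sex": ["male", "female"] * 3,
            "high_fever": [0, 0, 0, 1, 1, 1],
        })
        with pytest.raises(st.SeparationError, match="age_months|weight_kg"):
            st.fit_high_fever_logistic(d)

    def test_single_class_outcome_rejected(self):
        d = simulate_high_fever_outcomes(100, seed=7)
        d["high_fever"] = 0
        with pytest.raises(ValueError):
            st.fit_high_fever_logistic(d)

    def test_two_predictor_vif_equality_on_cohort(self):
        """With age and weight as the only continuous collinear pair, their
        VIFs share the auxiliary R-squared up to the sex adjustment."""
        d = simulate_high_fever_outcomes(5000, seed=8)
        fit = st.fit_high_fever_logistic(d)
        v = fit.vif.table.set_index("predictor")["vif"]
        assert v["age_months"] == pytest.approx(v["weight_kg"], rel=0.02)
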