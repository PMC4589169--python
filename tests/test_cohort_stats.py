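"""Tests of the statistical battery against oracles and known distributions."""

import numpy as np
import pandas as pd
import pytest

from wmhpath import synthgen as sg
from wmhpath.cohort_stats import (
    chi_square_2x2,
    mann_whitney_u,
    partial_corr,
    pooled_t,
    pooled_t_from_samples,
    route_test,
    stepwise_forward,
)


class TestPooledT:
    def test_mmse_contrast_from_published_summaries(self):
        t, df, p = pooled_t(28, 2.09, 6, 4.33, 3.9, 18)
        assert df == 22
        assert t == pytest.approx(14.07, abs=0.05)
        assert p < 0.001

    def test_pmd_contrast_from_published_summaries(self):
        t, df, p = pooled_t(49.95, 22.89, 22, 47.15, 24.43, 13)
        assert df == 33
        assert abs(t) == pytest.approx(0.34, abs=0.01)

    def test_identical_groups_give_zero(self, rng):
        x = rng.normal(size=30)
        t, df, _ = pooled_t_from_samples(x, x)
        assert t == pytest.approx(0.0, abs=1e-12) and df == 58

    def test_matches_scipy_summary_route(self, rng):
        from scipy import stats
        x, y = rng.normal(0, 1, 20), rng.normal(0.5, 1.2, 15)
        t1, _, p1 = pooled_t(x.mean(), x.std(ddof=1), 20, y.mean(), y.std(ddof=1), 15)
        ref = stats.ttest_ind(x, y, equal_var=True)
        assert t1 == pytest.approx(ref.statistic) and p1 == pytest.approx(ref.pvalue)

    def test_degenerate_group_rejected(self):
        with pytest.raises(ValueError):
            pooled_t(1.0, 1.0, 1, 2.0, 1.0, 10)


def _u_oracle(x, y):
    """All-pairs counting: U for x plus half-credit for ties."""
    u1 = sum((xi > yi) + 0.5 * (xi == yi) for xi in x for yi in y)
    return min(u1, len(x) * len(y) - u1)


class TestMannWhitney:
    def test_thal_phase_complete_separation(self):
        ad = [5] * 23
        ctrl = [0] * 5 + [1] * 3 + [2] * 3 + [3] + [4]
        u, p = mann_whitney_u(ad, ctrl)
        assert u == 0.0 and p < 0.001

    def test_braak_stage_complete_separation(self):
        ad = [6] * 23
        ctrl = [0] * 2 + [1] + [2] * 3 + [3] * 6 + [4]
        u, _ = mann_whitney_u(ad, ctrl)
        assert u == 0.0

    def test_full_ties_give_half_product(self):
        u, _ = mann_whitney_u([3.0] * 4, [3.0] * 5)
        assert u == 4 * 5 / 2

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=rng.integers(3, 12)).astype(float)
        y = rng.integers(0, 6, size=rng.integers(3, 12)).astype(float)
        u, _ = mann_whitney_u(x, y)
        assert u == pytest.approx(_u_oracle(x, y))


class TestPartialCorr:
    def test_self_correlation_is_one(self, rng):
        x = rng.normal(size=50)
        z = rng.normal(size=50)
        res = partial_corr(x, x.copy(), z)
        assert res.coefficient == pytest.approx(1.0)

    def test_constant_covariate_is_no_op_control(self, rng):
        x = rng.normal(size=60)
        y = x + rng.normal(size=60)
        plain = partial_corr(x, y, None, method="pearson")
        nulled = partial_corr(x, y, np.full(60, 7.0), method="pearson")
        assert nulled.coefficient == pytest.approx(plain.coefficient)

    def test_df_accounts_for_covariates(self, rng):
        x, y = rng.normal(size=40), rng.normal(size=40)
        z = rng.normal(size=(40, 2))
        res = partial_corr(x, y, z)
        assert res.df == 40 - 2 - 2

    def test_known_trivariate_partial_recovered(self):
        rng = np.random.default_rng(5)
        # rho_xy=0.625, rho_xz=rho_yz=0.5 -> partial(x,y|z) = 0.5 exactly
        C = np.array([[1, 0.625, 0.5], [0.625, 1, 0.5], [0.5, 0.5, 1]])
        X = rng.multivariate_normal(np.zeros(3), C, size=5000)
        res = partial_corr(X[:, 0], X[:, 1], X[:, 2], method="pearson")
        assert res.coefficient == pytest.approx(0.5, abs=0.03)

    def test_matches_pingouin_reference(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = pd.DataFrame({"x": rng.normal(size=60)})
        df["z"] = rng.normal(size=60)
        df["y"] = 0.5 * df.x + 0.3 * df.z + rng.normal(size=60)
        for method in ("pearson", "spearman"):
            mine = partial_corr(df.x, df.y, {"z": df.z}, method=method)
            ref = pingouin.partial_corr(df, x="x", y="y", covar="z", method=method)
            assert mine.coefficient == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
            assert mine.p_two_tailed == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-6)

    def test_spearman_invariant_to_monotone_transform(self, rng):
        x = rng.normal(size=80)
        y = x + rng.normal(size=80)
        z = rng.normal(size=80)
        a = partial_corr(x, y, z, method="spearman")
        b = partial_corr(np.exp(x), y, z, method="spearman")
        assert a.coefficient == pytest.approx(b.coefficient)

    def test_constant_input_after_ranking_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            partial_corr(np.ones(20), np.arange(20.0), np.arange(20.0))

    def test_one_tailed_p_directional(self, rng):
        x = rng.normal(size=50)
        y = -x + rng.normal(size=50) * 0.1
        res = partial_corr(x, y, None, alternative="greater")
        assert res.p_one_tailed > 0.99  # strong negative association


class TestStepwise:
    def test_single_dominant_predictor_recovered(self):
        rng = np.random.default_rng(9)
        hits = 0
        for _ in range(50):
            X = pd.DataFrame(rng.standard_normal((200, 4)), columns=list("abcd"))
            y = 0.8 * X["a"] + rng.normal(0, 0.5, 200)
            model = stepwise_forward(y, X)
            hits += bool(model.selected) and model.selected[0] == "a"
        assert hits >= 48

    def test_exact_dependence_gives_unit_model(self, rng):
        X = pd.DataFrame(rng.standard_normal((60, 3)), columns=list("abc"))
        model = stepwise_forward(X["a"].copy(), X)
        assert model.selected == ("a",)
        assert model.r_squared == pytest.approx(1.0)
        assert model.beta_std["a"] == pytest.approx(1.0)

    def test_excluded_candidates_reported(self, rng):
        X = pd.DataFrame(rng.standard_normal((100, 3)), columns=list("abc"))
        y = X["a"] + rng.normal(0, 0.3, 100)
        model = stepwise_forward(y, X)
        assert set(model.excluded) == set("abc") - set(model.selected)
        for beta, p in model.excluded.values():
            assert 0 <= p <= 1

    def test_collinear_pair_named_in_error(self, rng):
        a = rng.standard_normal(50)
        X = pd.DataFrame({"a": a, "twin": a * 2.0, "c": rng.standard_normal(50)})
        with pytest.raises(ValueError, match="a.*twin|twin.*a"):
            stepwise_forward(rng.standard_normal(50), X)

    def test_entry_must_be_below_removal(self, rng):
        X = pd.DataFrame(rng.standard_normal((30, 2)), columns=list("ab"))
        with pytest.raises(ValueError):
            stepwise_forward(X["a"], X, entry_p=0.10, removal_p=0.05)


class TestRouting:
    def test_gaussian_samples_route_parametric(self, rng):
        d = route_test({"g1": rng.normal(size=300), "g2": rng.normal(size=300)})
        assert d.route == "parametric"

    def test_skewed_samples_route_nonparametric(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(50):
            d = route_test({"g1": rng.exponential(size=50),
                            "g2": rng.exponential(size=50)})
            hits += d.route == "nonparametric"
        assert hits >= 48  # Shapiro-Wilk nearly always rejects exponential at n=50

    def test_tiny_group_flagged_nonparametric(self, rng):
        d = route_test({"g1": rng.normal(size=2), "g2": rng.normal(size=30)})
        assert d.route == "nonparametric" and d.flagged


class TestChiSquare:
    def test_proportional_table_is_zero(self):
        chi2, df, p = chi_square_2x2([[10, 20], [5, 10]])
        assert chi2 == pytest.approx(0.0, abs=1e-12) and df == 1

    def test_gender_style_table_hand_value(self):
        # N(ad-bc)^2 / (r1 r2 c1 c2) = 38*34^2/(23*15*18*20) = 0.3537
        chi2, _, _ = chi_square_2x2([[10, 13], [8, 7]])
        assert chi2 == pytest.approx(0.3537, abs=0.0005)

    def test_row_swap_invariance(self):
        a, _, _ = chi_square_2x2([[10, 13], [8, 7]])
        b, _, _ = chi_square_2x2([[8, 7], [10, 13]])
        assert a == pytest.approx(b)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_2x2([[0, 0], [5, 10]])


class TestCopulaPower:
    def test_latent_partial_04_detected_in_majority_of_cohorts(self):
        """Cohorts with tau-WMH latent partial correlation 0.4 at n=36 yield a
        one-tailed positive partial Spearman p < 0.05 in most replicates."""
        corr = sg.latent_corr_with_partial(0.4)
        hits = 0
        reps = 200
        for i in range(reps):
            df = sg.make_cohort(sg.CohortConfig(
                n_cases=36, latent_corr=corr, group_shift=(0,) * 5, seed=50_000 + i))
            res = partial_corr(df.hpt_total, df.arwmc_total,
                               {"age": df.age_at_death}, method="spearman",
                               tails=1, alternative="greater")
            hits += res.p_one_tailed < 0.05
        assert hits / reps > 0.5
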