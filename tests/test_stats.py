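"""Statistical layer: ANOVA/Tukey letters, OLS + backward AIC, VIF, LMG."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from chamberflux.stats import (backward_aic, compact_letter_display,
                               lmg_shares, ols_fit, one_way_anova, vif)


def _groups_from(rng, means, n=5, sd=1.0):
    return {f"g{i}": rng.normal(m, sd, n) for i, m in enumerate(means)}


class TestAnova:
    def test_f_matches_independent_implementation(self, rng):
        groups = _groups_from(rng, [0.0, 1.0, 3.0], n=5)
        res = one_way_anova(groups)
        f_ref, p_ref = sps.f_oneway(*groups.values())
        assert res.f_stat == pytest.approx(f_ref, rel=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-12)
        assert (res.df_between, res.df_within) == (2, 12)

    def test_identical_groups_share_one_letter(self):
        g = {k: np.array([1.0, 2.0, 3.0, 4.0]) for k in ("a", "b", "c")}
        res = one_way_anova(g)
        assert res.f_stat == 0.0
        assert len(set(res.group_letters.values())) == 1

    def test_perfectly_separated_groups_get_distinct_letters(self, rng):
        g = {"g0": 0.0 + rng.normal(0, 1e-3, 4),
             "g1": 10.0 + rng.normal(0, 1e-3, 4),
             "g2": 20.0 + rng.normal(0, 1e-3, 4)}
        res = one_way_anova(g)
        letters = list(res.group_letters.values())
        assert len(set(letters)) == 3
        assert all(len(l) == 1 for l in letters)

    def test_pairwise_p_matches_scipy_tukey_hsd_balanced(self, rng):
        groups = _groups_from(rng, [0.0, 0.8, 2.5], n=6)
        res = one_way_anova(groups)
        ref = sps.tukey_hsd(*groups.values())
        labels = sorted(groups)
        for (i, gi), (j, gj) in itertools.combinations(enumerate(labels), 2):
            assert res.pairwise_p[frozenset((gi, gj))] == pytest.approx(
                ref.pvalue[i, j], abs=1e-9)

    def test_letters_consistent_with_pairwise_significance(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            groups = _groups_from(r, [0.0, 1.0, 2.0, 4.0], n=5, sd=1.2)
            res = one_way_anova(groups)
            for g1, g2 in itertools.combinations(sorted(groups), 2):
                share = bool(set(res.group_letters[g1])
                             & set(res.group_letters[g2]))
                sig = res.pairwise_p[frozenset((g1, g2))] < 0.05
                assert share != sig, (g1, g2, res.group_letters)

    def test_undersized_group_is_named_in_error(self):
        with pytest.raises(ValueError, match="tiny"):
            one_way_anova({"ok": np.arange(4.0), "tiny": np.array([1.0])})

    def test_row_permutation_invariance(self, rng):
        groups = _groups_from(rng, [0.0, 1.5], n=8)
        permuted = {k: v[::-1].copy() for k, v in groups.items()}
        assert one_way_anova(groups).f_stat == pytest.approx(
            one_way_anova(permuted).f_stat, rel=1e-12)

    def test_studentized_range_monte_carlo_cross_check(self, rng):
        # empirical 95th percentile of the studentized range (k=3, df=12)
        k, n, reps = 3, 5, 20000
        draws = rng.normal(size=(reps, k, n))
        means = draws.mean(axis=2)
        s2 = draws.var(axis=2, ddof=1).mean(axis=1)
        q = (means.max(axis=1) - means.min(axis=1)) / np.sqrt(s2 / n)
        emp = np.quantile(q, 0.95)
        ref = sps.studentized_range.ppf(0.95, k, k * (n - 1))
        assert emp == pytest.approx(ref, rel=0.03)


class TestCompactLetterDisplay:
    def test_chain_structure_shares_letters_transitively(self):
        # a~b and b~c non-significant, a-c significant: b bridges both sets
        p = {frozenset(("a", "b")): 0.5, frozenset(("b", "c")): 0.5,
             frozenset(("a", "c")): 0.01}
        letters = compact_letter_display(["a", "b", "c"], p)
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])


class TestOls:
    def test_noise_free_plane_is_recovered_exactly(self, rng):
        X = pd.DataFrame({"x1": rng.normal(size=30), "x2": rng.normal(size=30)})
        y = 2 * X["x1"] - 3 * X["x2"] + 1
        fit = ols_fit(y, X)
        assert fit.coefficients["x1"] == pytest.approx(2.0, abs=1e-10)
        assert fit.coefficients["x2"] == pytest.approx(-3.0, abs=1e-10)
        assert fit.intercept == pytest.approx(1.0, abs=1e-10)
        assert fit.multiple_r2 == pytest.approx(1.0, abs=1e-12)

    def test_coefficients_match_normal_equations(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        y = rng.normal(size=40)
        fit = ols_fit(y, X)
        D = np.column_stack([np.ones(40), X.to_numpy()])
        beta = np.linalg.solve(D.T @ D, D.T @ y)
        assert fit.intercept == pytest.approx(beta[0], rel=1e-9)
        for b, c in zip(beta[1:], "abc"):
            assert fit.coefficients[c] == pytest.approx(b, rel=1e-9)

    def test_r2_invariant_under_affine_rescaling(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 2)), columns=["a", "b"])
        y = X["a"] + rng.normal(size=40)
        f1 = ols_fit(y, X)
        X2 = X.copy()
        X2["a"] = 100.0 * X2["a"] - 7.0
        f2 = ols_fit(y, X2)
        assert f1.multiple_r2 == pytest.approx(f2.multiple_r2, rel=1e-12)

    def test_rank_deficiency_is_reported(self, rng):
        X = pd.DataFrame({"a": rng.normal(size=20)})
        X["b"] = 2.0 * X["a"]
        with pytest.raises(ValueError, match="collinear"):
            ols_fit(rng.normal(size=20), X)


class TestBackwardAic:
    def test_pure_noise_predictor_is_removed(self):
        r = np.random.default_rng(100)
        X = pd.DataFrame(r.normal(size=(100, 3)),
                         columns=["signal1", "signal2", "noise"])
        y = 3 * X["signal1"] - 2 * X["signal2"] + r.normal(0, 0.5, 100)
        fit = backward_aic(y, X)
        assert "noise" not in fit.predictors
        assert {"signal1", "signal2"} <= set(fit.predictors)

    def test_single_relevant_predictor_is_retained(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=50)})
        y = 2 * X["x"] + rng.normal(0, 0.1, 50)
        fit = backward_aic(y, X)
        assert fit.predictors == ("x",)

    def test_never_worse_than_full_model(self):
        for seed in range(8):
            r = np.random.default_rng(seed)
            X = pd.DataFrame(r.normal(size=(30, 4)), columns=list("abcd"))
            y = X["a"] + 0.2 * X["b"] + r.normal(size=30)
            assert backward_aic(y, X).aic <= ols_fit(y, X).aic + 1e-12

    def test_matches_exhaustive_subset_search(self):
        # brute-force all-subsets AIC oracle, p = 4
        agree = 0
        for seed in range(10):
            r = np.random.default_rng(1000 + seed)
            X = pd.DataFrame(r.normal(size=(60, 4)), columns=list("abcd"))
            y = (1.5 * X["a"] + 0.8 * X["b"] + r.normal(0, 1.0, 60))
            greedy = backward_aic(y, X)
            best = min(
                (ols_fit(y, X[list(sub)]) for k in range(1, 5)
                 for sub in itertools.combinations(X.columns, k)),
                key=lambda f: f.aic)
            assert greedy.aic >= best.aic - 1e-12   # oracle bound always holds
            if set(greedy.predictors) == set(best.predictors):
                agree += 1
        # the greedy path is optimal on these well-separated designs
        assert agree >= 8


class TestVif:
    def test_orthogonal_design_gives_unit_vifs(self):
        n = 8
        X = pd.DataFrame({"a": np.tile([1.0, -1.0], n // 2),
                          "b": np.repeat([1.0, -1.0], n // 2)})
        for v in vif(X).values():
            assert v == pytest.approx(1.0, abs=1e-10)

    def test_closed_form_for_known_correlation(self, rng):
        # construct exact sample correlation r = 0.8 -> VIF = 1/(1-0.64)
        z = rng.normal(size=(50, 2))
        q, _ = np.linalg.qr(z - z.mean(axis=0))
        x1, x2 = q[:, 0], 0.8 * q[:, 0] + np.sqrt(1 - 0.64) * q[:, 1]
        vifs = vif(pd.DataFrame({"x1": x1, "x2": x2}))
        assert vifs["x1"] == pytest.approx(1.0 / (1.0 - 0.64), rel=1e-9)
        assert vifs["x2"] == pytest.approx(2.7778, abs=1e-4)

    def test_duplicated_column_reports_infinite_vif(self, rng):
        x = rng.normal(size=30)
        vifs = vif(pd.DataFrame({"a": x, "b": x}))
        assert np.isinf(vifs["a"]) and np.isinf(vifs["b"])


class TestLmg:
    def test_orthogonal_shares_equal_marginal_r2(self):
        n = 16
        X = pd.DataFrame({"a": np.tile([1.0, -1.0], n // 2),
                          "b": np.repeat([1.0, -1.0], n // 2)})
        r = np.random.default_rng(7)
        y = 2 * X["a"] + 1 * X["b"] + r.normal(0, 0.3, n)
        res = lmg_shares(y, X)
        for col in X.columns:
            marginal = ols_fit(y, X[[col]]).multiple_r2
            assert res.shares[col] == pytest.approx(marginal, rel=1e-9)

    def test_matches_literal_ordering_enumeration(self, rng):
        # independent oracle: average incremental R2 over all 3! orderings
        X = pd.DataFrame(rng.normal(size=(40, 3)), columns=list("abc"))
        X["b"] = 0.6 * X["a"] + 0.8 * X["b"]           # correlated design
        y = X["a"] + 0.5 * X["b"] - 0.7 * X["c"] + rng.normal(0, 1.0, 40)
        res = lmg_shares(y, X)

        def r2(cols):
            return ols_fit(y, X[list(cols)]).multiple_r2 if cols else 0.0

        for col in X.columns:
            acc = 0.0
            for order in itertools.permutations(X.columns):
                k = order.index(col)
                acc += r2(order[:k + 1]) - r2(order[:k])
            assert res.shares[col] == pytest.approx(acc / 6.0, rel=1e-9)

    def test_shares_sum_to_full_model_r2(self, rng):
        for _ in range(3):
            X = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
            y = X.sum(axis=1) + rng.normal(size=30)
            res = lmg_shares(y, X)
            assert sum(res.shares.values()) == pytest.approx(
                ols_fit(y, X).multiple_r2, abs=1e-9)
            assert res.total == pytest.approx(ols_fit(y, X).multiple_r2,
                                              abs=1e-12)

    def test_refuses_wide_designs(self, rng):
        X = pd.DataFrame(rng.normal(size=(40, 11)))
        X.columns = [f"p{i}" for i in range(11)]
        with pytest.raises(ValueError, match="p <= 10"):
            lmg_shares(rng.normal(size=40), X)
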