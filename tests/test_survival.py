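import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from lifedemog.survival import (
    GLM,
    StatsError,
    TestResult,
    candidate_models,
    glm_fit,
    km_estimate,
    kruskal_wallis,
    logrank_test,
    pairwise_logrank,
    pairwise_wilcoxon,
    select_model_aic,
    wilcoxon_rank_sum,
)


class TestKaplanMeier:
    def test_all_die_at_two(self):
        km = km_estimate([2, 2, 2], [True] * 3)
        assert km.survival_at(1.9) == 1.0
        assert km.survival_at(2.0) == 0.0

    def test_hand_product_limit(self):
        km = km_estimate([1, 2, 2, 3], [True] * 4)
        np.testing.assert_allclose(km.survival, [0.75, 0.25, 0.0])
        np.testing.assert_array_equal(km.n_at_risk, [4, 3, 1])
        np.testing.assert_array_equal(km.n_events, [1, 2, 1])

    def test_censored_only(self):
        km = km_estimate([1, 2, 3], [False] * 3)
        assert km.event_times.size == 0
        assert km.survival_at(10.0) == 1.0

    def test_no_censoring_matches_empirical_fraction(self):
        rng = np.random.default_rng(0)
        t = rng.integers(1, 10, 30).astype(float)
        km = km_estimate(t, [True] * 30)
        for ti in np.unique(t):
            assert km.survival_at(ti) == pytest.approx(np.mean(t > ti))

    def test_empty_rejected(self):
        with pytest.raises(StatsError):
            km_estimate([], [])


class TestLogRank:
    def test_identical_groups(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [True] * 4
        res = logrank_test(t, e, t, e)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_raw == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        ta, tb = rng.exponential(3, 15), rng.exponential(5, 12)
        ea, eb = rng.random(15) < 0.8, rng.random(12) < 0.8
        r1 = logrank_test(ta, ea, tb, eb)
        r2 = logrank_test(tb, eb, ta, ea)
        assert r1.statistic == pytest.approx(r2.statistic, abs=1e-12)

    def test_direct_moment_oracle(self):
        # brute-force hypergeometric moments on a tied fixture
        ta, ea = [1.0, 1.0, 2.0, 3.0], [True, True, True, False]
        tb, eb = [1.0, 2.0, 2.0, 3.0], [True, False, True, True]
        t_all = np.r_[ta, tb]
        e_all = np.r_[ea, eb]
        o_e, v = 0.0, 0.0
        for ti in np.unique(t_all[e_all]):
            n1 = np.sum(np.asarray(ta) >= ti)
            n2 = np.sum(np.asarray(tb) >= ti)
            n = n1 + n2
            d = np.sum((t_all == ti) & e_all)
            d1 = np.sum((np.asarray(ta) == ti) & np.asarray(ea))
            rv = hypergeom(n, n1, d)
            o_e += d1 - rv.mean()
            v += rv.var() * (1 if n > 1 else 0)
        expected = o_e**2 / v
        res = logrank_test(ta, ea, tb, eb)
        assert res.statistic == pytest.approx(expected, abs=1e-10)

    def test_agreement_with_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(2)
        for _ in range(50):
            n1, n2 = rng.integers(5, 25, 2)
            ta = np.round(rng.exponential(4, n1) * 2) / 2 + 0.5
            tb = np.round(rng.exponential(6, n2) * 2) / 2 + 0.5
            ea = rng.random(n1) < 0.85
            eb = rng.random(n2) < 0.85
            if not (ea.any() or eb.any()):
                continue
            mine = logrank_test(ta, ea, tb, eb)
            ref = ll_logrank(ta, tb, ea, eb)
            assert mine.statistic == pytest.approx(ref.test_statistic, abs=1e-8)
            assert mine.p_raw == pytest.approx(ref.p_value, abs=1e-6)

    def test_no_events_raises(self):
        with pytest.raises(StatsError):
            logrank_test([1, 2], [False, False], [1, 2], [False, False])

    def test_pairwise_counts_and_bonferroni(self):
        rng = np.random.default_rng(3)
        groups = {
            k: (rng.exponential(4, 10), np.ones(10, dtype=bool))
            for k in ("a", "b", "c")
        }
        results = pairwise_logrank(groups)
        assert len(results) == 3
        for res in results:
            assert res.p_adjusted == pytest.approx(min(1.0, 3 * res.p_raw))


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis({"a": [5, 5, 5], "b": [5, 5, 5]})
        assert res.statistic == 0.0
        assert res.p_raw == 1.0

    def test_brute_force_rank_oracle_with_ties(self):
        groups = {"a": [1.0, 2.0, 2.0], "b": [2.0, 3.0], "c": [3.0, 4.0, 4.0]}
        pooled = np.concatenate(list(groups.values()))
        order = np.argsort(pooled, kind="stable")
        ranks = np.empty_like(pooled)
        # explicit average ranks
        sorted_vals = pooled[order]
        r = np.arange(1, len(pooled) + 1, dtype=float)
        for v in np.unique(sorted_vals):
            m = sorted_vals == v
            r[m] = r[m].mean()
        ranks[order] = r
        n = len(pooled)
        h = 0.0
        start = 0
        for vals in groups.values():
            h += ranks[start:start + len(vals)].sum() ** 2 / len(vals)
            start += len(vals)
        h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
        ties = sum(
            (np.sum(pooled == v) ** 3 - np.sum(pooled == v))
            for v in np.unique(pooled)
        )
        h /= 1 - ties / (n**3 - n)
        res = kruskal_wallis(groups)
        assert res.statistic == pytest.approx(h, abs=1e-10)
        assert res.df == 2

    def test_agreement_with_scipy(self):
        from scipy.stats import kruskal

        rng = np.random.default_rng(4)
        for _ in range(50):
            groups = {
                str(i): rng.poisson(8, rng.integers(4, 15)) for i in range(3)
            }
            mine = kruskal_wallis(groups)
            ref = kruskal(*groups.values())
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-8)
            assert mine.p_raw == pytest.approx(ref.pvalue, abs=1e-6)

    def test_two_group_ordering_consistent_with_rank_sum(self):
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 12)
        b = rng.normal(1.0, 1, 14)
        kw = kruskal_wallis({"a": a, "b": b})
        mw = wilcoxon_rank_sum(a, b)
        # both see the same rank separation: significance must agree
        assert (kw.p_raw < 0.05) == (mw.p_raw < 0.05)


class TestWilcoxon:
    def test_identical_pair(self):
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p_raw == pytest.approx(1.0)

    def test_exact_fully_separated_three_vs_three(self):
        # U = 0; exact two-sided p = 2 * (1 / C(6,3)) = 0.1
        res = wilcoxon_rank_sum([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert res.method == "wilcoxon-exact"
        assert res.statistic == 0.0
        assert res.p_raw == pytest.approx(0.1, abs=1e-12)

    def test_exact_agreement_with_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(6)
        for _ in range(50):
            a = rng.normal(0, 1, int(rng.integers(3, 9)))
            b = rng.normal(0.8, 1, int(rng.integers(3, 9)))
            mine = wilcoxon_rank_sum(a, b)
            ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert mine.method == "wilcoxon-exact"
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_raw == pytest.approx(ref.pvalue, abs=1e-10)

    def test_asymptotic_agreement_with_scipy(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(7)
        for _ in range(50):
            a = rng.poisson(10, int(rng.integers(9, 25)))  # ties guaranteed
            b = rng.poisson(12, int(rng.integers(9, 25)))
            mine = wilcoxon_rank_sum(a, b)
            ref = mannwhitneyu(a, b, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
            assert mine.method == "wilcoxon-normal"
            assert mine.statistic == pytest.approx(ref.statistic, abs=1e-10)
            assert mine.p_raw == pytest.approx(ref.pvalue, abs=1e-8)

    def test_pairwise_bonferroni_capped(self):
        rng = np.random.default_rng(8)
        groups = {k: rng.normal(0, 1, 10) for k in "abcd"}
        results = pairwise_wilcoxon(groups)
        assert len(results) == 6
        for res in results:
            assert res.p_adjusted == pytest.approx(min(1.0, 6 * res.p_raw))
            assert res.p_adjusted <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(StatsError):
            wilcoxon_rank_sum([], [1.0])

    @given(st.lists(st.floats(0.001, 0.999), min_size=2, max_size=10),
           st.integers(2, 10))
    @settings(max_examples=50, deadline=None)
    def test_bonferroni_monotone_and_capped(self, p_raws, m):
        adj = [min(1.0, m * p) for p in p_raws]
        order = np.argsort(p_raws)
        assert all(adj[order[i]] <= adj[order[i + 1]] + 1e-15
                   for i in range(len(order) - 1))
        assert all(a <= 1.0 for a in adj)


class TestGLM:
    def test_intercept_only_gaussian_is_mean(self):
        y = np.array([1.0, 2.0, 3.0, 10.0])
        res = glm_fit(np.ones((4, 1)), y, family="gaussian")
        assert res.params.iloc[0] == pytest.approx(y.mean(), abs=1e-12)

    def test_gaussian_equals_least_squares_closed_form(self):
        rng = np.random.default_rng(9)
        x = np.column_stack([np.ones(40), rng.normal(size=(40, 2))])
        y = x @ [1.0, -2.0, 0.5] + rng.normal(size=40)
        res = glm_fit(x, y, family="gaussian")
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(res.params.values, beta, atol=1e-10)

    def test_noise_free_gaussian_zero_deviance(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        y = x @ [2.0, 3.0]
        res = glm_fit(x, y, family="gaussian")
        assert res.deviance == pytest.approx(0.0, abs=1e-18)

    def test_poisson_matches_newton_oracle(self):
        # independent Newton-Raphson on the Poisson log-likelihood
        x = np.column_stack([np.ones(5), np.arange(1.0, 6.0)])
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        beta = np.zeros(2)
        for _ in range(50):
            mu = np.exp(x @ beta)
            grad = x.T @ (y - mu)
            hess = x.T @ (mu[:, None] * x)
            beta = beta + np.linalg.solve(hess, grad)
        res = glm_fit(x, y, family="poisson")
        np.testing.assert_allclose(res.params.values, beta, atol=1e-8)

    def test_poisson_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(10)
        x = np.column_stack([np.ones(60), rng.normal(size=60)])
        y = rng.poisson(np.exp(0.3 + 0.5 * x[:, 1]))
        mine = glm_fit(x, y, family="poisson")
        ref = sm.GLM(y, x, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(mine.params.values, ref.params, atol=1e-8)
        assert mine.log_likelihood == pytest.approx(ref.llf, abs=1e-8)
        assert mine.aic == pytest.approx(ref.aic, abs=1e-8)

    def test_aic_identity(self):
        rng = np.random.default_rng(11)
        x = np.column_stack([np.ones(30), rng.normal(size=30)])
        y = rng.poisson(3.0, 30).astype(float)
        res = glm_fit(x, y, family="poisson")
        assert res.aic == pytest.approx(
            2 * len(res.params) - 2 * res.log_likelihood
        )

    def test_rank_deficient_rejected(self):
        x = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(StatsError):
            glm_fit(x, np.arange(10.0), family="gaussian")


class TestModelSelection:
    def _fit(self, aic, k, name):
        import pandas as pd

        from lifedemog.survival import GLMResults

        return GLMResults(family="poisson", params=pd.Series(np.zeros(k)),
                          log_likelihood=(2 * k - aic) / 2.0, deviance=0.0,
                          aic=aic, converged=True, n_obs=10, n_iter=1,
                          name=name)

    def test_single_candidate(self):
        only = self._fit(10.0, 2, "m")
        assert select_model_aic([only]) is only

    def test_tie_prefers_smaller_model(self):
        small = self._fit(10.0, 2, "small")
        big = self._fit(10.0, 4, "big")
        assert select_model_aic([big, small]) is small

    def test_empty_rejected(self):
        with pytest.raises(StatsError):
            select_model_aic([])

    def test_interaction_recovered_from_strong_interaction_data(self):
        import pandas as pd

        rng = np.random.default_rng(12)
        n = 200
        species = rng.choice(["s1", "s2"], n)
        temp = rng.choice([20.0, 26.0, 32.0], n)
        inter = (species == "s2") * (temp - 20.0)
        y = 10.0 - 0.2 * (temp - 20.0) - 1.5 * inter + rng.normal(0, 0.5, n)
        frame = pd.DataFrame(
            {"species": species, "temperature_C": temp, "lifespan": y}
        )
        fits = [m.fit() for m in candidate_models(frame, "lifespan")]
        best = select_model_aic(fits)
        assert best.name == "temperature+species+interaction"

    def test_candidate_lattice_size_and_nesting(self):
        import pandas as pd

        rng = np.random.default_rng(13)
        frame = pd.DataFrame(
            {
                "species": rng.choice(["s1", "s2"], 50),
                "temperature_C": rng.choice([20.0, 26.0], 50),
                "lifespan": rng.normal(5, 1, 50),
            }
        )
        models = candidate_models(frame, "lifespan")
        assert [m.name for m in models] == [
            "temperature", "species", "temperature+species",
            "temperature+species+interaction",
        ]
        sizes = [len(m.fit().params) for m in models]
        assert sizes == [2, 2, 3, 4]
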