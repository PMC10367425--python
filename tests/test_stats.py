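"""Group statistics: Kruskal-Wallis, Dunn, BH, Monte-Carlo Fisher, ORA."""

from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mucosanet.stats import (
    benjamini_hochberg,
    dunn_posthoc,
    fisher_monte_carlo,
    hypergeometric_ora,
    kruskal_wallis,
    kruskal_wallis_table,
)


class TestKruskalWallis:
    def test_closed_form_toy(self):
        # rank sums 6 / 15 / 24 over N=9 give H = 7.2 exactly
        r = kruskal_wallis([1, 2, 3, 4, 5, 6, 7, 8, 9], ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert r.H == pytest.approx(7.2, abs=1e-12)
        assert r.df == 2
        assert r.p == pytest.approx(float(sps.chi2.sf(7.2, 2)), rel=1e-12)

    def test_identical_group_multisets_give_zero(self):
        r = kruskal_wallis([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert r.H == pytest.approx(0.0, abs=1e-12)

    def test_all_identical_values_h_zero_p_one(self):
        r = kruskal_wallis([5.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert r.H == 0.0 and r.p == 1.0

    def test_empty_group_after_na_removal_raises(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1.0, 2.0, np.nan], ["a", "a", "b"])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 6, size=30).astype(float)  # heavy ties
        groups = rng.choice(["a", "b", "c"], size=30)
        if min((groups == g).sum() for g in "abc") == 0:
            pytest.skip("degenerate draw")
        ours = kruskal_wallis(vals, groups)
        ref = sps.kruskal(*(vals[groups == g] for g in "abc"))
        assert ours.H == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(10)
        vals = rng.lognormal(size=24)
        groups = np.repeat(["a", "b", "c"], 8)
        h1 = kruskal_wallis(vals, groups).H
        h2 = kruskal_wallis(np.log(vals), groups).H
        h3 = kruskal_wallis(vals**3, groups).H
        assert h1 == pytest.approx(h2, rel=1e-12) == pytest.approx(h3, rel=1e-12)

    def test_two_groups_equals_squared_standardized_mann_whitney(self):
        rng = np.random.default_rng(11)
        vals = rng.normal(size=20)  # tie-free
        groups = np.repeat(["a", "b"], 10)
        h = kruskal_wallis(vals, groups).H
        u = sps.mannwhitneyu(vals[:10], vals[10:], method="asymptotic").statistic
        n1 = n2 = 10
        z = (u - n1 * n2 / 2) / np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert h == pytest.approx(z**2, rel=1e-10)

    def test_table_adjusts_across_features(self):
        rng = np.random.default_rng(12)
        values = pd.DataFrame(rng.normal(size=(24, 5)), columns=list("vwxyz"))
        groups = np.repeat(["a", "b", "c"], 8)
        out = kruskal_wallis_table(values, groups)
        assert (out["p_adj"] >= out["p"] - 1e-15).all()
        assert set(out.columns) >= {"H", "df", "p", "p_adj", "median_a"}


def _dunn_bruteforce(vals, groups):
    """Independent naive Dunn z statistics (direct formula, no shared code)."""
    vals = np.asarray(vals, float)
    groups = np.asarray(groups)
    N = len(vals)
    order = np.argsort(vals, kind="mergesort")
    ranks = np.empty(N)
    sv = vals[order]
    i = 0
    pos = np.arange(1, N + 1)
    while i < N:
        j = i
        while j + 1 < N and sv[j + 1] == sv[i]:
            j += 1
        ranks[order[i : j + 1]] = pos[i : j + 1].mean()
        i = j + 1
    _, t = np.unique(vals, return_counts=True)
    T = float((t**3 - t).sum())
    out = {}
    labels = sorted(set(groups))
    for a in labels:
        for b in labels:
            if a < b:
                ra = ranks[groups == a].mean()
                rb = ranks[groups == b].mean()
                na, nb = (groups == a).sum(), (groups == b).sum()
                se = np.sqrt((N * (N + 1) / 12 - T / (12 * (N - 1))) * (1 / na + 1 / nb))
                out[(a, b)] = (ra - rb) / se
    return out


class TestDunn:
    def test_identical_groups_zero(self):
        res = dunn_posthoc([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert res[0].z == pytest.approx(0.0, abs=1e-12)
        assert res[0].p_adj == pytest.approx(1.0)

    def test_matches_independent_bruteforce(self):
        vals = [1, 2, 3, 4, 5, 6, 7, 8, 9]
        groups = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = dunn_posthoc(vals, groups, adjust="none")
        ref = _dunn_bruteforce(vals, groups)
        for r in res:
            assert abs(r.z) == pytest.approx(abs(ref[r.pair]), abs=1e-10)
        rng = np.random.default_rng(13)
        vals = rng.integers(0, 10, 30).astype(float)
        groups = rng.choice(["a", "b", "c"], 30)
        ref = _dunn_bruteforce(vals, groups)
        for r in dunn_posthoc(vals, groups, adjust="none"):
            assert r.z == pytest.approx(ref[r.pair], abs=1e-10)

    @pytest.mark.parametrize("adjust", ["sidak", "bonferroni", "bh"])
    def test_adjustment_never_decreases_p(self, adjust):
        rng = np.random.default_rng(14)
        vals = rng.normal(size=30)
        groups = np.repeat(["a", "b", "c"], 10)
        raw = dunn_posthoc(vals, groups, adjust="none")
        adj = dunn_posthoc(vals, groups, adjust=adjust)
        for r0, r1 in zip(raw, adj):
            assert r1.p_adj >= r0.p_adj - 1e-12


class TestBenjaminiHochberg:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert benjamini_hochberg([0.37])[0] == pytest.approx(0.37)

    def test_matches_manual_step_up_formula(self):
        rng = np.random.default_rng(15)
        p = rng.random(40)
        got = benjamini_hochberg(p)
        m = len(p)
        order = np.argsort(p)
        manual = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            i = order[rank - 1]
            running = min(running, m * p[i] / rank)
            manual[i] = running
        np.testing.assert_allclose(got, manual, rtol=1e-12)

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(16)
        p = np.sort(rng.random(25))
        q = benjamini_hochberg(p)
        assert (np.diff(q) >= -1e-15).all()
        assert ((q >= p - 1e-15) & (q <= 1.0)).all()

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])


class TestFisherMonteCarlo:
    def test_extreme_association_significant(self):
        for seed in range(10):
            p = fisher_monte_carlo([[5, 0], [0, 5]], iterations=2000, seed=seed)
            assert p < 0.05

    def test_identical_rows_near_one(self):
        p = fisher_monte_carlo([[10, 10], [10, 10]], iterations=2000, seed=0)
        assert p > 0.5

    def test_never_returns_zero(self):
        p = fisher_monte_carlo([[8, 0], [0, 8]], iterations=100, seed=1)
        assert p >= 1 / 101

    def test_degenerate_margin_raises(self):
        with pytest.raises(ValueError):
            fisher_monte_carlo([[0, 0], [3, 4]], iterations=10, seed=0)

    def test_2x2_agrees_with_exact_hypergeometric(self):
        table = [[7, 3], [2, 8]]
        exact = sps.fisher_exact(table).pvalue
        iters = 2000
        mc_se = np.sqrt(exact * (1 - exact) / iters)
        for seed in range(20):
            p = fisher_monte_carlo(table, iterations=iters, seed=seed)
            assert abs(p - exact) <= 3 * mc_se + 2 / iters


class TestHypergeometricOra:
    def test_closed_form_full_pathway_hit(self):
        universe = [f"g{i}" for i in range(100)]
        pw = set(universe[:5])
        res = hypergeometric_ora(pw, universe, {"pw": pw})
        expected = 1 / comb(100, 5)  # C(5,5)*C(95,0)/C(100,5)
        assert res.loc["pw", "p"] == pytest.approx(expected, rel=1e-9)

    def test_disjoint_pathway_p_one(self):
        universe = [f"g{i}" for i in range(50)]
        res = hypergeometric_ora(universe[:5], universe, {"pw": set(universe[40:])})
        assert res.loc["pw", "p"] == pytest.approx(1.0)

    def test_empty_hits_raises(self):
        with pytest.raises(ValueError):
            hypergeometric_ora([], ["a"], {"pw": {"a"}})

    def test_null_p_values_not_anticonservative(self):
        # random hit sets: the discrete hypergeometric p-values must be
        # stochastically >= uniform (valid test), checked one-sided
        rng = np.random.default_rng(17)
        universe = [f"g{i}" for i in range(400)]
        pw = {"pw": set(rng.choice(universe, 60, replace=False))}
        ps = []
        for _ in range(400):
            hits = rng.choice(universe, 40, replace=False)
            ps.append(hypergeometric_ora(hits, universe, pw).loc["pw", "p"])
        ps = np.asarray(ps)
        # empirical CDF never exceeds uniform CDF by more than sampling error
        grid = np.linspace(0.05, 0.95, 19)
        emp = [(ps <= g).mean() for g in grid]
        assert max(e - g for e, g in zip(emp, grid)) < 0.08
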