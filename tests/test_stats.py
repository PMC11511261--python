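"""ANOVA, Duncan letters, correlations, networks and OLS fits."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from oracles import brute_duncan_share, brute_network_edges, letters_share
from peonyforce.errors import DomainError
from peonyforce.stats import (
    build_network,
    correlation_matrix,
    duncan_letters,
    ols_fit,
    one_way_anova,
    pearson_with_p,
)


class TestOneWayAnova:
    def test_identical_groups_give_zero_F(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.F == 0.0
        assert res.p == 1.0

    def test_perfect_separation(self):
        rng = np.random.default_rng(0)
        a = np.zeros(4) + rng.normal(0, 1e-9, 4)
        b = np.full(4, 10.0) + rng.normal(0, 1e-9, 4)
        res = one_way_anova([a, b])
        assert res.p < 1e-12

    def test_three_shifted_groups(self):
        # SSB = 8, SSW = 15, df (2, 9): F = 4 / (15/9) = 2.4
        res = one_way_anova([[1, 2, 3, 4], [2, 3, 4, 5], [3, 4, 5, 6]])
        assert res.df_between == 2
        assert res.df_within == 9
        assert res.ms_between == pytest.approx(4.0)
        assert res.ms_within == pytest.approx(15 / 9)
        assert res.F == pytest.approx(2.4)

    def test_agrees_with_scipy_f_oneway(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(m, 1.0, 5) for m in (0.0, 0.5, 1.5)]
        res = one_way_anova(groups)
        F, p = sps.f_oneway(*groups)
        assert res.F == pytest.approx(float(F))
        assert res.p == pytest.approx(float(p))

    def test_degenerate_variance_is_nan(self):
        res = one_way_anova([[2.0, 2.0], [2.0, 2.0]])
        assert np.isnan(res.F) and np.isnan(res.p)

    def test_small_group_rejected(self):
        with pytest.raises(DomainError):
            one_way_anova([[1.0], [1.0, 2.0]])


class TestDuncanLetters:
    def test_equal_means_share_one_letter(self):
        rng = np.random.default_rng(1)
        base = rng.normal(0, 1, 6)
        groups = {f"g{i}": base + 0.0 for i in range(4)}
        res = duncan_letters(groups)
        assert set(res.letters.values()) == {"a"}

    def test_huge_gap_separates(self):
        rng = np.random.default_rng(2)
        groups = {
            "hi": 100.0 + rng.normal(0, 1, 6),
            "lo": rng.normal(0, 1, 6),
        }
        res = duncan_letters(groups)
        assert res.letters["hi"] == "a"
        assert res.letters["lo"] == "b"
        assert not set(res.letters["hi"]) & set(res.letters["lo"])

    def test_protected_mode_collapses_when_anova_ns(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": rng.normal(0, 5, 4) for i in range(4)}
        res = duncan_letters(groups, protected=True)
        if res.anova.p >= res.alpha:
            assert set(res.letters.values()) == {"a"}

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_brute_force_oracle(self, seed):
        """Letter sharing equals the exhaustive homogeneous-interval
        closure on randomized small instances."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 6))
        spread = float(rng.uniform(0.5, 4.0))
        groups = {
            f"g{i}": rng.normal(rng.uniform(0, spread), 1.0, int(rng.integers(4, 9)))
            for i in range(k)
        }
        res = duncan_letters(groups, protected=True)
        assert letters_share(res.letters) == brute_duncan_share(groups)

    def test_shift_and_relabel_invariance(self):
        rng = np.random.default_rng(9)
        groups = {f"g{i}": rng.normal(i * 1.2, 1.0, 5) for i in range(4)}
        res = duncan_letters(groups)
        shifted = {f"x{g}": np.asarray(v) + 42.0 for g, v in groups.items()}
        res2 = duncan_letters(shifted)
        assert {f"x{g}": s for g, s in res.letters.items()} == res2.letters

    def test_sorted_means_start_at_a(self):
        rng = np.random.default_rng(4)
        groups = {f"g{i}": rng.normal(3 * i, 0.5, 5) for i in range(3)}
        res = duncan_letters(groups)
        top = res.means.index[0]
        assert "a" in res.letters[top]


class TestPearson:
    def test_exact_linear(self):
        x = np.arange(1.0, 8.0)
        r, p = pearson_with_p(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_exact_negative(self):
        x = np.arange(1.0, 6.0)
        r, _ = pearson_with_p(x, -x)
        assert r == pytest.approx(-1.0)

    def test_hand_example(self):
        # cov = 10, Sxx = 10, Syy = 14.8 -> r = 10 / sqrt(148)
        r, _ = pearson_with_p([1, 2, 3, 4, 5], [2, 1, 4, 3, 6])
        assert r == pytest.approx(0.8220, abs=5e-5)

    def test_symmetry_and_scale_invariance(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        r1, p1 = pearson_with_p(x, y)
        r2, p2 = pearson_with_p(y, x)
        r3, _ = pearson_with_p(3.0 * x + 7.0, y)
        assert (r1, p1) == pytest.approx((r2, p2))
        assert r3 == pytest.approx(r1)

    def test_zero_variance_rejected(self):
        with pytest.raises(DomainError):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestCorrelationMatrix:
    def test_perfect_pair_flagged(self):
        df = pd.DataFrame({"u": [1.0, 2, 3, 4, 5], "v": [2.0, 4, 6, 8, 10]})
        r, p, stars = correlation_matrix(df)
        assert r.loc["u", "v"] == pytest.approx(1.0)
        assert stars.loc["u", "v"] == "**"
        assert stars.loc["u", "u"] == ""

    def test_matches_pairwise_calls(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(0, 1, (12, 5)), columns=list("abcde"))
        r, p, _ = correlation_matrix(df)
        for x, y in itertools.combinations(df.columns, 2):
            rr, pp = pearson_with_p(df[x], df[y])
            assert r.loc[x, y] == pytest.approx(rr)
            assert p.loc[x, y] == pytest.approx(pp)

    def test_constant_trait_reported_undefined(self):
        df = pd.DataFrame({"u": [1.0, 2, 3, 4], "c": [5.0, 5, 5, 5]})
        r, _, _ = correlation_matrix(df)
        assert r.loc["c"].isna().all()


def _toy_matrices():
    nodes = list("wxyz")
    r = pd.DataFrame(np.eye(4), index=nodes, columns=nodes)
    p = pd.DataFrame(np.zeros((4, 4)), index=nodes, columns=nodes)
    vals = {
        ("w", "x"): (0.9, 0.001), ("w", "y"): (0.39, 0.001),
        ("w", "z"): (0.95, 0.20), ("x", "y"): (-0.7, 0.01),
        ("x", "z"): (0.5, 0.04), ("y", "z"): (0.1, 0.9),
    }
    for (a, b), (rr, pp) in vals.items():
        r.loc[a, b] = r.loc[b, a] = rr
        p.loc[a, b] = p.loc[b, a] = pp
    return r, p


class TestBuildNetwork:
    def test_threshold_is_on_r_magnitude(self):
        r, p = _toy_matrices()
        net = build_network(r, p, r_threshold=0.4, alpha=0.05)
        kept = {tuple(sorted(e)) for e in net.graph.edges}
        assert ("w", "y") not in kept      # r = 0.39 despite tiny p
        assert ("w", "z") not in kept      # p = 0.20 despite huge r
        assert ("x", "y") in kept          # negative r counts by |r|

    def test_matches_brute_force_and_degrees(self):
        r, p = _toy_matrices()
        net = build_network(r, p, r_threshold=0.4, alpha=0.05)
        kept = {tuple(sorted(e)) for e in net.graph.edges}
        assert kept == brute_network_edges(r, p, 0.4, 0.05)
        assert net.weighted_degree["x"] == pytest.approx(0.9 + 0.7 + 0.5)
        assert net.weighted_degree.idxmax() == "x"

    def test_isolated_nodes_retained(self):
        r, p = _toy_matrices()
        net = build_network(r, p, r_threshold=0.99, alpha=0.05)
        assert set(net.graph.nodes) == set("wxyz")
        assert net.weighted_degree["y"] == 0.0

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(21)
        df = pd.DataFrame(rng.normal(0, 1, (15, 6)), columns=list("abcdef"))
        r, p, _ = correlation_matrix(df)
        prev = None
        for thr in (0.0, 0.2, 0.4, 0.6, 0.8, 1.0):
            edges = {tuple(sorted(e)) for e in build_network(r, p, thr).graph.edges}
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestOlsFit:
    def test_collinear_points(self):
        fit = ols_fit([1, 2, 3, 4], [3, 5, 7, 9])
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.slope == pytest.approx(2.0)

    def test_constant_response(self):
        fit = ols_fit([1, 2, 3, 4], [5, 5, 5, 5])
        assert fit.slope == pytest.approx(0.0)
        assert fit.r_squared == 0.0

    def test_hand_least_squares(self):
        # Sxy = 3, Sxx = 2 -> slope 1.5; intercept 10/3 - 3 = 1/3
        fit = ols_fit([1, 2, 3], [2, 3, 5])
        assert fit.slope == pytest.approx(1.5)
        assert fit.intercept == pytest.approx(1 / 3)
        assert fit.r_squared == pytest.approx(0.9643, abs=5e-5)

    def test_agrees_with_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(30)
        x = rng.uniform(0, 10, 25)
        y = 1.3 + 0.7 * x + rng.normal(0, 1.0, 25)
        fit = ols_fit(x, y)
        ref = sm.OLS(y, sm.add_constant(x)).fit()
        assert fit.slope == pytest.approx(ref.params[1])
        assert fit.intercept == pytest.approx(ref.params[0])
        assert fit.r_squared == pytest.approx(ref.rsquared)
        assert fit.p_slope == pytest.approx(ref.pvalues[1])

    def test_zero_x_variance_rejected(self):
        with pytest.raises(DomainError):
            ols_fit([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_log_predictor_option(self):
        x = np.array([1.0, np.e, np.e**2])
        fit = ols_fit(x, [0.0, 1.0, 2.0], log_x=True)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
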