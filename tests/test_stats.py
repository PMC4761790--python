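"""Altitude trends, Kruskal–Wallis/Nemenyi contrasts, trait correlations."""

import numpy as np
import pytest

from frost.errors import InputError
from frost.stats import (compact_letter_display, holm_adjust,
                         kruskal_nemenyi, linear_trend, trait_correlation)


class TestLinearTrend:
    def test_exact_line(self):
        alt = np.array([1950.0, 2000.0, 2100.0, 2250.0, 2400.0])
        fit = linear_trend(2.0 * alt + 1.0, alt)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.p_value < 1e-6

    def test_constant_response_is_flat(self):
        fit = linear_trend([5.0, 5.0, 5.0, 5.0], [1.0, 2.0, 3.0, 4.0])
        assert fit.slope == 0.0 and fit.r_squared == 0.0 and fit.p_value == 1.0

    def test_zero_altitude_variance_rejected(self):
        with pytest.raises(InputError, match="zero variance"):
            linear_trend([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_invariant_to_row_permutation(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(1900, 2400, 20)
        y = -0.004 * x + rng.normal(0, 0.5, 20)
        perm = rng.permutation(20)
        a, b = linear_trend(y, x), linear_trend(y[perm], x[perm])
        assert a.slope == pytest.approx(b.slope, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_na_pairs_dropped(self):
        fit = linear_trend([1.0, np.nan, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert fit.n == 3

    def test_negative_coupling_sign_recovered_across_seeds(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            alt = rng.uniform(1940, 2428, 38)
            y = -0.004 * alt + rng.normal(0, 0.5, 38)
            hits += linear_trend(y, alt).slope < 0
        assert hits >= 95


class TestKruskalNemenyi:
    def test_hand_ranked_statistic(self):
        res = kruskal_nemenyi([1, 2, 3, 4, 5, 6, 7, 8, 9],
                              ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
        assert res.kw_statistic == pytest.approx(7.2, abs=1e-9)

    def test_identical_groups_share_a_letter(self):
        vals = [1.0, 2.0, 3.0, 4.0] * 2
        res = kruskal_nemenyi(vals, ["a"] * 4 + ["b"] * 4)
        assert res.kw_p > 0.9
        assert set(res.letters["a"]) & set(res.letters["b"])

    def test_well_separated_groups_get_distinct_letters(self):
        # the rank-sum Nemenyi needs n=12 per group to separate ADJACENT
        # groups of three at alpha 0.05: with n=8 its minimum adjacent-pair
        # p is 0.061 even at maximal rank separation
        rng = np.random.default_rng(3)
        vals = np.concatenate([rng.normal(0, 0.3, 12),
                               rng.normal(10, 0.3, 12),
                               rng.normal(20, 0.3, 12)])
        groups = ["low"] * 12 + ["mid"] * 12 + ["high"] * 12
        res = kruskal_nemenyi(vals, groups)
        letters = res.letters
        assert len({letters["low"], letters["mid"], letters["high"]}) == 3
        for pair, p in res.pairwise.items():
            assert p < 0.05

    def test_extreme_pair_separates_at_small_n(self):
        rng = np.random.default_rng(8)
        vals = np.concatenate([rng.normal(0, 0.3, 8),
                               rng.normal(10, 0.3, 8),
                               rng.normal(20, 0.3, 8)])
        groups = ["low"] * 8 + ["mid"] * 8 + ["high"] * 8
        res = kruskal_nemenyi(vals, groups)
        assert res.pairwise[("low", "high")] < 0.05
        assert res.letters["low"] != res.letters["high"]

    def test_pairwise_matrix_symmetric(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, 15)
        groups = ["a"] * 5 + ["b"] * 5 + ["c"] * 5
        res = kruskal_nemenyi(vals, groups)
        for (g1, g2), p in res.pairwise.items():
            assert p == res.pairwise[(g2, g1)]

    def test_statistic_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(1, 5, 18)
        groups = ["a"] * 6 + ["b"] * 6 + ["c"] * 6
        a = kruskal_nemenyi(vals, groups)
        b = kruskal_nemenyi(np.exp(vals), groups)
        assert a.kw_statistic == pytest.approx(b.kw_statistic, abs=1e-9)
        for pair, p in a.pairwise.items():
            assert p == pytest.approx(b.pairwise[pair], abs=1e-9)

    def test_singleton_group_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            res = kruskal_nemenyi([1, 2, 3, 4, 5, 6, 99],
                                  ["a"] * 3 + ["b"] * 3 + ["c"])
        assert set(res.letters) == {"a", "b"}


class TestLetterDisplay:
    def test_chain_structure(self):
        # A differs from C; B bridges both → A:a, B:ab, C:b
        pairwise = {("A", "C"): 0.01, ("C", "A"): 0.01,
                    ("A", "B"): 0.5, ("B", "A"): 0.5,
                    ("B", "C"): 0.5, ("C", "B"): 0.5}
        letters = compact_letter_display(["A", "B", "C"], pairwise, 0.05)
        assert letters["A"] != letters["C"]
        assert set(letters["B"]) >= {letters["A"], letters["C"]}


class TestCorrelation:
    def test_monotone_pairs_give_spearman_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 4.0, 9.0, 16.0, 30.0]
        res = trait_correlation(x, y, method="spearman")
        assert res.coefficient == pytest.approx(1.0)

    def test_perfect_negative_either_method(self):
        x = np.linspace(0, 1, 8)
        for method in ("pearson", "spearman"):
            res = trait_correlation(x, -x, method=method)
            assert res.coefficient == pytest.approx(-1.0)

    def test_auto_switches_on_nonnormal_data(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(0, 1, 19), [50.0]])  # heavy outlier
        y = rng.normal(0, 1, 20)
        assert trait_correlation(x, y, method="auto").method == "spearman"

    def test_zero_variance_rejected(self):
        with pytest.raises(InputError):
            trait_correlation([1.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])

    def test_built_in_rank_coupling_recovered(self):
        from scipy import stats as sps
        rhos = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            z1 = rng.normal(size=38)
            rho_g = 2 * np.sin(np.pi * -0.55 / 6)
            z2 = rho_g * z1 + np.sqrt(1 - rho_g ** 2) * rng.normal(size=38)
            rhos.append(trait_correlation(z1, z2, "spearman").coefficient)
        assert abs(np.mean(rhos) - (-0.55)) < 0.1


def test_holm_adjustment_monotone_and_bounded():
    adj = holm_adjust([0.01, 0.04, 0.03, 0.6])
    assert all(0 <= p <= 1 for p in adj)
    assert adj[0] == pytest.approx(0.04)
    assert adj[3] == pytest.approx(0.6)
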