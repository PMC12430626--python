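"""Method comparison: relative errors, exact Wilcoxon and Spearman oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from forcarb.comparison import (
    ComparisonError,
    compare_methods,
    pairwise_wilcoxon,
    relative_errors,
    spearman,
    spearman_matrix,
    wilcoxon_signed_rank,
)

PRINTED_TOTALS = {
    "variable_bef": 692_548.39,
    "bef": 672_599.83,
    "volume_conversion": 673_161.07,
    "continuous_bcf": 400_369.17,
}


class TestRelativeErrors:
    def test_published_four_method_errors(self):
        re = relative_errors(PRINTED_TOTALS)
        assert {k: round(v, 2) for k, v in re.items()} == {
            "variable_bef": 13.59,
            "bef": 10.32,
            "volume_conversion": 10.41,
            "continuous_bcf": -34.33,
        }
        from forcarb.valuation import round_half_up

        mu = float(np.mean(list(PRINTED_TOTALS.values())))
        assert round_half_up(mu) == 609_669.62

    def test_equal_totals_give_zero_errors(self):
        assert set(relative_errors({"a": 5.0, "b": 5.0}).values()) == {0.0}

    def test_two_method_symmetry(self):
        re = relative_errors({"a": 1.0, "b": 3.0})
        assert re == {"a": -50.0, "b": 50.0}

    def test_deviations_sum_to_zero(self):
        re = relative_errors(PRINTED_TOTALS)
        assert sum(re.values()) == pytest.approx(0.0, abs=1e-9)

    def test_zero_mean_is_an_error(self):
        with pytest.raises(ComparisonError):
            relative_errors({"a": 1.0, "b": -1.0})
        with pytest.raises(ComparisonError):
            relative_errors({"a": 1.0})


def brute_force_signed_rank_p(x, y):
    """Independent oracle: enumerate all 2^n sign assignments of |d| ranks."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    dist = [
        sum(r for r, s in zip(ranks, signs) if s > 0)
        for signs in itertools.product((-1, 1), repeat=len(d))
    ]
    dist = np.array(dist)
    cdf = (dist <= w_obs + 1e-12).mean()
    sf = (dist >= w_obs - 1e-12).mean()
    return min(1.0, 2.0 * min(cdf, sf))


class TestWilcoxon:
    def test_identical_columns_vacuous(self):
        r = wilcoxon_signed_rank([1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
        assert r.p_value == 1.0 and r.all_zero and r.n_effective == 0

    @pytest.mark.parametrize(
        "x,y",
        [
            ([1, 2, 3, 4, 5, 6, 7], [2, 1, 5, 3, 9, 4, 6]),
            ([10, 12, 9, 14, 8, 11, 13], [9, 11, 10, 12, 7, 10, 12]),  # shifted
            ([1, 2, 3, 4, 5, 6, 7, 8], [1.5, 1.5, 4, 2, 7, 5, 9, 6]),  # n=8, ties in |d|
            ([3, 1, 4, 1, 5, 9, 2], [3, 1, 4, 1, 5, 9, 7]),  # zeros dropped
        ],
    )
    def test_exact_p_matches_brute_force_enumeration(self, x, y):
        r = wilcoxon_signed_rank(x, y)
        assert r.exact
        assert r.p_value == pytest.approx(brute_force_signed_rank_p(x, y), abs=1e-12)

    def test_agrees_with_scipy_exact_when_no_ties(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=12)
        y = x + rng.normal(0.3, 1.0, size=12)
        ours = wilcoxon_signed_rank(x, y)
        ref = stats.wilcoxon(x, y, method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-9)

    @given(shift=st.floats(-100, 100))
    def test_invariant_under_adding_a_constant_to_both_columns(self, shift):
        x = [1.0, 4.0, 2.0, 8.0, 5.0, 7.0, 3.5]
        y = [2.0, 3.0, 2.5, 6.0, 9.0, 7.5, 1.0]
        a = wilcoxon_signed_rank(x, y)
        b = wilcoxon_signed_rank([v + shift for v in x], [v + shift for v in y])
        assert a.p_value == pytest.approx(b.p_value, rel=1e-12)

    def test_large_n_uses_normal_approximation(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=40)
        y = x + rng.normal(0.1, 1.0, size=40)
        r = wilcoxon_signed_rank(x, y)
        assert not r.exact and 0 < r.p_value <= 1


def spearman_footrule_oracle(x, y):
    """Independent oracle: rho = 1 − 6Σd²/(n(n²−1)), valid without ties."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(x)
    return 1 - 6 * float(((rx - ry) ** 2).sum()) / (n * (n * n - 1))


class TestSpearman:
    def test_identical_ranking_gives_rho_one(self):
        r = spearman([1, 5, 10], [2, 50, 101])
        assert r.rho == pytest.approx(1.0)

    def test_reversed_ranking_gives_rho_minus_one(self):
        r = spearman([1, 2, 3, 4], [9, 7, 5, 3])
        assert r.rho == pytest.approx(-1.0)

    def test_rho_matches_rank_formula_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.permutation(7).astype(float)
            y = rng.permutation(7).astype(float)
            assert spearman(x, y).rho == pytest.approx(
                spearman_footrule_oracle(x, y), rel=1e-12
            )

    def test_exact_permutation_p_matches_full_enumeration(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.8]
        r = spearman(x, y)
        assert r.exact
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        obs = abs(np.corrcoef(rx, ry)[0, 1])
        rhos = [
            abs(np.corrcoef(rx, np.array(p))[0, 1]) for p in itertools.permutations(ry)
        ]
        expected = np.mean([r_ >= obs - 1e-12 for r_ in rhos])
        assert r.p_value == pytest.approx(expected, abs=1e-12)

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_invariant_under_strictly_monotone_transform(self, a, b):
        x = [3.0, 1.0, 4.0, 1.5, 5.0, 9.0, 2.0]
        y = [2.0, 7.0, 1.0, 8.0, 2.8, 1.8, 5.7]
        base = spearman(x, y)
        transformed = spearman([a * v + b for v in x], y)
        assert transformed.rho == pytest.approx(base.rho, rel=1e-12)
        assert transformed.p_value == pytest.approx(base.p_value, rel=1e-12)

    def test_constant_column_is_flagged_undefined(self):
        r = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert r.undefined


class TestMatrixLevel:
    def test_proportional_methods_have_unit_correlation(self):
        # methods that are positive multiples of one volume vector rank
        # species identically, reproducing the all-1.000 correlation table
        v = pd.Series([1000.0, 500.0, 80.0, 10.0, 4.0, 2.0, 1.0])
        matrix = pd.DataFrame({"m1": 0.5 * v, "m2": 0.47 * v, "m3": 0.61 * v, "m4": 0.3 * v})
        for r in spearman_matrix(matrix).values():
            assert r.rho == pytest.approx(1.0)
        for r in pairwise_wilcoxon(matrix).values():
            assert 0 < r.p_value <= 1

    def test_report_is_internally_consistent(self):
        rng = np.random.default_rng(5)
        matrix = pd.DataFrame(
            rng.lognormal(4, 1, size=(7, 4)), columns=["a", "b", "c", "d"]
        )
        rep = compare_methods(matrix)
        # stored relative errors reproduce from stored totals and mean
        for m, re_pct in rep.relative_errors_pct.items():
            again = (rep.method_totals[m] - rep.mean_total) / rep.mean_total * 100
            assert re_pct == pytest.approx(again, abs=1e-9)
        assert len(rep.wilcoxon) == len(rep.spearman) == 6
        d = rep.to_dict()
        assert set(d["wilcoxon"]) == set(d["spearman"])
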