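"""From-scratch exact tests against enumeration oracles and scipy."""

import itertools
from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as st_h

from chloroconv.exact_stats import (
    ContingencyTable2x2,
    TestResult,
    benjamini_hochberg,
    boschloo_test,
    category_contrast,
    fisher_exact,
    mann_whitney_exact,
)


def oracle_fisher_two_sided(a, b, c, d):
    """Exact-rational hypergeometric enumeration."""
    n1, n2, m = a + b, c + d, a + c
    N = n1 + n2
    if N == 0:
        return 1.0
    denom = comb(N, n1)
    lo, hi = max(0, m - n2), min(m, n1)
    probs = {x: Fraction(comb(m, x) * comb(N - m, n1 - x), denom)
             for x in range(lo, hi + 1)}
    p_obs = probs[a]
    return float(sum(p for p in probs.values() if p <= p_obs))


def oracle_boschloo(table, grid_points=10001, alternative="two_sided"):
    """Dense-grid enumeration over all outcome tables."""
    n1, n2 = table.n1, table.n2
    obs_p = fisher_exact(table, alternative).p_value
    fisher_ps = np.array(
        [
            [fisher_exact(ContingencyTable2x2(x1, n1 - x1, x2, n2 - x2),
                          alternative).p_value
             for x2 in range(n2 + 1)]
            for x1 in range(n1 + 1)
        ]
    )
    mask = fisher_ps <= obs_p * (1 + 1e-12)
    best = 0.0
    x1 = np.arange(n1 + 1)
    x2 = np.arange(n2 + 1)
    for pi in np.linspace(0, 1, grid_points)[1:-1]:
        pmf1 = st.binom.pmf(x1, n1, pi)
        pmf2 = st.binom.pmf(x2, n2, pi)
        best = max(best, float((np.outer(pmf1, pmf2) * mask).sum()))
    return best


def random_tables(rng, n, max_margin=40):
    out = []
    for _ in range(n):
        n1 = int(rng.integers(1, max_margin))
        n2 = int(rng.integers(1, max_margin))
        a = int(rng.integers(0, n1 + 1))
        c = int(rng.integers(0, n2 + 1))
        out.append(ContingencyTable2x2(a, n1 - a, c, n2 - c))
    return out


class TestFisher:
    def test_textbook_table(self):
        res = fisher_exact(ContingencyTable2x2(3, 1, 1, 3))
        assert res.p_value == pytest.approx(34 / 70, abs=1e-12)

    def test_degenerate_all_zero(self):
        assert fisher_exact(ContingencyTable2x2(0, 0, 0, 0)).p_value == 1.0

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(st_h.integers(0, 15), st_h.integers(0, 15),
           st_h.integers(0, 15), st_h.integers(0, 15))
    def test_symmetry_under_row_and_column_swap(self, a, b, c, d):
        p1 = fisher_exact(ContingencyTable2x2(a, b, c, d)).p_value
        p2 = fisher_exact(ContingencyTable2x2(d, c, b, a)).p_value
        assert p1 == pytest.approx(p2, rel=1e-10)

    def test_matches_rational_oracle_random(self, rng):
        for t in random_tables(rng, 300):
            mine = fisher_exact(t).p_value
            assert mine == pytest.approx(
                oracle_fisher_two_sided(t.a, t.b, t.c, t.d), abs=1e-10
            )

    def test_one_sided_matches_scipy(self, rng):
        for t in random_tables(rng, 100):
            for alt, scipy_alt in (("less", "less"), ("greater", "greater")):
                mine = fisher_exact(t, alt).p_value
                ref = st.fisher_exact(t.as_array(), alternative=scipy_alt)[1]
                assert mine == pytest.approx(ref, abs=1e-9)


class TestBoschloo:
    def test_identical_all_failure_rows(self):
        assert boschloo_test(ContingencyTable2x2(0, 5, 0, 7)).p_value == 1.0

    def test_matches_dense_grid_oracle(self):
        t = ContingencyTable2x2(7, 2, 1, 8)
        mine = boschloo_test(t).p_value
        assert mine == pytest.approx(oracle_boschloo(t), abs=1e-6)

    def test_matches_oracle_more_tables(self):
        for counts in [(5, 5, 1, 9), (3, 7, 8, 2), (2, 2, 2, 2), (10, 0, 4, 6)]:
            t = ContingencyTable2x2(*counts)
            assert boschloo_test(t).p_value == pytest.approx(
                oracle_boschloo(t), abs=1e-6
            )

    def test_never_exceeds_fisher(self, rng):
        for t in random_tables(rng, 100, max_margin=25):
            b = boschloo_test(t, grid_size=200)
            f = fisher_exact(t)
            assert b.p_value <= f.p_value * (1 + 1e-9)

    def test_grid_convergence(self):
        battery = [(40, 38, 10, 26), (7, 2, 1, 8), (12, 4, 3, 11)]
        for counts in battery:
            t = ContingencyTable2x2(*counts)
            p1 = boschloo_test(t, grid_size=1000).p_value
            p2 = boschloo_test(t, grid_size=2000).p_value
            assert abs(p1 - p2) < 1e-4

    def test_one_sided_matches_dense_grid_oracle(self):
        # (scipy's boschloo_exact shares the one-sided Fisher-p ordering
        # statistic but its nuisance optimization and tie handling can
        # differ in the third decimal, so the enumeration oracle is the
        # authoritative reference here)
        for counts in [(7, 12, 8, 3), (4, 16, 16, 4), (1, 7, 3, 9)]:
            t = ContingencyTable2x2(*counts)
            mine = boschloo_test(t, alternative="less", grid_size=2000).p_value
            assert mine == pytest.approx(
                oracle_boschloo(t, alternative="less"), abs=1e-6
            )

    def test_two_sided_close_to_scipy_on_headline_table(self):
        mine = boschloo_test(ContingencyTable2x2(40, 38, 10, 26)).p_value
        ref = st.boschloo_exact([[40, 38], [10, 26]]).pvalue
        assert mine == pytest.approx(ref, abs=2e-3)

    def test_row_total_zero_is_error(self):
        with pytest.raises(ValueError):
            boschloo_test(ContingencyTable2x2(0, 0, 3, 4))

    def test_exact_validity_at_nominal_level(self, rng):
        """Empirical type-I error <= 0.05 under the null (pi = 0.4)."""
        n1, n2, alpha = 78, 36, 0.05

        @lru_cache(maxsize=None)
        def p_of(x1, x2):
            return boschloo_test(
                ContingencyTable2x2(x1, n1 - x1, x2, n2 - x2), grid_size=200
            ).p_value

        reps = 10_000
        x1s = rng.binomial(n1, 0.4, size=reps)
        x2s = rng.binomial(n2, 0.4, size=reps)
        rejections = sum(p_of(int(a), int(b)) < alpha for a, b in zip(x1s, x2s))
        assert rejections / reps <= alpha


class TestMannWhitney:
    def test_identical_samples(self):
        assert mann_whitney_exact([1, 2, 3], [1, 2, 3]).p_value == 1.0

    def test_tiny_example(self):
        res = mann_whitney_exact([1, 2], [3, 4])
        assert res.p_value == pytest.approx(2 / 6)

    def test_matches_full_enumeration(self, rng):
        """Exact distribution equals enumeration of all rank assignments."""
        for _ in range(30):
            n = int(rng.integers(2, 7))
            m = int(rng.integers(2, 13 - n))
            pool = rng.integers(0, 6, size=n + m).astype(float)  # ties likely
            x, y = pool[:n], pool[n:]
            mine = mann_whitney_exact(x, y)

            order = np.argsort(pool, kind="mergesort")
            ranks = np.empty(len(pool))
            sorted_vals = pool[order]
            i = 0
            while i < len(pool):
                j = i
                while j + 1 < len(pool) and sorted_vals[j + 1] == sorted_vals[i]:
                    j += 1
                ranks[order[i: j + 1]] = (i + j) / 2 + 1
                i = j + 1
            r_obs = ranks[:n].sum()
            sums = [
                sum(ranks[list(idx)])
                for idx in itertools.combinations(range(n + m), n)
            ]
            total = len(sums)
            p_less = sum(s <= r_obs + 1e-9 for s in sums) / total
            p_greater = sum(s >= r_obs - 1e-9 for s in sums) / total
            expected = min(1.0, 2 * min(p_less, p_greater))
            assert mine.p_value == pytest.approx(expected, abs=1e-12)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])


class TestResultInvariants:
    def test_p_value_bounds_enforced(self):
        with pytest.raises(ValueError):
            TestResult(1.5, 0.0, "two_sided", "x")

    def test_bh_correction_monotone(self):
        raw = [0.001, 0.01, 0.04, 0.2, 0.9]
        adj = benjamini_hochberg(raw)
        assert all(a >= r for a, r in zip(adj, raw))
        assert all(np.diff(adj) >= -1e-12)


class TestCategoryContrast:
    def test_table1_sites_contrast(self, study):
        t = category_contrast(study["summary"], "con_vs_nc_sites", "C4:C4", "C3:C3")
        assert (t.a, t.b, t.c, t.d) == (104, 96, 34, 39)

    def test_pair_row_columns_partition_category(self, study):
        for row in ("no_replacements", "con_gt_nc", "con_gt_1"):
            t = category_contrast(study["summary"], row, "C4:C4", "C3:C3")
            assert t.n1 == 78 and t.n2 == 36

    def test_unknown_metric(self, study):
        with pytest.raises(ValueError, match="metric"):
            category_contrast(study["summary"], "nope", "C4:C4", "C3:C3")

    def test_gene_restricted_events(self, study):
        t_all = category_contrast(study["summary"], "con_vs_nc_events",
                                  "C4:C4", "C3:C3")
        t_gene = category_contrast(study["summary"], "con_vs_nc_events",
                                   "C4:C4", "C3:C3", gene="rbcL")
        assert t_gene.a <= t_all.a and t_gene.total < t_all.total
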