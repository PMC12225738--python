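"""Statistical primitives against closed forms, enumeration oracles and
reference implementations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from planaxis.stats import (
    ContingencyTable,
    DegenerateTableWarning,
    bh_adjust,
    fisher_exact,
    rank_sum_matrix,
    wilcoxon_rank_sum,
)

from _oracles import fisher_enumeration, wilcoxon_enumeration


class TestFisherExact:
    @pytest.mark.parametrize(
        "cells, alternative, expected",
        [
            ((0, 10, 0, 10), "greater", 1.0),
            ((5, 0, 0, 5), "greater", 1 / 252),       # 1 / C(10, 5)
            ((10, 0, 0, 10), "greater", 1 / 184756),  # 1 / C(20, 10)
        ],
    )
    def test_closed_forms(self, cells, alternative, expected):
        assert fisher_exact(ContingencyTable(*cells), alternative) == pytest.approx(
            expected, rel=1e-12
        )

    def test_two_sided_matches_enumeration(self):
        p = fisher_exact(ContingencyTable(3, 7, 6, 4), "two_sided")
        exact = float(fisher_enumeration(3, 7, 6, 4, "two_sided"))
        assert p == pytest.approx(exact, abs=1e-12)

    def test_matches_enumeration_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = (int(v) for v in rng.integers(0, 12, size=4))
            if a + b == 0 or a + c == 0 or a + b + c + d == 0:
                continue
            t = ContingencyTable(a, b, c, d)
            for alt in ("greater", "two_sided"):
                assert fisher_exact(t, alt) == pytest.approx(
                    float(fisher_enumeration(a, b, c, d, alt)), abs=1e-12
                )

    def test_matches_scipy_greater(self, rng):
        from scipy.stats import fisher_exact as scipy_fisher

        for _ in range(50):
            a, b, c, d = (int(v) for v in rng.integers(0, 30, size=4))
            if a + b == 0 or a + c == 0:
                continue
            ours = fisher_exact(ContingencyTable(a, b, c, d), "greater")
            ref = scipy_fisher([[a, b], [c, d]], alternative="greater")[1]
            assert ours == pytest.approx(ref, rel=1e-9)

    def test_tail_complement_identity(self, rng):
        """P(X >= a) + P(X <= a-1) = 1 exactly for every table with a >= 1.

        The complementary lower tail is the 'less' p-value of the shifted
        table (a-1, b+1, c+1 stays on the same margins via a-1 in-set).
        """
        from _oracles import fisher_margin_pmfs

        for _ in range(100):
            a, b, c, d = (int(v) for v in rng.integers(0, 15, size=4))
            a += 1
            upper = fisher_exact(ContingencyTable(a, b, c, d), "greater")
            ks, nums, den = fisher_margin_pmfs(a + b + c + d, a + b, a + c)
            lower = sum(n for k, n in zip(ks, nums) if k <= a - 1) / den
            assert upper + lower == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_margins_warn_not_raise(self):
        with pytest.warns(DegenerateTableWarning):
            assert fisher_exact(ContingencyTable(0, 0, 3, 4), "greater") == 1.0

    def test_large_counts_match_scipy(self):
        """Cell-level tables (tens of thousands of counts) stay exact."""
        from scipy.stats import fisher_exact as scipy_fisher

        t = ContingencyTable(5100, 4900, 4800, 5200)
        ours = fisher_exact(t, "greater")
        ref = scipy_fisher([[5100, 4900], [4800, 5200]], alternative="greater")[1]
        assert ours == pytest.approx(ref, rel=1e-9)
        # strongly enriched table: representable, astronomically small
        p = fisher_exact(ContingencyTable(900, 100, 100, 900), "greater")
        assert 0.0 < p < 1e-200

    def test_rejects_negative_cells(self):
        with pytest.raises(ValueError):
            ContingencyTable(-1, 2, 3, 4)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "p, expected",
        [
            ([0.05, 0.05, 0.05], [0.05, 0.05, 0.05]),
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.2], [0.2]),
            ([], []),
        ],
    )
    def test_step_up_examples(self, p, expected):
        assert bh_adjust(p) == pytest.approx(np.asarray(expected))

    def test_matches_statsmodels(self, rng):
        from statsmodels.stats.multitest import multipletests

        p = rng.uniform(size=300)
        ref = multipletests(p, method="fdr_bh")[1]
        assert bh_adjust(p) == pytest.approx(ref, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=30))
    def test_never_decreases_and_preserves_order(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0)
        # sorted order of q follows sorted order of p (step-up monotonicity)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestWilcoxon:
    def test_identical_samples_are_null(self):
        u, p = wilcoxon_rank_sum([1, 2, 3, 4], [1, 2, 3, 4])
        assert u == 4 * 4 / 2
        assert p == 1.0

    def test_complete_separation_orientation(self):
        """U counts x-over-y pairs: every x below every y gives U = 0."""
        u, p = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
        assert u == 0.0
        u2, _ = wilcoxon_rank_sum([10, 11, 12], [1, 2, 3])
        assert u2 == 9.0

    def test_all_values_identical(self):
        assert wilcoxon_rank_sum([5, 5], [5, 5, 5])[1] == 1.0

    def test_against_exact_enumeration_small_samples(self, rng):
        """U matches the exhaustive oracle exactly; the approximate p stays
        within a coarse absolute band on tiny tie-heavy samples, where a
        normal approximation cannot do better."""
        for _ in range(40):
            n, m = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            x = list(rng.integers(0, 6, size=n).astype(float))
            y = list(rng.integers(0, 6, size=m).astype(float))
            if len(set(x + y)) == 1:
                continue
            u, p = wilcoxon_rank_sum(x, y)
            u_ref, p_ref = wilcoxon_enumeration(x, y)
            assert u == pytest.approx(u_ref)
            assert abs(p - p_ref) <= 0.25

    def test_relative_accuracy_without_ties(self, rng):
        """On tie-free samples of eight per group, and outside the extreme
        tail, the approximation is within 10% relative of the exact
        enumeration."""
        for _ in range(10):
            x = list(rng.normal(size=8))
            y = list(rng.normal(size=8))
            _, p = wilcoxon_rank_sum(x, y)
            _, p_ref = wilcoxon_enumeration(x, y)
            if p_ref >= 0.05:
                assert abs(p - p_ref) <= 0.10 * p_ref

    def test_antisymmetry(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=11)
        u1, p1 = wilcoxon_rank_sum(x, y)
        u2, p2 = wilcoxon_rank_sum(y, x)
        assert u1 + u2 == pytest.approx(8 * 11)
        assert p1 == pytest.approx(p2, rel=1e-12)

    def test_matches_scipy_with_ties(self, rng):
        from scipy.stats import mannwhitneyu

        x = rng.integers(0, 5, size=30).astype(float)
        y = rng.integers(0, 5, size=40).astype(float)
        u, p = wilcoxon_rank_sum(x, y)
        ref = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_matrix_version_agrees_with_scalar(self, rng):
        values = rng.integers(0, 8, size=(40, 6)).astype(float)
        mask = np.zeros(40, dtype=bool)
        mask[:13] = True
        u, p = rank_sum_matrix(values, mask)
        for j in range(6):
            uj, pj = wilcoxon_rank_sum(values[mask, j], values[~mask, j])
            assert u[j] == pytest.approx(uj)
            assert p[j] == pytest.approx(pj, rel=1e-12)
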