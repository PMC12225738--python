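"""Independent brute-force oracles used only by the test suite.

Each oracle computes its quantity by a route disjoint from the package
implementation: exact rational hypergeometric enumeration for Fisher's
test, exhaustive alignment-path enumeration for local alignment, and
exhaustive label-assignment enumeration for the rank-sum test.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

TIE_REL_TOL = Fraction(10**7 + 1, 10**7)


def fisher_enumeration(a: int, b: int, c: int, d: int, alternative: str) -> Fraction:
    """Exact Fisher p-value by full enumeration of the hypergeometric support."""
    r1, c1, n = a + b, a + c, a + b + c + d
    if n == 0 or r1 == 0 or c1 == 0:
        return Fraction(1)
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    num = {k: comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)}
    den = comb(n, c1)
    if alternative == "greater":
        total = sum(v for k, v in num.items() if k >= a)
    elif alternative == "less":
        total = sum(v for k, v in num.items() if k <= a)
    else:  # two_sided with the documented relative tie tolerance
        cut = Fraction(num[a]) * TIE_REL_TOL
        total = sum(v for v in num.values() if Fraction(v) <= cut)
    return Fraction(total, den)


def fisher_margin_pmfs(n: int, r1: int, c1: int) -> tuple[list[int], list[int], int]:
    """Support, integer pmf numerators and the common denominator."""
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    ks = list(range(lo, hi + 1))
    nums = [comb(r1, k) * comb(n - r1, c1 - k) for k in ks]
    return ks, nums, comb(n, c1)


def local_alignment_enumeration(
    a: str, b: str, score: dict[tuple[str, str], float],
    gap_open: float, gap_extend: float,
) -> float:
    """Optimal local alignment score by exhaustive path enumeration.

    Every alignment path over the full rectangle is enumerated (three
    moves per step, affine gap state carried along); the local score is
    the best partial-path score ever seen, floored at 0. Exponential —
    fixture lengths must stay tiny.
    """
    n, m = len(a), len(b)
    best = 0.0

    def rec(i: int, j: int, last: int, acc: float) -> None:
        nonlocal best
        if acc > best:
            best = acc
        if i < n and j < m:
            rec(i + 1, j + 1, 0, acc + score[(a[i], b[j])])
        if i < n:
            rec(i + 1, j, 2, acc - (gap_extend if last == 2 else gap_open))
        if j < m:
            rec(i, j + 1, 1, acc - (gap_extend if last == 1 else gap_open))

    # a local alignment may start at any cell; starting mid-gap is never
    # better, so a diagonal first move suffices
    for i in range(n):
        for j in range(m):
            rec(i + 1, j + 1, 0, score[(a[i], b[j])])
    return best


def wilcoxon_enumeration(x: list[float], y: list[float]) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating all group assignments.

    U uses midranks (ties counted half); the p-value is
    ``P(|U - nm/2| >= |u_obs - nm/2|)`` over all C(n+m, n) assignments.
    """
    pooled = sorted(x + y)
    n1, n2 = len(x), len(y)
    nm = n1 * n2

    def u_stat(group: tuple[float, ...], rest: list[float]) -> float:
        u = 0.0
        for xv in group:
            for yv in rest:
                u += 1.0 if xv > yv else (0.5 if xv == yv else 0.0)
        return u

    u_obs = u_stat(tuple(x), list(y))
    dev = abs(u_obs - nm / 2.0)
    hits = total = 0
    for idx in combinations(range(n1 + n2), n1):
        grp = tuple(pooled[i] for i in idx)
        rest = [pooled[i] for i in range(n1 + n2) if i not in set(idx)]
        if abs(u_stat(grp, rest) - nm / 2.0) >= dev - 1e-12:
            hits += 1
        total += 1
    return u_obs, hits / total
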