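"""Exact and rank-based statistical primitives shared by every pipeline stage.

This module provides the three tests the axis-mapping pipeline leans on:

* :func:`fisher_exact` — Fisher's exact test on a 2x2 contingency table,
  computed from the hypergeometric distribution with all margins fixed.
  Point probabilities are evaluated in log space so tables with cell counts
  in the tens of thousands (cell-level enrichment tables) remain exact.
* :func:`bh_adjust` — Benjamini-Hochberg step-up adjustment of a p-value
  vector, returned in the original input order.
* :func:`wilcoxon_rank_sum` — two-sample Wilcoxon/Mann-Whitney test with
  midranks for ties, tie-corrected normal approximation and continuity
  correction; the workhorse behind cluster-marker calling.

Enrichment tests downstream default to the one-sided ``greater``
alternative: every enrichment claim in the pipeline is directional
(over-representation of a class or of high-scoring cells), and the
two-sided variant remains available wherever a direction is not assumed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp
from scipy.stats import norm, rankdata

__all__ = [
    "ContingencyTable",
    "DegenerateTableWarning",
    "fisher_exact",
    "bh_adjust",
    "wilcoxon_rank_sum",
]

#: Relative tolerance used when comparing point probabilities in the
#: two-sided tail sum; tables whose probability exceeds the observed one
#: by less than this factor count as ties and are included.
TWO_SIDED_REL_TOL = 1e-7


class DegenerateTableWarning(UserWarning):
    """Raised (as a warning, never an exception) for degenerate 2x2 margins."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table ``[[a, b], [c, d]]``.

    Rows are group membership (in-set vs out-of-set), columns are the label
    being tested (in-class vs out-of-class). All cells must be non-negative
    integers.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if v != int(v) or v < 0:
                raise ValueError(f"cell {name}={v!r} must be a non-negative integer")
            object.__setattr__(self, name, int(v))

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


def _hypergeom_pmf(table: ContingencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Support and normalized pmf of the `a` cell with all margins fixed.

    Log-space evaluation followed by a normalizing exp keeps the pmf exact
    to machine precision even for very large counts, and guarantees that
    complementary tail sums add to 1 up to rounding.
    """
    r1 = table.a + table.b
    c1 = table.a + table.c
    n = table.n
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    logpmf = (
        gammaln(r1 + 1)
        - gammaln(k + 1)
        - gammaln(r1 - k + 1)
        + gammaln(n - r1 + 1)
        - gammaln(c1 - k + 1)
        - gammaln(n - r1 - (c1 - k) + 1)
    )
    logpmf -= logsumexp(logpmf)
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()
    return k, pmf


def fisher_exact(table: ContingencyTable, alternative: str = "greater") -> float:
    """Fisher's exact test for a 2x2 table.

    Parameters
    ----------
    table
        The observed :class:`ContingencyTable`.
    alternative
        ``"greater"`` sums hypergeometric probabilities ``P(X >= a)``;
        ``"less"`` sums ``P(X <= a)``; ``"two_sided"`` sums the
        probabilities of every table (margins fixed) whose point
        probability does not exceed the observed one (relative tie
        tolerance :data:`TWO_SIDED_REL_TOL`).

    Returns
    -------
    float
        The p-value in ``[0, 1]``. Degenerate margins (an empty row or
        column, or an empty table) yield ``p = 1.0`` with a
        :class:`DegenerateTableWarning` rather than an exception.
    """
    if alternative not in ("greater", "less", "two_sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    r1 = table.a + table.b
    c1 = table.a + table.c
    if table.n == 0 or r1 == 0 or c1 == 0:
        warnings.warn(
            "degenerate 2x2 margins; p-value fixed at 1.0", DegenerateTableWarning
        )
        return 1.0
    k, pmf = _hypergeom_pmf(table)
    a = table.a
    if alternative == "greater":
        p = pmf[k >= a].sum()
    elif alternative == "less":
        p = pmf[k <= a].sum()
    else:
        p_obs = pmf[k == a][0]
        p = pmf[pmf <= p_obs * (1.0 + TWO_SIDED_REL_TOL)].sum()
    return float(min(1.0, p))


def bh_adjust(p: np.ndarray | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, in the input order.

    ``q(i) = min_{j >= i} p(j) * m / j`` over the sorted p-values, clipped
    at 1. Never smaller than the input and monotone in the sorted order.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D p-value vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def wilcoxon_rank_sum(
    x: np.ndarray | list[float], y: np.ndarray | list[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    ``U`` counts pairs where an ``x`` value exceeds a ``y`` value, ties
    counted half (so complete separation with every ``x`` below every ``y``
    gives ``U = 0``, and the mirror image gives ``U = len(x) * len(y)``).
    The p-value uses the normal approximation with midrank tie correction
    and a 0.5 continuity correction. If every value in both samples is
    identical the p-value is 1.0.

    Returns
    -------
    (U, p)
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled, method="average")
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts**3 - counts).sum()
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return float(u), 1.0
    mu = n1 * n2 / 2.0
    diff = u - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var_u)
    p = float(2.0 * norm.sf(abs(z)))
    return float(u), min(1.0, p)


def rank_sum_matrix(
    values: np.ndarray, in_group: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Wilcoxon rank-sum of ``in_group`` rows vs the rest, per column.

    ``values`` is an observations x variables matrix; ``in_group`` a boolean
    mask over rows. Returns per-column ``(U, p)`` with the same conventions
    as :func:`wilcoxon_rank_sum`. Columns with zero rank variance (constant
    values) get ``p = 1``.
    """
    values = np.asarray(values, dtype=float)
    in_group = np.asarray(in_group, dtype=bool)
    n, _ = values.shape
    n1 = int(in_group.sum())
    n2 = n - n1
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(values, method="average", axis=0)
    r1 = ranks[in_group].sum(axis=0)
    u = r1 - n1 * (n1 + 1) / 2.0
    tie_term = _tie_terms(values)
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    mu = n1 * n2 / 2.0
    diff = u - mu
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var_u)
    p = 2.0 * norm.sf(np.abs(z))
    p = np.where(var_u <= 0, 1.0, np.minimum(p, 1.0))
    return u, p


def _tie_terms(values: np.ndarray) -> np.ndarray:
    """Per-column sum of t^3 - t over tied groups."""
    s = np.sort(values, axis=0)
    n, m = s.shape
    out = np.empty(m)
    for j in range(m):
        _, counts = np.unique(s[:, j], return_counts=True)
        out[j] = (counts.astype(float) ** 3 - counts).sum()
    return out
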