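"""One-to-one ortholog assignment by Smith-Waterman reciprocal best hits.

Local protein alignment uses the Smith-Waterman algorithm with affine gap
costs (a gap of length L costs ``gap_open + (L - 1) * gap_extend``) and
BLOSUM62 scoring, executed by Biopython's ``PairwiseAligner``; the letter
``X`` is tolerated and scores 0 against everything. Reciprocal best hits
(RBH) pair genes that are each other's unique highest-scoring partner
across two proteomes — the operational proxy for one-to-one orthology.
Tied best hits disqualify the query (no pair is emitted), so duplicated
sequences never produce arbitrary assignments.

:func:`shared_enriched` chains pairwise one-to-one links transitively
across species and reports, for each ortholog group, in how many species
the group is part of the enriched gene set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentParams",
    "OrthologMap",
    "smith_waterman",
    "reciprocal_best_hits",
    "shared_enriched",
]


def _blosum62_with_x_zero() -> Align.substitution_matrices.Array:
    mat = substitution_matrices.load("BLOSUM62")
    arr = np.array(mat)
    letters = mat.alphabet
    out = substitution_matrices.Array(alphabet=letters, dims=2)
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            out[a, b] = 0.0 if ("X" in (a, b)) else arr[i, j]
    return out


@dataclass
class AlignmentParams:
    """Scoring scheme for local protein alignment.

    ``gap_open`` is the cost of the first residue of a gap and
    ``gap_extend`` of each further residue, so a gap of length L costs
    ``gap_open + (L - 1) * gap_extend``. ``score_min`` is the minimum
    alignment score for a reportable hit. ``kmer_prefilter``, when set,
    skips pairs sharing fewer than that many 4-mers (a cheap screen for
    large proteomes; off by default).
    """

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    score_min: float = 50.0
    kmer_prefilter: int | None = None

    def __post_init__(self) -> None:
        if not (self.gap_open >= self.gap_extend > 0):
            raise ValueError("require gap_open >= gap_extend > 0")

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        if self.matrix == "BLOSUM62":
            aligner.substitution_matrix = _blosum62_with_x_zero()
        else:
            aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        aligner.open_gap_score = -float(self.gap_open)
        aligner.extend_gap_score = -float(self.gap_extend)
        return aligner


@dataclass
class OrthologMap:
    """One-to-one pairs (idA, idB, score) plus the ids left unassigned."""

    pairs: list[tuple[str, str, float]] = field(default_factory=list)
    unassigned: set[str] = field(default_factory=set)

    def as_dict(self) -> dict[str, str]:
        """idA -> idB and idB -> idA lookup."""
        d: dict[str, str] = {}
        for a, b, _ in self.pairs:
            d[a] = b
            d[b] = a
        return d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pairs, columns=["id_a", "id_b", "score"])


def smith_waterman(
    a: str, b: str, params: AlignmentParams | None = None
) -> tuple[float, tuple[str, str]]:
    """Optimal local alignment score and one optimal alignment.

    Empty input on either side yields ``(0.0, ("", ""))``. The aligned
    strings contain ``-`` at gap positions.
    """
    params = params or AlignmentParams()
    if not a or not b:
        return 0.0, ("", "")
    aligner = params.make_aligner()
    score = float(aligner.score(a, b))
    if score <= 0:
        return max(0.0, score), ("", "")
    aln = next(iter(aligner.align(a, b)))
    text_a, text_b = str(aln[0]), str(aln[1])
    return score, (text_a, text_b)


def _kmer_set(seq: str, k: int = 4) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _score_matrix(
    seqs_a: list[str], seqs_b: list[str], params: AlignmentParams
) -> np.ndarray:
    aligner = params.make_aligner()
    scores = np.zeros((len(seqs_a), len(seqs_b)))
    kmers_b = None
    if params.kmer_prefilter is not None:
        kmers_b = [_kmer_set(s) for s in seqs_b]
    for i, sa in enumerate(seqs_a):
        ka = _kmer_set(sa) if kmers_b is not None else None
        for j, sb in enumerate(seqs_b):
            if kmers_b is not None and len(ka & kmers_b[j]) < params.kmer_prefilter:
                continue
            if sa and sb:
                scores[i, j] = aligner.score(sa, sb)
    return scores


def _unique_best(row: np.ndarray) -> int | None:
    """Index of the strict maximum, or None on a tie / empty row."""
    best = row.max()
    if best <= 0:
        return None
    winners = np.nonzero(row == best)[0]
    if winners.size != 1:
        return None
    return int(winners[0])


def reciprocal_best_hits(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    params: AlignmentParams | None = None,
) -> OrthologMap:
    """One-to-one ortholog pairs between two proteomes.

    A pair (x, y) is reported iff y is the unique best-scoring hit of x in
    B, x the unique best of y in A, and the score reaches
    ``params.score_min``. Ties disqualify the query (logged). The result
    is invariant to the input ordering of records.
    """
    params = params or AlignmentParams()
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    ids_a = sorted(proteome_a)
    ids_b = sorted(proteome_b)
    seqs_a = [proteome_a[i] for i in ids_a]
    seqs_b = [proteome_b[i] for i in ids_b]
    scores = _score_matrix(seqs_a, seqs_b, params)

    best_in_b = [_unique_best(scores[i, :]) for i in range(len(ids_a))]
    best_in_a = [_unique_best(scores[:, j]) for j in range(len(ids_b))]
    n_ties = sum(
        1 for i in range(len(ids_a)) if best_in_b[i] is None and scores[i, :].max() > 0
    )
    if n_ties:
        logger.info("%d queries disqualified by tied best hits", n_ties)

    pairs: list[tuple[str, str, float]] = []
    paired: set[str] = set()
    for i, j in enumerate(best_in_b):
        if j is None:
            continue
        if best_in_a[j] == i and scores[i, j] >= params.score_min:
            pairs.append((ids_a[i], ids_b[j], float(scores[i, j])))
            paired.add(ids_a[i])
            paired.add(ids_b[j])
    unassigned = (set(ids_a) | set(ids_b)) - paired
    return OrthologMap(pairs=pairs, unassigned=unassigned)


# ---------------------------------------------------------------------
# cross-species intersection of enriched sets


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[max(rx, ry)] = min(rx, ry)


def shared_enriched(
    sets: dict[str, set[str]],
    maps: dict[tuple[str, str], OrthologMap],
    ranks: dict[str, dict[str, int]] | None = None,
) -> pd.DataFrame:
    """Ortholog groups enriched in k of n species.

    Groups are connected components of the pairwise one-to-one links;
    enriched genes with no ortholog anywhere form singleton groups
    (species count 1) rather than being dropped. A component holding two
    or more genes of one species implies inconsistent chaining; it is
    flagged ``ambiguous`` and excluded from shared-in-all accounting by
    the caller. Output is sorted by number of supporting species
    (descending), then combined rank (sum of per-species enriched-list
    ranks when ``ranks`` is given), then group id.
    """
    uf = _UnionFind()
    nodes: set[tuple[str, str]] = set()
    for (sp_a, sp_b), omap in maps.items():
        for ida, idb, _ in omap.pairs:
            na, nb = (sp_a, ida), (sp_b, idb)
            nodes.update((na, nb))
            uf.union(na, nb)
    for sp, genes in sets.items():
        for g in genes:
            nodes.add((sp, g))
            uf.find((sp, g))

    components: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for node in nodes:
        components.setdefault(uf.find(node), []).append(node)

    rows = []
    species = sorted(sets)
    for root in sorted(components):
        members = sorted(components[root])
        by_sp: dict[str, list[str]] = {}
        for sp, g in members:
            by_sp.setdefault(sp, []).append(g)
        enriched_in = sorted(
            sp for sp in by_sp if any(g in sets.get(sp, set()) for g in by_sp[sp])
        )
        if not enriched_in:
            continue
        ambiguous = any(len(v) > 1 for v in by_sp.values())
        combined_rank = 0
        if ranks is not None:
            for sp in enriched_in:
                sp_ranks = ranks.get(sp, {})
                combined_rank += min(
                    (sp_ranks.get(g, len(sp_ranks)) for g in by_sp[sp]),
                    default=len(sp_ranks),
                )
        row = {
            "group_id": f"{root[0]}:{root[1]}",
            "n_species_enriched": len(enriched_in),
            "enriched_in": ";".join(enriched_in),
            "ambiguous": ambiguous,
            "combined_rank": combined_rank,
        }
        for sp in species:
            row[f"members_{sp}"] = ";".join(by_sp.get(sp, []))
        rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        cols = ["group_id", "n_species_enriched", "enriched_in", "ambiguous",
                "combined_rank"] + [f"members_{sp}" for sp in species]
        return pd.DataFrame(columns=cols)
    df = df.sort_values(
        ["n_species_enriched", "combined_rank", "group_id"],
        ascending=[False, True, True],
    ).reset_index(drop=True)
    return df
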