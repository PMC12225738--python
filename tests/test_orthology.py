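"""Local alignment, reciprocal best hits and cross-species intersection."""

import numpy as np
import pytest

from planaxis.orthology import (
    AlignmentParams,
    OrthologMap,
    _blosum62_with_x_zero,
    reciprocal_best_hits,
    shared_enriched,
    smith_waterman,
)
from planaxis.simulate import SimulationConfig, generate_proteomes

from _oracles import local_alignment_enumeration

PARAMS = AlignmentParams(gap_open=11, gap_extend=1, score_min=0.0)


def _score_lookup(letters="ACDE"):
    mat = _blosum62_with_x_zero()
    return {(p, q): float(mat[p, q]) for p in letters for q in letters}


class TestSmithWaterman:
    def test_identity_alignment_sums_diagonal(self):
        score, (a, b) = smith_waterman("ACDEF", "ACDEF", PARAMS)
        assert score == 30.0  # 4 + 9 + 6 + 5 + 6 on BLOSUM62
        assert a == b == "ACDEF"

    def test_empty_sequence_scores_zero(self):
        assert smith_waterman("ACDEF", "", PARAMS)[0] == 0.0
        assert smith_waterman("", "", PARAMS)[0] == 0.0

    def test_x_scores_zero_against_everything(self):
        mat = _blosum62_with_x_zero()
        for aa in "ACDEFGHIKLMNPQRSTVWYX":
            assert mat["X", aa] == 0.0 and mat[aa, "X"] == 0.0

    def test_score_symmetry(self, rng):
        letters = list("ACDEFGHIKL")
        for _ in range(20):
            a = "".join(rng.choice(letters, size=rng.integers(3, 15)))
            b = "".join(rng.choice(letters, size=rng.integers(3, 15)))
            assert smith_waterman(a, b, PARAMS)[0] == smith_waterman(b, a, PARAMS)[0]

    def test_score_monotone_under_extension(self, rng):
        letters = list("ACDEFGHIKL")
        a = "".join(rng.choice(letters, size=10))
        b = "".join(rng.choice(letters, size=10))
        base = smith_waterman(a, b, PARAMS)[0]
        for suffix in ("A", "KLM", "WWWW"):
            assert smith_waterman(a + suffix, b, PARAMS)[0] >= base
            assert smith_waterman(a, b + suffix, PARAMS)[0] >= base

    def test_matches_enumeration_oracle_short(self, rng):
        """DP scores equal the exhaustive path enumerator on short pairs
        over a four-letter alphabet."""
        import itertools

        score = _score_lookup()
        letters = "ACDE"
        for la, lb in [(1, 1), (2, 2), (2, 3), (3, 3)]:
            pool_a = ["".join(t) for t in itertools.product(letters, repeat=la)]
            pool_b = ["".join(t) for t in itertools.product(letters, repeat=lb)]
            pool_a = list(rng.choice(pool_a, size=min(12, len(pool_a)), replace=False))
            pool_b = list(rng.choice(pool_b, size=min(12, len(pool_b)), replace=False))
            for a in pool_a:
                for b in pool_b:
                    bf = local_alignment_enumeration(a, b, score, 11, 1)
                    assert smith_waterman(a, b, PARAMS)[0] == bf


class TestReciprocalBestHits:
    def test_identical_proteomes_identity_mapping(self, rng):
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        prot = {f"g{i}": "".join(rng.choice(letters, size=60)) for i in range(8)}
        prot_b = {f"h{i}": prot[f"g{i}"] for i in range(8)}
        omap = reciprocal_best_hits(prot, prot_b, PARAMS)
        assert {(a, b) for a, b, _ in omap.pairs} == {(f"g{i}", f"h{i}") for i in range(8)}

    def test_duplicate_sequence_disqualified_by_tie(self, rng):
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        seqs = ["".join(rng.choice(letters, size=60)) for _ in range(3)]
        prot_a = {"a0": seqs[0], "a1": seqs[1], "a2": seqs[2]}
        prot_b = {"b0": seqs[0], "b0copy": seqs[0], "b1": seqs[1], "b2": seqs[2]}
        omap = reciprocal_best_hits(prot_a, prot_b, PARAMS)
        paired = {a for a, _, _ in omap.pairs}
        assert "a0" not in paired  # its two perfect hits tie
        assert {"a1", "a2"} <= paired

    def test_input_order_invariance(self):
        cfg = SimulationConfig(seed=4, n_proteins=15, protein_length=60,
                               divergence=0.1)
        prot, _ = generate_proteomes(cfg)
        omap1 = reciprocal_best_hits(prot["spA"], prot["spB"], PARAMS)
        shuffled = dict(reversed(list(prot["spA"].items())))
        omap2 = reciprocal_best_hits(shuffled, prot["spB"], PARAMS)
        assert omap1.pairs == omap2.pairs

    def test_recovery_on_diverged_proteomes(self):
        cfg = SimulationConfig(seed=4, n_proteins=40, protein_length=100,
                               divergence=0.1)
        prot, truth = generate_proteomes(cfg)
        omap = reciprocal_best_hits(prot["spA"], prot["spB"],
                                    AlignmentParams(score_min=50))
        got = {(a, b) for a, b, _ in omap.pairs}
        expected = set(map(tuple, truth.ortholog_pairs["spA|spB"]))
        assert len(got & expected) / len(expected) >= 0.95


class TestSharedEnriched:
    def _maps(self):
        m_ab = OrthologMap(pairs=[("A1", "B1", 100.0), ("A2", "B2", 90.0)])
        m_ac = OrthologMap(pairs=[("A1", "C1", 95.0)])
        m_bc = OrthologMap(pairs=[("B1", "C1", 92.0), ("B3", "C3", 80.0)])
        return {("spA", "spB"): m_ab, ("spA", "spC"): m_ac, ("spB", "spC"): m_bc}

    def test_empty_sets_give_empty_table(self):
        df = shared_enriched({"spA": set(), "spB": set(), "spC": set()},
                             self._maps())
        assert df.empty

    def test_counts_supporting_species(self):
        sets = {"spA": {"A1", "A2"}, "spB": {"B1"}, "spC": {"C1", "C3"}}
        df = shared_enriched(sets, self._maps())
        by_count = df.set_index("group_id")["n_species_enriched"].to_dict()
        assert by_count["spA:A1"] == 3   # A1-B1-C1 chained, enriched in all
        assert by_count["spA:A2"] == 1   # A2-B2 pair, enriched in A only
        assert by_count["spB:B3"] == 1   # B3-C3 pair, enriched in C only

    def test_orphan_enriched_gene_kept_as_singleton(self):
        sets = {"spA": {"A9"}, "spB": set(), "spC": set()}
        df = shared_enriched(sets, self._maps())
        assert "spA:A9" in set(df["group_id"])
        assert df.loc[df["group_id"] == "spA:A9", "n_species_enriched"].iloc[0] == 1

    def test_inconsistent_chain_flagged_ambiguous(self):
        maps = {
            ("spA", "spB"): OrthologMap(pairs=[("A1", "B1", 100.0)]),
            ("spB", "spC"): OrthologMap(pairs=[("B1", "C1", 90.0)]),
            ("spA", "spC"): OrthologMap(pairs=[("A2", "C1", 85.0)]),
        }
        sets = {"spA": {"A1", "A2"}, "spB": {"B1"}, "spC": {"C1"}}
        df = shared_enriched(sets, maps)
        # A1 and A2 both chain to C1: one component with two spA members
        row = df.iloc[0]
        assert bool(row["ambiguous"])

    def test_planted_three_species_intersection(self):
        """End-to-end: the same ancestral genes enriched in all three
        species come back as exactly those shared-in-3 groups."""
        cfg = SimulationConfig(seed=4, n_proteins=30, protein_length=80,
                               divergence=0.05)
        prot, truth = generate_proteomes(cfg, n_species=3)
        params = AlignmentParams(score_min=50)
        maps = {}
        for sa, sb in [("spA", "spB"), ("spA", "spC"), ("spB", "spC")]:
            maps[(sa, sb)] = reciprocal_best_hits(prot[sa], prot[sb], params)
        shared_idx = [0, 3, 5, 7, 9]
        sets = {
            sp: {f"{sp}_g{i:04d}" for i in shared_idx} for sp in ("spA", "spB", "spC")
        }
        df = shared_enriched(sets, maps)
        in_all = df[df["n_species_enriched"] == 3]
        assert len(in_all) == len(shared_idx)
        assert set(in_all["group_id"]) == {f"spA:spA_g{i:04d}" for i in shared_idx}


class TestParams:
    def test_gap_penalty_ordering_enforced(self):
        with pytest.raises(ValueError):
            AlignmentParams(gap_open=1, gap_extend=5)

    def test_kmer_prefilter_preserves_strong_pairs(self):
        cfg = SimulationConfig(seed=4, n_proteins=12, protein_length=80,
                               divergence=0.05)
        prot, _ = generate_proteomes(cfg)
        plain = reciprocal_best_hits(prot["spA"], prot["spB"],
                                     AlignmentParams(score_min=50))
        filtered = reciprocal_best_hits(
            prot["spA"], prot["spB"],
            AlignmentParams(score_min=50, kmer_prefilter=3),
        )
        assert set(filtered.pairs) == set(plain.pairs)
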