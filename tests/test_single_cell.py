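"""QC filtering, aboral scoring, cluster enrichment and marker calling."""

import numpy as np
import pytest
from scipy import sparse
from scipy.special import gammaln

from planaxis.single_cell import (
    CellMatrix,
    QCThresholds,
    aboral_score,
    cluster_enrichment,
    cluster_markers,
    normalize_log,
    qc_filter,
)


def _matrix(counts, mito=None, clusters=None):
    counts = np.asarray(counts)
    n, g = counts.shape
    return CellMatrix(
        counts=sparse.csr_matrix(counts),
        cell_ids=[f"cell{i}" for i in range(n)],
        gene_ids=[f"g{j}" for j in range(g)],
        cluster=np.asarray(clusters if clusters is not None
                           else [f"c{i % 2}" for i in range(n)]),
        mito_gene_ids=set(mito or []),
    )


class TestQCFilter:
    def test_cell_with_exactly_200_genes_retained(self):
        # 300 genes; cell 0 detects exactly 200 (2 UMI each -> 400 total),
        # cell 1 detects 199
        row0 = np.zeros(300, dtype=int)
        row0[:200] = 2
        row1 = np.zeros(300, dtype=int)
        row1[:199] = 2
        filler = np.full((4, 300), 2, dtype=int)
        m = _matrix(np.vstack([row0, row1, filler]),
                    clusters=["c0"] * 6)
        out = qc_filter(m, QCThresholds(min_cells_per_gene=0, min_umi=300))
        assert "cell0" in out.cell_ids and "cell1" not in out.cell_ids

    def test_gene_in_exactly_3_cells_retained(self):
        counts = np.full((4, 250), 2, dtype=int)
        counts[0, 0] = 0          # gene g0 detected in 3 of 4 cells
        counts[:2, 1] = 0         # gene g1 detected in 2 of 4 cells
        m = _matrix(counts, clusters=["c0"] * 4)
        out = qc_filter(m, QCThresholds(min_genes_per_cell=100, min_umi=300))
        assert "g0" in out.gene_ids and "g1" not in out.gene_ids

    def test_umi_cutoff_strict_boundary(self):
        counts = np.zeros((2, 300), dtype=int)
        counts[0, :300] = 1        # exactly 300 UMI -> retained
        counts[1, :299] = 1        # 299 -> dropped
        m = _matrix(counts, clusters=["c0", "c0"])
        out = qc_filter(m, QCThresholds(min_genes_per_cell=0,
                                        min_cells_per_gene=0))
        assert out.cell_ids == ["cell0"]

    def test_mito_fraction_boundary_kept(self):
        counts = np.zeros((2, 400), dtype=int)
        counts[:, :320] = 1                   # 320 non-mito genes detected
        counts[0, 399] = 80                   # exactly 20% mito
        counts[1, 399] = 81                   # just above
        m = _matrix(counts, mito=["g399"], clusters=["c0", "c0"])
        out = qc_filter(m, QCThresholds(max_mito_fraction=80 / 400,
                                        min_cells_per_gene=0))
        assert out.cell_ids == ["cell0"]

    def test_survivors_match_direct_rule_recomputation(self, rng):
        counts = rng.integers(0, 4, size=(150, 320))
        counts[rng.random(counts.shape) < 0.6] = 0
        mito = [f"g{j}" for j in range(310, 320)]
        m = _matrix(counts, mito=mito, clusters=["c0"] * 150)
        t = QCThresholds(min_genes_per_cell=40, min_cells_per_gene=3,
                         min_umi=60, max_mito_fraction=0.15)
        out = qc_filter(m, t)

        # independent recomputation, same four rules in order
        keep = counts.sum(axis=1) >= t.min_umi
        cur = counts[keep]
        ids = np.asarray(m.cell_ids)[keep]
        keep = (cur > 0).sum(axis=1) >= t.min_genes_per_cell
        cur, ids = cur[keep], ids[keep]
        mito_mask = np.zeros(320, dtype=bool)
        mito_mask[310:] = True
        frac = cur[:, mito_mask].sum(axis=1) / cur.sum(axis=1)
        keep = frac <= t.max_mito_fraction
        cur, ids = cur[keep], ids[keep]
        keep_g = (cur > 0).sum(axis=0) >= t.min_cells_per_gene
        assert out.cell_ids == list(ids)
        assert out.gene_ids == [f"g{j}" for j in np.nonzero(keep_g)[0]]

    def test_empty_result_names_depleting_step(self):
        m = _matrix(np.ones((3, 10), dtype=int), clusters=["c0"] * 3)
        with pytest.raises(ValueError, match="UMI"):
            qc_filter(m, QCThresholds(min_umi=1000))

    def test_ordering_invariance(self, rng):
        counts = rng.integers(0, 5, size=(60, 260))
        m1 = _matrix(counts, clusters=["c0"] * 60)
        perm = rng.permutation(60)
        m2 = CellMatrix(
            counts=sparse.csr_matrix(counts[perm]),
            cell_ids=[f"cell{i}" for i in perm],
            gene_ids=m1.gene_ids,
            cluster=np.asarray(["c0"] * 60),
        )
        t = QCThresholds(min_genes_per_cell=50, min_umi=100,
                         min_cells_per_gene=3)
        out1 = qc_filter(m1, t)
        out2 = qc_filter(m2, t)
        assert sorted(out1.cell_ids) == sorted(out2.cell_ids)
        assert out1.gene_ids == out2.gene_ids


class TestNormalize:
    def _filtered(self, counts, **kw):
        m = _matrix(counts, **kw)
        m.qc_state = "filtered"
        return m

    def test_closed_form_single_cell(self):
        m = self._filtered([[10, 0, 90]], clusters=["c0"])
        norm = np.asarray(normalize_log(m).todense())
        assert norm[0] == pytest.approx(
            [np.log(1001), 0.0, np.log(9001)]
        )

    def test_depth_conservation(self, rng):
        counts = rng.integers(1, 30, size=(20, 50))
        m = self._filtered(counts, clusters=["c0"] * 20)
        norm = normalize_log(m)
        sums = np.expm1(np.asarray(norm.todense())).sum(axis=1)
        assert sums == pytest.approx(np.full(20, 1e4), abs=1e-6)

    def test_raw_matrix_rejected(self):
        m = _matrix([[1, 2]], clusters=["c0"])
        with pytest.raises(ValueError, match="filtered"):
            normalize_log(m)


class TestAboralScore:
    def test_pure_and_zero_cells(self):
        m = _matrix([[5, 5, 0], [0, 0, 7]], clusters=["c0", "c1"])
        sc = aboral_score(m, {"g0", "g1"})
        assert sc["score"].tolist() == [1.0, 0.0]

    def test_matches_direct_sparse_sums(self, rng):
        counts = rng.integers(0, 6, size=(80, 120))
        m = _matrix(counts, clusters=["c0"] * 80)
        genes = {f"g{j}" for j in range(0, 120, 7)}
        sc = aboral_score(m, genes)
        cols = [j for j in range(120) if f"g{j}" in genes]
        direct = counts[:, cols].sum(axis=1) / counts.sum(axis=1)
        assert sc["score"].to_numpy() == pytest.approx(direct, abs=1e-12)

    def test_missing_gene_set_raises_with_count(self):
        m = _matrix([[1, 2]], clusters=["c0"])
        with pytest.raises(ValueError, match="2 aboral genes"):
            aboral_score(m, {"zz1", "zz2"})

    def test_invariant_to_inert_gene_duplication(self, rng):
        counts = rng.integers(0, 6, size=(30, 40))
        m1 = _matrix(counts, clusters=["c0"] * 30)
        counts2 = np.hstack([counts, np.zeros((30, 1), dtype=int)])
        m2 = _matrix(counts2, clusters=["c0"] * 30)
        genes = {f"g{j}" for j in range(5)}
        assert aboral_score(m1, genes)["score"].to_numpy() == pytest.approx(
            aboral_score(m2, genes)["score"].to_numpy()
        )


class TestClusterEnrichment:
    def test_concentrated_positives_closed_form(self):
        """All 100 positives in a 100-cell cluster of 1000: the one-sided p
        is 1 / C(1000, 100), checked in log space against the closed form."""
        import pandas as pd

        scores = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(1000)],
            "cluster": ["hot"] * 100 + ["cold"] * 900,
            "score": [1.0] * 100 + [0.0] * 900,
        })
        out = cluster_enrichment(scores, positive_quantile=0.75)
        p_hot = out.set_index("cluster").loc["hot", "p"]
        log_expected = -(gammaln(1001) - gammaln(101) - gammaln(901))
        assert np.log(p_hot) == pytest.approx(log_expected, rel=1e-9)
        assert out.set_index("cluster").loc["cold", "p"] == 1.0

    def test_constant_scores_warn_all_null(self):
        import pandas as pd

        scores = pd.DataFrame({
            "cell_id": [f"c{i}" for i in range(40)],
            "cluster": ["a"] * 20 + ["b"] * 20,
            "score": [0.5] * 40,
        })
        with pytest.warns(UserWarning, match="constant"):
            out = cluster_enrichment(scores)
        assert (out["p"] == 1.0).all()

    def test_positive_negative_partition(self, clustered_cells):
        _, cm, truth = clustered_cells
        sc = aboral_score(cm, truth.aboral_gene_ids)
        out = cluster_enrichment(sc)
        assert out["n_cells"].sum() == cm.n_cells
        cutoff = out.attrs["score_cutoff"]
        assert out["n_positive"].sum() == (sc["score"] > cutoff).sum()

    def test_label_renaming_invariance(self, clustered_cells):
        _, cm, truth = clustered_cells
        sc = aboral_score(cm, truth.aboral_gene_ids)
        out1 = cluster_enrichment(sc)
        sc2 = sc.copy()
        sc2["cluster"] = ["k" + c for c in sc2["cluster"]]
        out2 = cluster_enrichment(sc2)
        assert out1["p"].to_numpy() == pytest.approx(out2["p"].to_numpy())

    def test_planted_clusters_called_exactly(self, clustered_cells):
        _, cm, truth = clustered_cells
        sc = aboral_score(cm, truth.aboral_gene_ids)
        out = cluster_enrichment(sc)
        called = set(out.loc[out["enriched"], "cluster"])
        assert called == truth.aboral_cluster_ids


class TestAnnDataView:
    def test_round_trips_counts_and_metadata(self, rng):
        counts = rng.integers(0, 5, size=(12, 20))
        m = _matrix(counts, mito=["g19"], clusters=["c0"] * 6 + ["c1"] * 6)
        adata = m.to_anndata()
        assert adata.shape == (12, 20)
        assert list(adata.obs["cluster"]) == list(m.cluster)
        assert adata.var["mito"].sum() == 1
        assert adata.uns["qc_state"] == "raw"


class TestClusterMarkers:
    def test_exclusive_gene_ranks_first(self):
        counts = np.ones((30, 60), dtype=int) * 2
        counts[:, 0] = 0
        counts[:10, 0] = 50        # gene g0 exclusive to cluster k0
        m = _matrix(counts, clusters=["k0"] * 10 + ["k1"] * 10 + ["k2"] * 10)
        m.qc_state = "filtered"
        norm = normalize_log(m)
        markers = cluster_markers(norm, m.cluster, m.gene_ids)
        assert markers["k0"].iloc[0]["gene_id"] == "g0"
        assert markers["k0"].iloc[0]["log2fc"] > 0

    def test_planted_markers_recovered_at_rank_one(self, clustered_cells):
        _, cm, truth = clustered_cells
        norm = normalize_log(cm)
        markers = cluster_markers(norm, cm.cluster, cm.gene_ids)
        for cl, gene in truth.cluster_marker_genes.items():
            assert markers[cl].iloc[0]["gene_id"] == gene

    def test_permuted_labels_not_anticonservative(self, calibration_cells, rng):
        """With labels permuted, well-detected genes show no excess of
        small marker p-values."""
        _, cm, _ = calibration_cells
        norm = normalize_log(cm)
        dense = np.asarray(norm.todense())
        det = np.asarray((cm.counts > 0).sum(axis=0)).ravel()
        cols = np.argsort(-det)[:100]
        perm = rng.permutation(cm.cluster)
        from planaxis.stats import rank_sum_matrix

        _, p = rank_sum_matrix(dense[:, cols], perm == perm[0])
        assert (p < 0.05).mean() <= 0.1
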