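"""Single-cell QC, per-cell aboral scoring, cluster enrichment and markers.

The central quantity is the per-cell *aboral score*: the fraction of a
cell's raw UMI counts that falls on the aborally enriched gene set
(counts on aboral genes divided by total counts). Scores are computed on
raw counts — the score is a count fraction, so depth normalization would
distort it. Cells above a dataset-wide score quantile (default the upper
quartile) are "aboral-positive", and each cluster is tested for an excess
of positive cells with a one-sided Fisher exact test, BH-adjusted across
clusters.

QC follows the conventional droplet filters, applied in a fixed order,
each on the current matrix: total UMI >= ``min_umi``, detected genes per
cell >= ``min_genes_per_cell``, mitochondrial fraction <=
``max_mito_fraction``, then genes detected in >= ``min_cells_per_gene``
cells. All comparisons against "fewer than" thresholds are strict: a cell
with exactly 200 detected genes and a gene seen in exactly 3 cells are
retained.

Marker calling is a per-gene Wilcoxon rank-sum of each cluster against
all other cells on depth-normalized log values, BH-adjusted within the
cluster and ranked by p-value then effect size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .stats import ContingencyTable, bh_adjust, fisher_exact, rank_sum_matrix

__all__ = [
    "CellMatrix",
    "QCThresholds",
    "qc_filter",
    "normalize_log",
    "aboral_score",
    "cluster_enrichment",
    "cluster_markers",
]


@dataclass
class CellMatrix:
    """Sparse cells x genes UMI matrix with cluster labels and QC state."""

    counts: sparse.csr_matrix
    cell_ids: list[str]
    gene_ids: list[str]
    cluster: np.ndarray
    mito_gene_ids: set[str] = field(default_factory=set)
    qc_state: str = "raw"
    qc_log: dict | None = None

    def __post_init__(self) -> None:
        self.counts = sparse.csr_matrix(self.counts)
        n, g = self.counts.shape
        if len(self.cell_ids) != n or len(self.gene_ids) != g:
            raise ValueError("id lengths do not match the matrix shape")
        self.cluster = np.asarray(self.cluster)
        if self.cluster.shape != (n,):
            raise ValueError("one cluster label per cell required")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def subset(self, cell_mask: np.ndarray | None = None,
               gene_mask: np.ndarray | None = None) -> "CellMatrix":
        counts = self.counts
        cell_ids, gene_ids, cluster = self.cell_ids, self.gene_ids, self.cluster
        mito = self.mito_gene_ids
        if cell_mask is not None:
            counts = counts[cell_mask]
            cell_ids = [c for c, keep in zip(cell_ids, cell_mask) if keep]
            cluster = cluster[cell_mask]
        if gene_mask is not None:
            counts = counts[:, gene_mask]
            gene_ids = [g for g, keep in zip(gene_ids, gene_mask) if keep]
            mito = {g for g in mito if g in set(gene_ids)}
        return CellMatrix(counts=sparse.csr_matrix(counts), cell_ids=cell_ids,
                          gene_ids=gene_ids, cluster=cluster,
                          mito_gene_ids=mito, qc_state=self.qc_state,
                          qc_log=self.qc_log)

    def to_anndata(self):
        """Convenience view as an AnnData (optional dependency)."""
        import anndata as ad

        adata = ad.AnnData(
            X=self.counts.copy(),
            obs=pd.DataFrame({"cluster": self.cluster}, index=self.cell_ids),
            var=pd.DataFrame(
                {"mito": [g in self.mito_gene_ids for g in self.gene_ids]},
                index=self.gene_ids,
            ),
        )
        adata.uns["qc_state"] = self.qc_state
        return adata


@dataclass
class QCThresholds:
    min_genes_per_cell: int = 200
    min_cells_per_gene: int = 3
    min_umi: int = 300
    max_mito_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not (0 <= self.max_mito_fraction <= 1):
            raise ValueError("max_mito_fraction must lie in [0, 1]")
        if min(self.min_genes_per_cell, self.min_cells_per_gene, self.min_umi) < 0:
            raise ValueError("thresholds must be non-negative")


def qc_filter(m: CellMatrix, t: QCThresholds | None = None) -> CellMatrix:
    """Apply the four QC rules in order, each on the current matrix.

    Order: total UMI, detected genes per cell, mitochondrial fraction,
    genes detected in too few cells. 'Fewer than' thresholds are strict
    (boundary cases retained). Raises if any step empties the matrix,
    naming the step. Per-step removal counts are stored in ``qc_log``.
    """
    t = t or QCThresholds()
    if m.qc_state != "raw":
        raise ValueError("qc_filter expects a raw matrix")
    log: dict[str, int] = {}
    cur = m

    totals = np.asarray(cur.counts.sum(axis=1)).ravel()
    keep = totals >= t.min_umi
    log["cells_low_umi"] = int((~keep).sum())
    if not keep.any():
        raise ValueError("empty after QC: UMI-cutoff step removed every cell")
    cur = cur.subset(cell_mask=keep)

    detected = np.asarray((cur.counts > 0).sum(axis=1)).ravel()
    keep = detected >= t.min_genes_per_cell
    log["cells_few_genes"] = int((~keep).sum())
    if not keep.any():
        raise ValueError("empty after QC: genes-per-cell step removed every cell")
    cur = cur.subset(cell_mask=keep)

    mito_mask = np.array([g in cur.mito_gene_ids for g in cur.gene_ids])
    totals = np.asarray(cur.counts.sum(axis=1)).ravel()
    mito_counts = (
        np.asarray(cur.counts[:, mito_mask].sum(axis=1)).ravel()
        if mito_mask.any() else np.zeros_like(totals)
    )
    frac = np.divide(mito_counts, totals, out=np.zeros_like(totals, dtype=float),
                     where=totals > 0)
    keep = frac <= t.max_mito_fraction
    log["cells_high_mito"] = int((~keep).sum())
    if not keep.any():
        raise ValueError("empty after QC: mitochondrial step removed every cell")
    cur = cur.subset(cell_mask=keep)

    cells_per_gene = np.asarray((cur.counts > 0).sum(axis=0)).ravel()
    keep_g = cells_per_gene >= t.min_cells_per_gene
    log["genes_few_cells"] = int((~keep_g).sum())
    if not keep_g.any():
        raise ValueError("empty after QC: genes-in-cells step removed every gene")
    cur = cur.subset(gene_mask=keep_g)

    cur.qc_state = "filtered"
    cur.qc_log = log
    return cur


def normalize_log(m: CellMatrix, target_sum: float = 1e4) -> sparse.csr_matrix:
    """Depth-normalize each cell to ``target_sum`` total, then log1p.

    Used for marker testing only — never for aboral scores, which are
    count fractions on raw UMIs.
    """
    if m.qc_state != "filtered":
        raise ValueError("normalize_log expects a QC-filtered matrix")
    totals = np.asarray(m.counts.sum(axis=1)).ravel()
    if np.any(totals == 0):
        raise ValueError("zero-count cell encountered after QC")
    scale = target_sum / totals
    norm = sparse.csr_matrix(m.counts, dtype=float)
    norm = sparse.diags(scale) @ norm
    norm.data = np.log1p(norm.data)
    return norm


def aboral_score(m: CellMatrix, aboral_genes: set[str]) -> pd.DataFrame:
    """Per-cell aboral count fraction on raw UMIs.

    score = (counts on aboral genes) / (total counts). Raises if none of
    the aboral genes is present in the matrix, naming the miss count.
    """
    gene_mask = np.array([g in aboral_genes for g in m.gene_ids])
    if not gene_mask.any():
        raise ValueError(
            f"none of the {len(aboral_genes)} aboral genes is present in the matrix"
        )
    totals = np.asarray(m.counts.sum(axis=1)).ravel().astype(float)
    aboral = np.asarray(m.counts[:, gene_mask].sum(axis=1)).ravel().astype(float)
    score = np.divide(aboral, totals, out=np.zeros_like(totals), where=totals > 0)
    return pd.DataFrame({
        "cell_id": m.cell_ids,
        "cluster": m.cluster,
        "score": score,
    })


def cluster_enrichment(
    scores: pd.DataFrame,
    positive_quantile: float = 0.75,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fisher enrichment of aboral-positive cells per cluster.

    A cell is positive iff its score strictly exceeds the dataset-wide
    ``positive_quantile`` of scores. Per cluster the one-sided test is on
    ``[[pos_in, neg_in], [pos_out, neg_out]]``; q-values are BH across
    clusters and ``enriched`` flags q < ``alpha``. Constant scores leave
    no positives definable: all p = 1 with a warning.
    """
    clusters = sorted(set(scores["cluster"]))
    if len(clusters) < 2:
        raise ValueError("cluster enrichment needs >= 2 clusters")
    vals = scores["score"].to_numpy()
    cutoff = float(np.quantile(vals, positive_quantile))
    positive = vals > cutoff
    if not positive.any():
        warnings.warn("constant scores: no aboral-positive cells definable")
    rows = []
    n_total = len(vals)
    n_pos_total = int(positive.sum())
    for c in clusters:
        in_c = (scores["cluster"] == c).to_numpy()
        pos_in = int(positive[in_c].sum())
        n_in = int(in_c.sum())
        if n_pos_total == 0:
            p = 1.0
        else:
            table = ContingencyTable(
                pos_in, n_in - pos_in,
                n_pos_total - pos_in, (n_total - n_in) - (n_pos_total - pos_in),
            )
            p = fisher_exact(table, alternative="greater")
        rows.append({
            "cluster": c,
            "n_cells": n_in,
            "mean_score": float(vals[in_c].mean()),
            "n_positive": pos_in,
            "p": p,
        })
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["enriched"] = out["q"] < alpha
    out.attrs["score_cutoff"] = cutoff
    return out


def cluster_markers(
    norm: sparse.csr_matrix,
    clusters: np.ndarray,
    gene_ids: list[str],
    min_cluster_size: int = 2,
) -> dict[str, pd.DataFrame]:
    """Per-cluster ranked marker tables (cluster vs rest Wilcoxon).

    For every cluster and gene: Wilcoxon U and p of the cluster's cells
    against all others on the normalized log values, BH within the
    cluster, and the log2 fold change of expm1 means. Ranked by p then
    decreasing |lfc|. Singleton clusters are still tested but flagged
    ``low_power`` in the frame's attrs.
    """
    dense = np.asarray(norm.todense())
    clusters = np.asarray(clusters)
    out: dict[str, pd.DataFrame] = {}
    eps = 1e-9
    expm1 = np.expm1(dense)
    for c in sorted(set(clusters)):
        mask = clusters == c
        u, p = rank_sum_matrix(dense, mask)
        q = bh_adjust(p)
        mean_in = expm1[mask].mean(axis=0)
        mean_out = expm1[~mask].mean(axis=0)
        lfc = np.log2((mean_in + eps) / (mean_out + eps))
        df = pd.DataFrame({
            "gene_id": gene_ids, "U": u, "p": p, "q": q, "log2fc": lfc,
        })
        df["_abs_lfc"] = df["log2fc"].abs()
        df = df.sort_values(["p", "_abs_lfc"], ascending=[True, False])
        df = df.drop(columns="_abs_lfc").reset_index(drop=True)
        df.attrs["low_power"] = bool(mask.sum() < min_cluster_size)
        out[str(c)] = df
    return out
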