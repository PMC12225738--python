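# planaxis

Mapping cell types along the oral–aboral body axis of cnidarian planula
larvae, from bulk and single-cell transcriptomes.

Planula larvae swim with their aboral (anterior) pole leading and use it
to choose a settlement site, but which cell types populate that pole is
hard to pin down: the axis is molecularly graded rather than segmented.
A productive strategy is to bisect larvae into aboral and oral halves,
sequence both, and then project the resulting "aborally enriched" gene
set onto a single-cell atlas to find the clusters that carry the aboral
program. `planaxis` implements that computational chain as a reusable,
tested Python library:

1. **Bulk differential expression** (`planaxis.bulk_de`) — negative-
   binomial Wald tests on bisected-larva counts: median-of-ratios size
   factors *s_j*, per-gene dispersion *α_i* (Cox–Reid adjusted likelihood
   with empirical-Bayes shrinkage toward an *a₀ + a₁/m* trend), a
   per-gene GLM `log μ_ij = β₀ + β₁·aboral_j (+ batch) + log s_j`, Wald
   `p = 2Φ(−|β̂₁/SE|)`, Benjamini–Hochberg adjustment, and symmetric
   enriched-set calls at `q < 0.05`, `log2FC > 0`.
2. **Orthology** (`planaxis.orthology`) — one-to-one orthologs by
   Smith–Waterman reciprocal best hits (BLOSUM62, affine gaps, ties
   disqualify), and transitive chaining of pairwise maps into ortholog
   groups shared by *k* of *n* species.
3. **Gene-class composition** (`planaxis.annotation`) — Pfam-style
   domain rules (GPCR: 7tm_1/2/3; ion channels: Ion_trans, Lig_chan,
   Neur_chan_memb, Neur_chan_LBD; secreted: signal peptide) with
   one-sided Fisher tests of aboral over-representation.
4. **Single-cell projection** (`planaxis.single_cell`) — droplet QC
   (300-UMI cutoff, <200 genes/cell, <3 cells/gene, per-dataset
   mitochondrial maximum), a per-cell **aboral score** = aboral-set UMIs
   / total UMIs on raw counts, Fisher enrichment of high-scoring cells
   per cluster, and Wilcoxon rank-sum cluster markers.
5. **Neuropeptide prediction** (`planaxis.neuropeptides`) — dibasic-site
   cleavage ({KR, RR, KK, RK}), C-terminal amidation from a trailing
   glycine (HFRIG → HFRI-amide), N-terminal pyroglutamate from a leading
   glutamine (QYFG → pyroGlu-YF-amide), and tandem-repeat motif
   detection (IPYFAN-type precursors).
6. **Synthetic data** (`planaxis.simulate`) — every input above with
   known ground truth: NB bulk counts with planted enriched genes,
   multinomial UMI matrices with planted aboral clusters, diverged
   ortholog proteomes, and precursors with rule-derivable products.
7. **Pipeline + CLI** (`planaxis.pipeline`, `planaxis` command) — all
   stages from one YAML config with deterministic, config-hash-stamped
   TSV outputs.

The statistical primitives (`planaxis.stats`) — log-space exact Fisher
tests that stay precise on cell-level tables, BH adjustment, tie-aware
Wilcoxon — are authored here and verified against exhaustive enumeration
oracles in the test suite.

## Worked example

`examples/` holds one short script per capability. Projecting a planted
aboral gene set onto a simulated 1200-cell atlas
(`python examples/04_aboral_cell_scoring.py`) prints:

```
cluster  n_cells  mean_score  n_positive            p            q  enriched
    c00      100    0.132039         100 3.265348e-67 1.959209e-66      True
    c01      100    0.095070          98 3.235644e-62 1.294258e-61      True
    c02      100    0.124073         100 3.265348e-67 1.959209e-66      True
    c03      100    0.058484           1 1.000000e+00 1.000000e+00     False
    ...
clusters called aboral: ['c00', 'c01', 'c02']  planted: ['c00', 'c01', 'c02']
```

Each row is a cell cluster: `mean_score` is the average fraction of the
cluster's UMIs falling on aborally enriched genes, `n_positive` counts
cells above the dataset-wide upper-quartile score, and `p`/`q` give the
one-sided Fisher enrichment of positive cells with BH adjustment. The
three planted aboral clusters — and only those — are called.

The neuropeptide scanner (`python examples/05_neuropeptide_scan.py`)
reproduces the canonical worked cases:

```
pp-HFRI: 4 dibasic sites -> ['HFRI-amide', 'HFRI-amide', 'HFRI-amide']  ...
pp-QYF: 3 dibasic sites -> ['QYF-amide (pyroGlu)', 'QYF-amide (pyroGlu)']  ...
pp-IPYFAN: 6 dibasic sites -> ['IPYFAN', ...]  repeat motif IPYFAN x5  ...
```

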