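# Methods

This note documents the models behind each `planaxis` stage, the
parameters that matter, what the synthetic-data generators do and do not
emulate, and the numerical choices made where the design was open.

## Exact and rank-based primitives

**Fisher's exact test** on a 2×2 table is computed from the
hypergeometric distribution with all margins fixed. Log-space point
probabilities (via `gammaln`) are exponentiated and renormalized, so the
pmf is exact to machine precision even for cell-level tables with tens
of thousands of counts, and complementary tail sums add to 1 to ~1e-15.
The one-sided `greater` alternative sums `P(X ≥ a)`; the two-sided
variant sums probabilities of all tables whose point probability does
not exceed the observed one, with a relative tie tolerance of 1e-7 (the
common convention). Degenerate margins (an empty row, column or table)
return `p = 1` with a warning rather than raising: degenerate tables
arise routinely in composition tests on small sets and should not abort
a pipeline run. Enrichment tests throughout default to `greater`
because every downstream claim is directional (over-representation);
the two-sided form remains available.

**Benjamini–Hochberg adjustment** is the standard step-up
`q(i) = min_{j≥i} p(j)·m/j`, clipped at 1, returned in input order. It
never decreases a p-value and is monotone in the sorted order. (It is
*not* idempotent on its own output — re-adjusting multiplies by `m/j`
again — so no such property is claimed or tested.)

**Wilcoxon rank-sum** uses midranks, the tie-corrected normal
approximation and a 0.5 continuity correction; `U` counts x-over-y
pairs with ties at half weight. The approximation's relative accuracy
degrades in extreme tails and for tiny tie-heavy samples (errors up to
~50% relative at n, m ≤ 5 with heavy ties); the exact-enumeration
comparison in the tests is therefore absolute-bounded at tiny sizes and
10%-relative on tie-free samples of eight per group. Production use is
cluster-marker calling at hundreds of cells per group, far inside the
approximation's comfort zone.

## Bulk differential expression

The model is the standard negative-binomial GLM for RNA-seq counts
`K_ij`: `K_ij ~ NB(μ_ij, α_i)` with `Var = μ + αμ²` and
`log μ_ij = β₀ᵢ + β₁ᵢ·aboral_j (+ batch terms) + log s_j`.

* **Size factors** `s_j`: median across always-detected genes of
  `K_ij / geomean_i(K_i·)`, computed literally in linear space (the
  log-space median differs at the 1e-8 level for even gene counts and
  was rejected in favor of the stated formula). A fallback over
  per-sample positive genes handles matrices without universally
  detected genes.
* **Dispersion** `α_i`: with two replicates per condition, the
  method-of-moments estimate `(v−m)/m²` has ~2 degrees of freedom and a
  log-scale sampling deviation above 1, and a fixed halfway shrinkage
  toward a trend leaves the Wald stage badly anticonservative (null
  type-I ≈ 0.12 at p < 0.05 in our simulations). The default estimator
  therefore maximizes the Cox–Reid-adjusted profile likelihood
  `ℓ(α) = Σ_j log NB(y_j; μ̂_j, α) − ½ log det(XᵀWX)` on a 48-point log
  grid (1e-7…30, parabolic refinement), fits a robust `α(m) = a₀ + a₁/m`
  trend to the gene-wise maxima, sets a log-normal prior width from the
  residual spread minus the `trigamma((n−p)/2)` sampling variance
  (floored at 0.25), and returns the MAP estimate. This brings null
  type-I to ≈ 0.06. The simpler method-of-moments + fixed-weight
  shrinkage path is retained behind `DEConfig.shrink_weight` for
  comparison. `α_floor = 1e-8`.
* **Wald test**: per-gene IRLS (batched across genes with `einsum`
  normal equations), `p = 2Φ(−|β̂₁/SE|)` with SE from the observed
  information at convergence, BH adjustment, and calls at `q < alpha`
  with `log2FC` strictly beyond `±lfc_min` (defaults 0.05 and 0 —
  "fold change above 1" read as a sign condition on the log scale, with
  the magnitude knob exposed). Non-converged genes get `p = NA` and are
  excluded from calls; all-zero genes are excluded before fitting.
* **Deliberately omitted**: independent filtering, LFC shrinkage and
  outlier replacement. With n = 2 per condition these refinements are
  under-determined; the calls are transparent instead of maximally
  powered.

**Known limitation — FDR at two replicates.** With 2 residual degrees
of freedom, any plug-in-dispersion Wald pipeline has heavy-tailed null
p-values at extreme thresholds (null rate ≈ 4.5e-3 at p < 1e-4 in our
simulations), so BH's realized false-discovery proportion among
discoveries runs near 0.2 rather than the nominal 0.05–0.075 when true
dispersions span two decades. A reference DESeq2 run on identical
simulated matrices shows the same recall and FDR to within 0.02 — this
is a property of the design size, not of this implementation. Treat
two-replicate calls as candidate sets for downstream intersection (the
cross-species sharing step is itself a strong false-positive filter).

## Synthetic data

Generators are pure functions of `(config, seed)` (NumPy `Generator`
streams; byte-identical reruns) and emit files that round-trip through
the pipeline's own readers.

* **Bulk**: NB counts with planted `β = ±bulk_lfc` genes, gene means
  log-uniform on [20, 2000], per-gene α log-uniform on [0.01, 1], size
  factors log-uniform on [0.5, 2], optional per-gene Gaussian batch
  coefficients on an alternating batch label. Defaults encode the
  bisected-larva design: two replicates per condition, 2000 genes, 100
  planted per direction, lfc 2.
* **Single cell**: per cell, depth ~ Poisson(`cell_depth_mean`), a
  uniform mitochondrial fraction routed to dedicated `mt-` genes, and a
  multinomial draw from the cell's cluster profile (gamma-distributed
  gene weights, concentration 0.3). Planted aboral clusters multiply
  aboral-gene weights by `aboral_score_shift` before renormalization —
  the simplest model under which the aboral score's expectation is
  analytically elevated. Each cluster also carries one exclusive marker
  gene for marker-recovery tests. Not emulated: doublets, ambient RNA,
  batch structure, zero-inflation beyond the multinomial.
* **Proteomes**: ancestor sequences uniform over the 20-letter
  alphabet; descendants mutate each site independently with probability
  `divergence`; optional duplicated decoys at twice the divergence.
  Uniform residue frequencies are unrealistic but sufficient for
  recovery testing of reciprocal best hits; no indels or rate
  heterogeneity.
* **Precursors**: a 20-residue basic-free signal stub, then peptide
  cassettes each flanked by KR sites; expected products (with
  amidation/pyroGlu flags) recorded exactly as the scanner rules
  dictate. Templates whose peptides contain internal dibasic pairs or
  terminal basics are refused — their ground truth would be ambiguous.

Passing tests on these fixtures demonstrate correctness of the
algorithms under their stated noise models, not performance on real
larval data — real data add mapping artifacts, compositional biases and
annotation errors that no fixture here reproduces.

## Orthology

Local alignment is Smith–Waterman with affine gaps under BLOSUM62,
executed by Biopython's `PairwiseAligner` behind the package interface;
`X` is rescored to 0 against everything. The gap convention is
`cost(L) = gap_open + (L−1)·gap_extend`, defaults 11/1, `score_min` 50 —
conventional protein-search settings; nothing in the problem pins them,
and all are configurable. Reciprocal best hits require mutual *unique*
maxima: tied best hits disqualify the query, so identical duplicates are
left unassigned instead of arbitrarily paired. An optional shared-4-mer
prefilter (off by default) bounds all-vs-all cost on large proteomes.
Cross-species groups are connected components of the pairwise one-to-one
links; a component with two members in one species marks inconsistent
chaining and is flagged ambiguous rather than silently resolved; an
enriched gene with no ortholog anywhere is reported as a singleton
group, never dropped.

## Single-cell integration

QC applies four rules in a fixed order, each on the current matrix:
total UMI ≥ 300, detected genes ≥ 200 per cell, mitochondrial fraction
≤ the per-dataset maximum, genes detected in ≥ 3 cells. "Fewer than"
thresholds are strict, so boundary cells/genes are retained. The order
is logged per step so alternative orders can be compared; the rules
themselves do not commute exactly (gene filtering changes detected-gene
counts), which is why the order is part of the contract.

The aboral score is a count fraction on **raw** UMIs — normalizing
first would reweight cells by depth and break the "fraction of the
cell's transcripts" reading. Cluster enrichment binarizes cells at the
dataset-wide 0.75 score quantile and Fisher-tests positive-cell counts
per cluster (one-sided, BH across clusters, called at q < 0.05). The
binarization-based table was chosen because enrichment p-values of
realistic magnitude (10⁻¹⁰…10⁻⁷⁰ at ~10⁴ cells) arise from cell-count
tables, whereas pooling UMIs into the table would produce implausibly
extreme values; a pooled mode can be emulated by passing precomputed
scores. The quantile is exposed in config.

Marker calling normalizes cells to 10⁴ total counts, log1p-transforms,
and runs a per-gene Wilcoxon of cluster vs rest with BH within cluster,
ranking by p then |log2FC| of expm1 means. Normalized values are used
for markers only, never for scores.

Because Fisher and Wilcoxon p-values are discrete, permutation-null
uniformity checks are run at sizes where point masses sit below the
Kolmogorov–Smirnov resolution: cluster tables of ~1000 cells (six
clusters of a 6000-cell matrix) and one cluster p-value per permutation;
markers on well-detected genes, one gene per permutation. At smaller
table sizes the same p-values are visibly superuniform (conservative) —
a property of discrete tests, not a calibration failure.

## Neuropeptide scanning

Sites are adjacent basic pairs {KR, RR, KK, RK} (all four dibasics on by
default, monobasic sites off), scanned left to right without overlap —
in a run like `KRR` the leftmost pair wins and scanning resumes after
it. Products are the inter-site segments downstream of the signal
cleavage position (a 20-residue default stub when the flag is set
without a position); a trailing glycine before a site or the terminus is
trimmed and marks amidation, a leading glutamine marks pyroglutamate;
products outside 3–50 residues (after trimming) are discarded as
implausible. Precursors without a signal peptide yield no products — a
secreted precursor is definitional. The repeat-motif search chains
tandem k-mers (k 4–8) allowing a ≤4-residue linker that contains a
cleavage motif; homopolymers and k-mers overlapping a detected cleavage
site are excluded (the repeat unit is the mature peptide, not the
peptide-plus-site cassette); ties prefer larger k, then the leftmost
occurrence. A precursor is flagged neuropeptide-like iff it has a
signal peptide and ≥ 2 products with ≥ 1 amidated; IPYFAN-type repeat
precursors lacking the amidation glycine yield non-amidated products
and are deliberately not flagged by this criterion. Copy-number and
length bounds are declared defaults, not inferred from data.

## Pipeline

`run_all` executes DE per species → orthology and shared-set
intersection → composition tests → single-cell scoring/enrichment/
markers → precursor scan from one validated YAML config (unknown keys
rejected, paths checked before any computation). Every output TSV's
first line records the producing stage, a 12-hex hash of the scientific
parameters (paths excluded, so re-running into a different directory
stays byte-identical) and the package version. Identical config and
seed give byte-identical outputs; stage failure halts with the stage
name. The run report echoes only numbers recomputable from the emitted
tables.

The default end-to-end fixture plants saturating bulk effects (lfc 6,
dispersions ≤ 0.2, means ≥ 100) and low divergence (0.05) across three
200-gene species: the intersection test is meant to isolate the
chaining/bookkeeping logic under saturated set recovery, while DE power
and RBH sensitivity are exercised separately at the harder study
conditions (lfc 2; divergence 0.1). Problem sizes throughout
(2000-gene bulk, 1200–6000-cell matrices, 200-protein proteomes) were
chosen as the smallest at which the statistical checks are
well-resolved.
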