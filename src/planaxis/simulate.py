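"""Synthetic fixtures with known ground truth for every pipeline stage.

Everything the pipeline consumes can be generated here: bisected-larva
bulk count tables with a planted aborally/orally enriched gene set,
clustered sparse UMI matrices with planted aboral clusters, diverged
ortholog proteome pairs, and neuropeptide precursor proteins whose
cleavage products are known by construction. All generators are pure
functions of ``(config, seed)``: the same configuration yields
bit-identical output on every run.

The defaults encode the study design the pipeline targets: two biological
replicates per condition (aboral/oral halves), negative-binomial bulk
counts with per-gene dispersion, multinomial per-cell UMI sampling over
cluster-specific expression profiles, and per-site substitution for
ortholog divergence. See ``docs/methods.md`` for what the simulations do
and do not emulate about real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import sparse

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "PeptideSpec",
    "PrecursorTemplate",
    "generate_bulk",
    "generate_cells",
    "generate_proteomes",
    "generate_precursors",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_SIGNAL_ALPHABET = "LAVFST"  # hydrophobic-ish, free of basic residues


@dataclass(frozen=True)
class PeptideSpec:
    """One peptide cassette of a precursor template.

    ``amidated`` appends the glycine that marks C-terminal amidation;
    ``copies`` repeats the cassette (each copy flanked by dibasic sites).
    """

    peptide: str
    amidated: bool = True
    copies: int = 1


@dataclass(frozen=True)
class PrecursorTemplate:
    name: str
    has_signal_peptide: bool
    peptides: tuple[PeptideSpec, ...]


DEFAULT_PRECURSOR_TEMPLATES: tuple[PrecursorTemplate, ...] = (
    PrecursorTemplate("pp-HFRIa", True, (PeptideSpec("HFRI", True, 3),)),
    PrecursorTemplate("pp-QYFa", True, (PeptideSpec("QYF", True, 2),)),
    PrecursorTemplate("pp-IPYFAN", True, (PeptideSpec("IPYFAN", False, 5),)),
    PrecursorTemplate("decoy-nosignal", False, (PeptideSpec("HFRI", True, 2),)),
)


@dataclass
class SimulationConfig:
    """Knobs of every generator; defaults encode the target study design."""

    seed: int = 0

    # -- bulk aboral/oral design --------------------------------------
    n_genes: int = 2000
    n_enriched_aboral: int = 100
    n_enriched_oral: int = 100
    bulk_lfc: float = 2.0  # log2 fold change magnitude of planted genes
    #: scalar alpha for all genes, or a (lo, hi) log-uniform range per gene
    nb_dispersion: float | tuple[float, float] = (0.01, 1.0)
    n_replicates: int = 2  # samples per condition
    base_mean_range: tuple[float, float] = (20.0, 2000.0)
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    #: s.d. (log2) of per-gene batch coefficients; 0 disables the batch covariate
    batch_lfc: float = 0.0

    # -- single-cell matrix -------------------------------------------
    n_cells: int = 1200
    n_clusters: int = 12
    n_aboral_clusters: int = 3
    cell_depth_mean: float = 1000.0
    aboral_score_shift: float = 3.0
    mito_fraction_range: tuple[float, float] = (0.01, 0.10)
    n_mito_genes: int = 10
    #: Dirichlet-like concentration of cluster expression profiles
    profile_concentration: float = 0.3
    #: weight multiplier of the one planted exclusive marker gene per cluster
    marker_boost: float = 30.0

    # -- proteomes ----------------------------------------------------
    n_proteins: int = 200
    protein_length: int = 120
    divergence: float = 0.1  # per-site substitution probability
    paralog_fraction: float = 0.0

    # -- precursors ---------------------------------------------------
    precursor_templates: tuple[PrecursorTemplate, ...] = DEFAULT_PRECURSOR_TEMPLATES

    def __post_init__(self) -> None:
        if self.n_enriched_aboral + self.n_enriched_oral > self.n_genes:
            raise ValueError("planted enriched genes exceed n_genes")
        if self.n_aboral_clusters > self.n_clusters:
            raise ValueError("n_aboral_clusters exceeds n_clusters")
        for lo, hi in (self.mito_fraction_range,):
            if not (0 <= lo <= hi <= 1):
                raise ValueError("mito_fraction_range must be within [0, 1]")
        if not (0 <= self.divergence <= 0.5):
            raise ValueError("divergence must lie in [0, 0.5]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted truth emitted alongside every fixture bundle."""

    aboral_gene_ids: set[str] = field(default_factory=set)
    oral_gene_ids: set[str] = field(default_factory=set)
    #: species-pair key "spA|spB" -> list of (idA, idB)
    ortholog_pairs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    aboral_cluster_ids: set[str] = field(default_factory=set)
    #: precursor id -> list of {"peptide", "amidated", "pyro_glu"}
    expected_products: dict[str, list[dict]] = field(default_factory=dict)
    #: precursor id -> (motif, count); only for repeat-bearing templates
    expected_motifs: dict[str, tuple[str, int]] = field(default_factory=dict)
    #: cluster id -> planted exclusive marker gene id
    cluster_marker_genes: dict[str, str] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "aboral_gene_ids": sorted(self.aboral_gene_ids),
            "oral_gene_ids": sorted(self.oral_gene_ids),
            "ortholog_pairs": {
                k: [list(p) for p in v] for k, v in self.ortholog_pairs.items()
            },
            "aboral_cluster_ids": sorted(self.aboral_cluster_ids),
            "expected_products": self.expected_products,
            "expected_motifs": {k: list(v) for k, v in self.expected_motifs.items()},
            "cluster_marker_genes": self.cluster_marker_genes,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            aboral_gene_ids=set(d["aboral_gene_ids"]),
            oral_gene_ids=set(d["oral_gene_ids"]),
            ortholog_pairs={
                k: [tuple(p) for p in v] for k, v in d["ortholog_pairs"].items()
            },
            aboral_cluster_ids=set(d["aboral_cluster_ids"]),
            expected_products=d["expected_products"],
            expected_motifs={k: tuple(v) for k, v in d["expected_motifs"].items()},
            cluster_marker_genes=d["cluster_marker_genes"],
        )


# ---------------------------------------------------------------------
# bulk counts


def _dispersions(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(config.nb_dispersion, (int, float)):
        return np.full(config.n_genes, float(config.nb_dispersion))
    lo, hi = config.nb_dispersion
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=config.n_genes))


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, variance = mu + alpha*mu^2); alpha ~ 0 degenerates to Poisson."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    poisson_like = alpha < 1e-12
    if poisson_like.any():
        out[poisson_like] = rng.poisson(mu[poisson_like])
    nb = ~poisson_like
    if nb.any():
        size = 1.0 / alpha[nb]
        p = size / (size + mu[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def generate_bulk(config: SimulationConfig):
    """Bisected-larva bulk counts with a planted enriched gene set.

    Counts are negative-binomial with mean
    ``mu_ij = s_j * q_i * 2**(beta_i * x_j + b_i * z_j)`` where ``x_j`` is
    the aboral indicator, ``beta_i = +lfc`` for planted aboral genes,
    ``-lfc`` for planted oral genes and 0 otherwise, and ``z_j`` an
    optional batch indicator with per-gene coefficients ``b_i``.

    Returns ``(BulkCounts, GroundTruth)``.
    """
    from .bulk_de import BulkCounts  # local import to avoid a cycle

    if config.n_replicates < 2:
        raise ValueError("n_replicates must be >= 2: the DE stage needs "
                         "within-condition variance")
    if config.n_genes < 1:
        raise ValueError("n_genes must be positive")
    rng = np.random.default_rng(config.seed)
    g = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(g)]
    aboral = set(gene_ids[: config.n_enriched_aboral])
    oral = set(
        gene_ids[config.n_enriched_aboral : config.n_enriched_aboral + config.n_enriched_oral]
    )
    beta = np.zeros(g)
    beta[: config.n_enriched_aboral] = config.bulk_lfc
    beta[config.n_enriched_aboral : config.n_enriched_aboral + config.n_enriched_oral] = (
        -config.bulk_lfc
    )
    lo, hi = config.base_mean_range
    q = np.exp(rng.uniform(np.log(lo), np.log(hi), size=g))
    alpha = _dispersions(config, rng)

    n_per = config.n_replicates
    n_samples = 2 * n_per
    condition = ["aboral"] * n_per + ["oral"] * n_per
    x = np.array([1.0] * n_per + [0.0] * n_per)
    slo, shi = config.size_factor_range
    s = np.exp(rng.uniform(np.log(slo), np.log(shi), size=n_samples))

    batch = None
    log2_mu = np.log2(q)[:, None] + beta[:, None] * x[None, :]
    if config.batch_lfc > 0:
        z = np.array([j % 2 for j in range(n_samples)], dtype=float)
        batch = [f"b{int(v)}" for v in z]
        b = rng.normal(0.0, config.batch_lfc, size=g)
        log2_mu = log2_mu + b[:, None] * z[None, :]
    mu = s[None, :] * np.exp2(log2_mu)
    counts = _nb_draw(rng, mu, alpha[:, None])

    sample_ids = [f"{c}_{j % n_per + 1}" for j, c in enumerate(condition)]
    bc = BulkCounts(
        matrix=counts,
        gene_ids=gene_ids,
        sample_ids=sample_ids,
        condition=condition,
        batch=batch,
    )
    truth = GroundTruth(aboral_gene_ids=aboral, oral_gene_ids=oral)
    return bc, truth


# ---------------------------------------------------------------------
# single-cell UMI matrix


def generate_cells(config: SimulationConfig, truth: GroundTruth):
    """Clustered sparse UMI matrix with planted aboral clusters.

    Per cell: depth ~ Poisson(cell_depth_mean), a mitochondrial fraction
    drawn uniformly from ``mito_fraction_range`` and assigned to dedicated
    ``mt-`` genes, and the remaining counts drawn multinomially from the
    cell's cluster expression profile. Planted aboral clusters multiply the
    aboral-set probabilities by ``aboral_score_shift`` before
    renormalization, so the expected aboral count fraction is analytically
    elevated in exactly those clusters.
    """
    import warnings as _warnings
    from .single_cell import CellMatrix  # local import to avoid a cycle

    if not truth.aboral_gene_ids:
        raise ValueError("ground truth lacks aboral_gene_ids")
    if config.aboral_score_shift <= 1 and config.n_aboral_clusters > 0:
        _warnings.warn("aboral_score_shift <= 1: planted aboral signal is absent")
    rng = np.random.default_rng(config.seed + 1)

    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]
    mito_ids = [f"mt-g{i:03d}" for i in range(config.n_mito_genes)]
    all_genes = gene_ids + mito_ids
    aboral_idx = np.array(
        [i for i, gid in enumerate(gene_ids) if gid in truth.aboral_gene_ids]
    )
    if aboral_idx.size == 0:
        raise ValueError("no aboral ground-truth gene is present in the catalog")

    k = config.n_clusters
    cluster_ids = [f"c{j:02d}" for j in range(k)]
    planted = set(cluster_ids[: config.n_aboral_clusters])

    # cluster expression profiles over non-mito genes
    profiles = rng.gamma(config.profile_concentration, 1.0, size=(k, config.n_genes))
    profiles = np.maximum(profiles, 1e-12)
    # one exclusive marker gene per cluster, drawn from unplanted genes
    n_planted_genes = config.n_enriched_aboral + config.n_enriched_oral
    marker_pool = np.arange(n_planted_genes, config.n_genes)
    marker_genes = rng.choice(marker_pool, size=k, replace=False)
    mean_w = profiles.sum(axis=1, keepdims=True) / config.n_genes
    for j in range(k):
        profiles[:, marker_genes[j]] = 0.0
        profiles[j, marker_genes[j]] = config.marker_boost * mean_w[j, 0]
    truth.cluster_marker_genes = {
        cluster_ids[j]: gene_ids[marker_genes[j]] for j in range(k)
    }
    for j, cid in enumerate(cluster_ids):
        if cid in planted:
            profiles[j, aboral_idx] *= config.aboral_score_shift
    profiles /= profiles.sum(axis=1, keepdims=True)

    labels = np.array([cluster_ids[i % k] for i in range(config.n_cells)])
    depths = np.maximum(1, rng.poisson(config.cell_depth_mean, size=config.n_cells))
    flo, fhi = config.mito_fraction_range
    mito_frac = rng.uniform(flo, fhi, size=config.n_cells)

    rows, cols, vals = [], [], []
    n_main = config.n_genes
    for i in range(config.n_cells):
        j = cluster_ids.index(labels[i])
        n_mito = rng.binomial(depths[i], mito_frac[i])
        main = rng.multinomial(depths[i] - n_mito, profiles[j])
        nz = np.nonzero(main)[0]
        rows.extend([i] * nz.size)
        cols.extend(nz.tolist())
        vals.extend(main[nz].tolist())
        if n_mito > 0 and config.n_mito_genes > 0:
            mvec = rng.multinomial(n_mito, np.full(config.n_mito_genes, 1.0 / config.n_mito_genes))
            mnz = np.nonzero(mvec)[0]
            rows.extend([i] * mnz.size)
            cols.extend((n_main + mnz).tolist())
            vals.extend(mvec[mnz].tolist())
    counts = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(config.n_cells, len(all_genes)), dtype=np.int64
    )
    truth.aboral_cluster_ids = planted
    return CellMatrix(
        counts=counts,
        cell_ids=[f"cell{i:05d}" for i in range(config.n_cells)],
        gene_ids=all_genes,
        cluster=labels,
        mito_gene_ids=set(mito_ids),
        qc_state="raw",
    )


# ---------------------------------------------------------------------
# proteomes


def _mutate(seq: str, p: float, rng: np.random.Generator) -> str:
    if p <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < p
    if hit.any():
        alphabet = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
        for i in np.nonzero(hit)[0]:
            choices = alphabet[alphabet != arr[i]]
            arr[i] = rng.choice(choices)
    return arr.tobytes().decode()


def generate_proteomes(
    config: SimulationConfig, n_species: int = 2, species_names: Sequence[str] | None = None
):
    """Diverged descendant proteomes from a common set of ancestor proteins.

    Each descendant proteome mutates every ancestor sequence independently
    per site with probability ``config.divergence``. A
    ``paralog_fraction`` of proteins per species gains a duplicated decoy
    diverged twice as far. Ground-truth one-to-one pairs (index-wise
    correspondence of the non-decoy sequences) are recorded for every
    species pair under the key ``"spA|spB"``.

    Returns ``(proteomes, truth)`` where ``proteomes`` maps species name to
    an id -> sequence dict.
    """
    rng = np.random.default_rng(config.seed + 2)
    if species_names is None:
        species_names = [f"sp{chr(ord('A') + i)}" for i in range(n_species)]
    else:
        species_names = list(species_names)
        n_species = len(species_names)
    lengths = rng.integers(
        max(10, int(0.8 * config.protein_length)),
        int(1.2 * config.protein_length) + 1,
        size=config.n_proteins,
    )
    ancestors = [
        "".join(rng.choice(list(AMINO_ACIDS), size=L)) for L in lengths
    ]
    proteomes: dict[str, dict[str, str]] = {}
    for sp in species_names:
        records: dict[str, str] = {}
        for i, anc in enumerate(ancestors):
            records[f"{sp}_g{i:04d}"] = _mutate(anc, config.divergence, rng)
        n_decoys = int(round(config.paralog_fraction * config.n_proteins))
        if n_decoys:
            decoy_src = rng.choice(config.n_proteins, size=n_decoys, replace=False)
            for i in decoy_src:
                records[f"{sp}_g{i:04d}_dup"] = _mutate(
                    ancestors[i], min(0.5, 2 * config.divergence), rng
                )
        proteomes[sp] = records
    truth = GroundTruth()
    for a in range(n_species):
        for b in range(a + 1, n_species):
            spa, spb = species_names[a], species_names[b]
            truth.ortholog_pairs[f"{spa}|{spb}"] = [
                (f"{spa}_g{i:04d}", f"{spb}_g{i:04d}") for i in range(config.n_proteins)
            ]
    return proteomes, truth


# ---------------------------------------------------------------------
# neuropeptide precursors

_DIBASIC = ("KR", "RR", "KK", "RK")


def _validate_peptide(pep: str, amidated: bool) -> None:
    full = pep + ("G" if amidated else "")
    for i in range(len(full) - 1):
        if full[i] in "KR" and full[i + 1] in "KR":
            raise ValueError(
                f"template peptide {pep!r} contains an internal dibasic pair: "
                "ground truth would be ambiguous"
            )
    if full[0] in "KR" or full[-1] in "KR":
        raise ValueError(
            f"template peptide {pep!r} starts or ends with a basic residue: "
            "would fuse with the flanking cleavage site"
        )


def generate_precursors(config: SimulationConfig):
    """Precursor proteins with cleavage products known by construction.

    Layout per precursor: a 20-residue signal stub (basic-residue-free),
    then each peptide cassette flanked by KR dibasic sites
    (``...KR | peptide(+G) | KR...``). Expected products carry the
    amidation flag (cassette ends in G) and the pyroglutamate flag
    (cassette starts with Q) exactly as the scanner rules dictate.

    Returns ``(precursors, truth)`` where ``precursors`` is a list of
    ``(id, sequence, has_signal_peptide, signal_cleavage_pos)`` tuples.
    """
    if not config.precursor_templates:
        raise ValueError("precursor_templates must be non-empty")
    rng = np.random.default_rng(config.seed + 3)
    precursors = []
    truth = GroundTruth()
    for tpl in config.precursor_templates:
        stub = "M" + "".join(rng.choice(list(_SIGNAL_ALPHABET), size=19))
        parts = [stub]
        expected = []
        for spec in tpl.peptides:
            _validate_peptide(spec.peptide, spec.amidated)
            cassette = spec.peptide + ("G" if spec.amidated else "")
            for _ in range(spec.copies):
                parts.append("KR" + cassette)
            if tpl.has_signal_peptide:
                expected.extend(
                    {
                        "peptide": spec.peptide,
                        "amidated": spec.amidated,
                        "pyro_glu": spec.peptide.startswith("Q"),
                    }
                    for _ in range(spec.copies)
                )
        parts.append("KR")
        seq = "".join(parts)
        precursors.append((tpl.name, seq, tpl.has_signal_peptide, 20 if tpl.has_signal_peptide else None))
        truth.expected_products[tpl.name] = expected
        for spec in tpl.peptides:
            if not spec.amidated and spec.copies >= 3 and 4 <= len(spec.peptide) <= 8:
                truth.expected_motifs[tpl.name] = (spec.peptide, spec.copies)
    return precursors, truth
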