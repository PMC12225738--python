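"""End-to-end orchestration: fixture generation, staged runs, run report.

``make_fixtures`` writes a complete synthetic input bundle (multi-species
bulk counts, proteomes, annotation tables, a clustered UMI matrix,
precursor proteins and the ground-truth JSON). ``run_all`` executes the
stages — per-species bulk DE, reciprocal-best-hit orthology with
cross-species intersection of enriched sets, gene-class composition
tests, single-cell QC/scoring/enrichment/markers, and the neuropeptide
scan — from one validated configuration, writing TSV outputs whose first
line records the producing stage and the configuration hash. Identical
configuration and seed give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .annotation import DEFAULT_CLASS_RULES, classify_genes, composition_test
from .bulk_de import BulkCounts, DEConfig, call_enriched, run_de
from .neuropeptides import PrecursorProtein, ScanConfig, scan_fasta
from .orthology import AlignmentParams, reciprocal_best_hits, shared_enriched
from .simulate import GroundTruth, SimulationConfig, generate_bulk, generate_cells, \
    generate_precursors, generate_proteomes
from .single_cell import QCThresholds, aboral_score, cluster_enrichment, \
    cluster_markers, normalize_log, qc_filter

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "ConfigError", "StageError", "make_fixtures", "run_all"]


class ConfigError(ValueError):
    """Invalid or incomplete pipeline configuration."""


class StageError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """All stage parameters plus input paths and the output directory."""

    seed: int = 0
    input_dir: str = "fixtures"
    output_dir: str = "results"
    species: list[str] = field(default_factory=lambda: ["spA", "spB", "spC"])
    cell_species: str = "spA"
    skip_stages: list[str] = field(default_factory=list)
    # stage parameter blocks
    de_alpha: float = 0.05
    de_lfc_min: float = 0.0
    gap_open: int = 11
    gap_extend: int = 1
    score_min: float = 50.0
    qc_min_genes_per_cell: int = 200
    qc_min_cells_per_gene: int = 3
    qc_min_umi: int = 300
    qc_max_mito_fraction: float = 0.20
    positive_quantile: float = 0.75
    site_motifs: list[str] = field(default_factory=lambda: ["KR", "RR", "KK", "RK"])

    _KNOWN = None  # populated below

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if not f.startswith("_")}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d.pop("_KNOWN", None)
        return d

    def params_dict(self) -> dict:
        """Scientific parameters only — paths and stage skips excluded."""
        d = self.to_dict()
        for k in ("input_dir", "output_dir", "skip_stages"):
            d.pop(k, None)
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.params_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    def validate_paths(self) -> None:
        root = Path(self.input_dir)
        if not root.is_dir():
            raise ConfigError(f"input directory {root} does not exist")
        required = []
        for sp in self.species:
            required += [root / f"bulk_{sp}.tsv", root / f"samples_{sp}.tsv",
                         root / f"proteome_{sp}.fasta", root / f"annotation_{sp}.tsv"]
        required += [root / "cells", root / "precursors.fasta",
                     root / "precursor_meta.tsv"]
        missing = [str(p) for p in required if not p.exists()]
        if missing:
            raise ConfigError(f"missing inputs: {missing}")


# ---------------------------------------------------------------------
# fixture bundle


def default_fixture_config(seed: int = 0) -> SimulationConfig:
    """Simulation settings for the end-to-end fixture bundle.

    Sized so the full pipeline runs in well under a minute per stage:
    200-gene catalogs shared across three species, strong planted bulk
    effects (lfc 4) and low sequence divergence (0.05) so that set
    recovery is saturated and the cross-species intersection isolates the
    chaining logic, and a 600-cell matrix with three planted aboral
    clusters of twelve.
    """
    return SimulationConfig(
        seed=seed,
        n_genes=200,
        n_enriched_aboral=10,
        n_enriched_oral=10,
        bulk_lfc=6.0,
        nb_dispersion=(0.01, 0.2),
        base_mean_range=(100.0, 2000.0),
        n_cells=600,
        n_clusters=12,
        n_aboral_clusters=3,
        cell_depth_mean=800.0,
        n_proteins=200,
        protein_length=90,
        divergence=0.05,
    )


def default_pipeline_config(input_dir: str, output_dir: str, seed: int = 0) -> PipelineConfig:
    """Pipeline settings matched to :func:`default_fixture_config` scale.

    The droplet-QC gene threshold is scaled to the 200-gene fixture
    catalog (real datasets keep the conventional 200-genes-per-cell
    default).
    """
    return PipelineConfig(
        seed=seed,
        input_dir=input_dir,
        output_dir=output_dir,
        qc_min_genes_per_cell=50,
    )


def make_fixtures(
    config: SimulationConfig,
    outdir: str | Path,
    species: list[str] | None = None,
) -> GroundTruth:
    """Write a complete, internally consistent fixture bundle.

    Per species: a proteome FASTA diverged from shared ancestors, a bulk
    count table + sample sheet whose planted enriched genes are the
    descendants of the same ancestral gene indices in every species, and
    an annotation TSV with random domain/signal-peptide labels. One
    species additionally carries the clustered UMI matrix (its planted
    aboral genes boosted in the planted clusters) and the precursor FASTA.
    The combined ground truth is written as JSON alongside.
    """
    if config.n_genes <= 0:
        raise ConfigError("n_genes must be positive")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species = species or ["spA", "spB", "spC"]
    rng = np.random.default_rng(config.seed + 10)

    if config.n_proteins != config.n_genes:
        config = SimulationConfig(**{**config.to_dict(),
                                     "n_proteins": config.n_genes,
                                     "precursor_templates": config.precursor_templates})
    proteomes, truth = generate_proteomes(config, species_names=species)
    for sp in species:
        pio.write_fasta(proteomes[sp], outdir / f"proteome_{sp}.fasta")

    combined = GroundTruth(ortholog_pairs=truth.ortholog_pairs)
    cell_cm = None
    for k, sp in enumerate(species):
        sp_cfg = SimulationConfig(**{**config.to_dict(),
                                     "seed": config.seed + 100 + k,
                                     "precursor_templates": config.precursor_templates})
        bc, sp_truth = generate_bulk(sp_cfg)
        # rename catalog genes to this species' protein ids
        rename = {f"g{i:05d}": f"{sp}_g{i:04d}" for i in range(config.n_genes)}
        bc.gene_ids = [rename[g] for g in bc.gene_ids]
        pio.write_bulk_counts(bc, outdir / f"bulk_{sp}.tsv")
        pio.write_sample_sheet(bc, outdir / f"samples_{sp}.tsv")
        combined.aboral_gene_ids |= {rename[g] for g in sp_truth.aboral_gene_ids}
        combined.oral_gene_ids |= {rename[g] for g in sp_truth.oral_gene_ids}

        domains = []
        for gid in bc.gene_ids:
            r = rng.random()
            if r < 0.05:
                domains.append(str(rng.choice(["7tm_1", "7tm_2", "7tm_3"])))
            elif r < 0.10:
                domains.append(str(rng.choice(
                    ["Ion_trans", "Lig_chan", "Neur_chan_memb", "Neur_chan_LBD"])))
            elif r < 0.15:
                domains.append("TauD")
            else:
                domains.append("")
        ann = pd.DataFrame({
            "gene_id": bc.gene_ids,
            "domains": domains,
            "signal_peptide": (rng.random(len(bc.gene_ids)) < 0.2).astype(int),
        })
        pio.write_annotation(ann, outdir / f"annotation_{sp}.tsv")

        if sp == species[0]:
            cell_cm = generate_cells(sp_cfg, sp_truth)
            cell_cm.gene_ids = [rename.get(g, g) for g in cell_cm.gene_ids]
            combined.aboral_cluster_ids = sp_truth.aboral_cluster_ids
            combined.cluster_marker_genes = {
                c: rename[g] for c, g in sp_truth.cluster_marker_genes.items()
            }
    pio.write_cell_matrix(cell_cm, outdir / "cells")

    precursors, pre_truth = generate_precursors(config)
    pio.write_fasta({pid: seq for pid, seq, _, _ in precursors},
                    outdir / "precursors.fasta")
    meta = pd.DataFrame({
        "precursor_id": [p[0] for p in precursors],
        "has_signal_peptide": [int(p[2]) for p in precursors],
        "signal_cleavage_pos": [p[3] if p[3] is not None else -1 for p in precursors],
    })
    pio.write_table(meta, outdir / "precursor_meta.tsv", "simulate")
    combined.expected_products = pre_truth.expected_products
    combined.expected_motifs = pre_truth.expected_motifs

    (outdir / "ground_truth.json").write_text(combined.to_json() + "\n")
    return combined


# ---------------------------------------------------------------------
# staged execution


def run_all(config: PipelineConfig) -> dict:
    """Execute every stage from a validated config; returns the run report."""
    from . import __version__

    config.validate_paths()
    root = Path(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = config.config_hash()
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": h,
        "config": config.params_dict(),
        "stages": {},
    }
    skip = set(config.skip_stages)

    enriched_sets: dict[str, set[str]] = {}
    oral_sets: dict[str, set[str]] = {}
    de_ranks: dict[str, dict[str, int]] = {}
    if "de" not in skip:
        for sp in config.species:
            try:
                bc = pio.read_bulk_counts(root / f"bulk_{sp}.tsv",
                                          root / f"samples_{sp}.tsv")
                de = run_de(bc, DEConfig(alpha=config.de_alpha,
                                         lfc_min=config.de_lfc_min))
            except Exception as exc:  # noqa: BLE001 - halt with stage context
                raise StageError("de", f"species {sp}: {exc}") from exc
            pio.write_table(de.drop(columns=[], errors="ignore"),
                            out / f"de_{sp}.tsv", "bulk_de", h)
            ab, orl = call_enriched(de, config.de_alpha, config.de_lfc_min)
            enriched_sets[sp], oral_sets[sp] = ab, orl
            ranked = de.dropna(subset=["q"]).sort_values(["q", "p", "gene_id"])
            de_ranks[sp] = {g: i for i, g in enumerate(ranked["gene_id"])}
            pio.write_gene_set(ab, out / f"aboral_set_{sp}.tsv", "bulk_de", h)
            pio.write_gene_set(orl, out / f"oral_set_{sp}.tsv", "bulk_de", h)
            report["stages"][f"de_{sp}"] = {
                "n_genes": len(bc.gene_ids), "n_aboral": len(ab), "n_oral": len(orl),
                "n_nonconverged": de.attrs["n_nonconverged"],
            }

    maps = {}
    if "orthology" not in skip:
        params = AlignmentParams(gap_open=config.gap_open,
                                 gap_extend=config.gap_extend,
                                 score_min=config.score_min)
        try:
            for i, sp_a in enumerate(config.species):
                for sp_b in config.species[i + 1:]:
                    pa = pio.read_fasta(root / f"proteome_{sp_a}.fasta")
                    pb = pio.read_fasta(root / f"proteome_{sp_b}.fasta")
                    omap = reciprocal_best_hits(pa, pb, params)
                    maps[(sp_a, sp_b)] = omap
                    pio.write_table(omap.to_frame(),
                                    out / f"orthologs_{sp_a}_{sp_b}.tsv",
                                    "orthology", h)
                    report["stages"][f"rbh_{sp_a}_{sp_b}"] = {
                        "n_pairs": len(omap.pairs),
                        "n_unassigned": len(omap.unassigned),
                    }
            shared = shared_enriched(enriched_sets, maps, de_ranks or None)
            pio.write_table(shared, out / "shared_aboral_groups.tsv", "orthology", h)
            n_all = int((shared["n_species_enriched"] == len(config.species))
                        .sum()) if not shared.empty else 0
            n_all_clean = int(((shared["n_species_enriched"] == len(config.species))
                               & (~shared["ambiguous"])).sum()) if not shared.empty else 0
            report["stages"]["shared"] = {
                "n_groups": int(len(shared)),
                "n_shared_in_all": n_all,
                "n_shared_in_all_unambiguous": n_all_clean,
            }
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001
            raise StageError("orthology", str(exc)) from exc

    if "compose" not in skip:
        try:
            for sp in config.species:
                ann = pio.read_annotation(root / f"annotation_{sp}.tsv")
                classes = classify_genes(ann, DEFAULT_CLASS_RULES)
                comp = composition_test(enriched_sets.get(sp, set()),
                                        oral_sets.get(sp, set()), classes)
                pio.write_table(comp, out / f"composition_{sp}.tsv", "composition", h)
                report["stages"][f"composition_{sp}"] = {
                    "n_classes": int(len(comp)),
                }
        except Exception as exc:  # noqa: BLE001
            raise StageError("compose", str(exc)) from exc

    if "cells" not in skip:
        try:
            cm = pio.read_cell_matrix(root / "cells")
            thresholds = QCThresholds(
                min_genes_per_cell=config.qc_min_genes_per_cell,
                min_cells_per_gene=config.qc_min_cells_per_gene,
                min_umi=config.qc_min_umi,
                max_mito_fraction=config.qc_max_mito_fraction,
            )
            filtered = qc_filter(cm, thresholds)
            ab_set = enriched_sets.get(config.cell_species, set())
            scores = aboral_score(filtered, ab_set)
            pio.write_table(scores, out / "cell_scores.tsv", "cells", h)
            enr = cluster_enrichment(scores, config.positive_quantile)
            pio.write_table(enr, out / "cluster_enrichment.tsv", "cells", h)
            norm = normalize_log(filtered)
            markers = cluster_markers(norm, filtered.cluster, filtered.gene_ids)
            top = pd.concat(
                [df.head(20).assign(cluster=c) for c, df in sorted(markers.items())],
                ignore_index=True,
            )
            pio.write_table(top, out / "cluster_markers.tsv", "cells", h)
            report["stages"]["cells"] = {
                "n_cells_raw": cm.n_cells,
                "n_cells_filtered": filtered.n_cells,
                "n_genes_filtered": filtered.n_genes,
                "qc_log": filtered.qc_log,
                "n_enriched_clusters": int(enr["enriched"].sum()),
                "enriched_clusters": sorted(enr.loc[enr["enriched"], "cluster"]),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("cells", str(exc)) from exc

    if "scan" not in skip:
        try:
            seqs = pio.read_fasta(root / "precursors.fasta")
            meta = pio.read_table(root / "precursor_meta.tsv",
                                  dtype={"precursor_id": str})
            precursors = []
            for row in meta.itertuples(index=False):
                pos = int(row.signal_cleavage_pos)
                precursors.append(PrecursorProtein(
                    id=str(row.precursor_id),
                    sequence=seqs[str(row.precursor_id)],
                    has_signal_peptide=bool(int(row.has_signal_peptide)),
                    signal_cleavage_pos=pos if pos >= 0 else None,
                ))
            scan = scan_fasta(precursors, ScanConfig(
                site_motifs=tuple(config.site_motifs)))
            pio.write_table(scan, out / "neuropeptide_report.tsv", "scan", h)
            report["stages"]["scan"] = {
                "n_precursors": len(precursors),
                "n_products": int((scan["peptide"] != "").sum()),
                "n_neuropeptide_like": int(
                    scan.drop_duplicates("precursor_id")["neuropeptide_like"].sum()),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("scan", str(exc)) from exc

    pio.write_json(report, out / "run_report.json")
    return report
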