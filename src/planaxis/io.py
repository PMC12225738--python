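"""Readers and writers for the plain-text formats the pipeline exchanges.

Bulk counts and sample sheets are TSV; single-cell matrices are
MatrixMarket coordinate files with barcodes/features sidecars; sequences
are FASTA (via Biopython); ground truth and class rules are JSON. Every
table written by a pipeline stage starts with a ``#`` comment line
declaring the producing stage, the configuration hash and the package
version, and every reader here skips such lines.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy import sparse
from scipy.io import mmread, mmwrite


def table_header(stage: str, config_hash: str | None = None) -> str:
    from . import __version__

    parts = [f"stage={stage}", f"planaxis={__version__}"]
    if config_hash:
        parts.insert(1, f"config_hash={config_hash}")
    return "# " + " ".join(parts)


def write_table(df: pd.DataFrame, path: str | Path, stage: str,
                config_hash: str | None = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(table_header(stage, config_hash) + "\n")
        df.to_csv(fh, sep="\t", index=index, lineterminator="\n")


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


# ---------------------------------------------------------------------
# bulk counts + sample sheet


def write_bulk_counts(bc, path: str | Path, stage: str = "simulate",
                      config_hash: str | None = None) -> None:
    df = pd.DataFrame(bc.matrix, index=bc.gene_ids, columns=bc.sample_ids)
    df.index.name = "gene_id"
    write_table(df, path, stage, config_hash, index=True)


def write_sample_sheet(bc, path: str | Path, stage: str = "simulate",
                       config_hash: str | None = None) -> None:
    df = pd.DataFrame({
        "sample_id": bc.sample_ids,
        "condition": bc.condition,
        "batch": bc.batch if bc.batch is not None else [""] * len(bc.sample_ids),
    })
    write_table(df, path, stage, config_hash)


def read_bulk_counts(counts_path: str | Path, sheet_path: str | Path):
    from .bulk_de import BulkCounts

    df = read_table(counts_path, index_col=0)
    sheet = read_table(sheet_path, dtype={"sample_id": str}, keep_default_na=False)
    sheet = sheet.set_index("sample_id").loc[list(df.columns)]
    batch = None
    if "batch" in sheet.columns and any(str(b) not in ("", "nan") for b in sheet["batch"]):
        batch = [str(b) for b in sheet["batch"]]
    return BulkCounts(
        matrix=df.to_numpy(dtype=np.int64),
        gene_ids=[str(g) for g in df.index],
        sample_ids=[str(s) for s in df.columns],
        condition=[str(c) for c in sheet["condition"]],
        batch=batch,
    )


# ---------------------------------------------------------------------
# single-cell matrix (MTX + sidecars + cluster labels)


def write_cell_matrix(cm, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mat = sparse.coo_matrix(cm.counts)
    mmwrite(str(outdir / "matrix.mtx"), mat, field="integer")
    pd.Series(cm.cell_ids).to_csv(outdir / "barcodes.tsv", index=False, header=False)
    feats = pd.DataFrame({
        "gene_id": cm.gene_ids,
        "mito": [1 if g in cm.mito_gene_ids else 0 for g in cm.gene_ids],
    })
    feats.to_csv(outdir / "features.tsv", sep="\t", index=False, header=False)
    pd.DataFrame({"barcode": cm.cell_ids, "cluster": cm.cluster}).to_csv(
        outdir / "clusters.tsv", sep="\t", index=False
    )


def read_cell_matrix(outdir: str | Path):
    from .single_cell import CellMatrix

    outdir = Path(outdir)
    counts = sparse.csr_matrix(mmread(str(outdir / "matrix.mtx")), dtype=np.int64)
    barcodes = [
        line.strip() for line in open(outdir / "barcodes.tsv") if line.strip()
    ]
    feats = pd.read_csv(outdir / "features.tsv", sep="\t", header=None,
                        names=["gene_id", "mito"])
    clusters = pd.read_csv(outdir / "clusters.tsv", sep="\t", dtype=str)
    label_of = dict(zip(clusters["barcode"], clusters["cluster"]))
    return CellMatrix(
        counts=counts,
        cell_ids=barcodes,
        gene_ids=[str(g) for g in feats["gene_id"]],
        cluster=np.array([label_of[b] for b in barcodes]),
        mito_gene_ids={str(g) for g, m in zip(feats["gene_id"], feats["mito"]) if int(m) == 1},
        qc_state="raw",
    )


# ---------------------------------------------------------------------
# FASTA


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------
# annotations, rules, gene sets, JSON


def write_annotation(df: pd.DataFrame, path: str | Path, stage: str = "simulate",
                     config_hash: str | None = None) -> None:
    """Annotation schema: gene_id, domains (semicolon-joined), signal_peptide {0,1}."""
    write_table(df, path, stage, config_hash)


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = read_table(path, dtype={"gene_id": str}, keep_default_na=False)
    df["signal_peptide"] = df["signal_peptide"].astype(int)
    return df


def write_gene_set(genes: Iterable[str], path: str | Path, stage: str,
                   config_hash: str | None = None) -> None:
    write_table(pd.DataFrame({"gene_id": sorted(genes)}), path, stage, config_hash)


def read_gene_set(path: str | Path) -> set[str]:
    df = read_table(path, dtype=str)
    return set(df["gene_id"])


def write_json(obj, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
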