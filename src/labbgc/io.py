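"""Readers and writers for the plain-text formats the pipeline exchanges.

TSV carries matrices and tables (feature matrix, read counts in long format,
taxon profiles, cluster assignments, edge lists), GFF3 carries BGC gene models
with a ``gene_kind`` attribute marking each gene's biosynthetic role, and
FASTA carries peptide/nucleotide sequences.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .gcf_clustering import ClusterAssignment, FeatureMatrix
from .metagenome_quant import BGCGeneModel, Gene, ReadCountTable

__all__ = [
    "write_feature_tsv",
    "read_feature_tsv",
    "write_gene_models_gff3",
    "read_gene_models_gff3",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_fasta",
    "read_fasta",
    "write_assignment_tsv",
    "read_assignment_tsv",
    "read_taxonomy_tsv",
]


# --- feature matrices ------------------------------------------------------

def write_feature_tsv(path: str | Path, features: FeatureMatrix) -> None:
    frame = features.to_frame()
    frame.index.name = "bgc_id"
    frame.to_csv(path, sep="\t")


def read_feature_tsv(path: str | Path) -> FeatureMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return FeatureMatrix.from_frame(frame)


# --- gene models (GFF3 with gene_kind attribute) ---------------------------

def write_gene_models_gff3(path: str | Path, models: Sequence[BGCGeneModel]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for model in models:
            start = 1
            for gene in model.genes:
                end = start + gene.length - 1
                attrs = f"ID={gene.gene_id};gene_kind={gene.kind}"
                fh.write(
                    "\t".join(
                        [
                            model.bgc_id, "labbgc", "CDS",
                            str(start), str(end), ".", "+", "0", attrs,
                        ]
                    )
                    + "\n"
                )
                start = end + 1


def read_gene_models_gff3(path: str | Path) -> list[BGCGeneModel]:
    by_bgc: dict[str, list[Gene]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            seqid, _, _, start, end, _, _, _, attrs = fields
            attr_map = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if "ID" not in attr_map or "gene_kind" not in attr_map:
                raise ValueError(f"GFF3 record lacks ID or gene_kind: {line!r}")
            length = int(end) - int(start) + 1
            by_bgc.setdefault(seqid, []).append(
                Gene(attr_map["ID"], length, attr_map["gene_kind"])
            )
    return [BGCGeneModel(bgc, genes) for bgc, genes in by_bgc.items()]


# --- read counts (long format) + sample metadata ---------------------------

def write_counts_tsv(
    counts_path: str | Path, samples_path: str | Path, table: ReadCountTable
) -> None:
    long = (
        table.counts.stack()
        .rename("count")
        .rename_axis(["sample_id", "gene_id"])
        .reset_index()
    )
    long.to_csv(counts_path, sep="\t", index=False)
    meta = pd.DataFrame(
        {
            "sample_id": table.samples,
            "site": (
                table.sites.reindex(table.samples)
                if table.sites is not None
                else ["unknown"] * len(table.samples)
            ),
            "N": table.library_sizes.reindex(table.samples).astype(int),
        }
    )
    meta.to_csv(samples_path, sep="\t", index=False)


def read_counts_tsv(
    counts_path: str | Path, samples_path: str | Path
) -> ReadCountTable:
    long = pd.read_csv(counts_path, sep="\t")
    meta = pd.read_csv(samples_path, sep="\t").set_index("sample_id")
    wide = long.pivot(index="sample_id", columns="gene_id", values="count").fillna(0)
    wide = wide.reindex(meta.index)
    return ReadCountTable(
        counts=wide,
        library_sizes=meta["N"],
        sites=meta["site"] if "site" in meta.columns else None,
    )


# --- sequences -------------------------------------------------------------

def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# --- cluster assignments and taxonomy --------------------------------------

def write_assignment_tsv(
    path: str | Path,
    assignment: ClusterAssignment,
    ref_distance: pd.Series | None = None,
) -> None:
    frame = assignment.to_frame()
    if ref_distance is not None:
        frame["min_ref_distance"] = ref_distance.reindex(frame.index)
    frame.to_csv(path, sep="\t")


def read_assignment_tsv(path: str | Path) -> ClusterAssignment:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    return ClusterAssignment(
        bgc_ids=list(frame.index.astype(str)),
        gcf=frame["gcf_id"].to_numpy(),
        gcc=frame["gcc_id"].to_numpy(),
    )


def read_taxonomy_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t").set_index("genome_id")
    for col in ("genus", "species"):
        if col not in frame.columns:
            raise ValueError(f"taxonomy table lacks column {col!r}")
        if frame[col].isna().any() or (frame[col].astype(str) == "").any():
            raise ValueError(f"taxonomy column {col!r} has empty labels")
    return frame
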