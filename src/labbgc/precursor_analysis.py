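"""Mining class II bacteriocin precursor peptides: merging detector hits,
length filtering, identity clustering, known-bacteriocin matching and
abundance quantification.

Class II bacteriocins are small unmodified ribosomal antimicrobial peptides.
Candidate precursors come from two independent detectors (a profile-HMM domain
search and a dedicated bacteriocin miner); their hit sets are unioned,
sequences longer than 150 amino acids are discarded, and the survivors are
grouped into clusters by greedy incremental clustering at 50% identity
(cd-hit-style: longest sequence founds a cluster and recruits members).
Clusters are screened against curated known bacteriocins with local alignments
(identity > 90%, query coverage > 95%), and per-sample abundances follow::

    precursor abundance = N_i / (L_i * N) * 1e6

with N_i mapped reads on the precursor gene of length L_i (bp) and N the
sample library size; a cluster's abundance is the sum over its members.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "PrecursorRecord",
    "PrecursorCluster",
    "AlignmentConfig",
    "merge_filter_precursors",
    "global_identity",
    "pairwise_stats",
    "greedy_cluster",
    "match_known",
    "precursor_abundance",
    "cluster_abundance",
]

MAX_PRECURSOR_LENGTH = 150
CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class PrecursorRecord:
    """One putative class II bacteriocin precursor peptide."""

    precursor_id: str
    sequence: str | None = None
    length: int | None = None  # aa; inferred from sequence when present
    gene_length: int | None = None  # nt, for read-count quantification
    detector_a: bool = False
    detector_b: bool = False
    bgc_id: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            object.__setattr__(self, "length", len(self.sequence))
        if self.length is None:
            raise ValueError(f"{self.precursor_id}: need a sequence or a length")


@dataclass
class PrecursorCluster:
    """A precursor cluster: founding (longest) member is the representative."""

    cluster_id: int
    representative: str
    members: list[str]
    known_homolog: str | None = None


@dataclass(frozen=True)
class AlignmentConfig:
    """Scoring for peptide alignments: BLOSUM62, gap open 10, extend 0.5,
    end gaps penalized in global mode."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5

    def aligner(self, mode: str) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = mode
        aligner.substitution_matrix = substitution_matrices.load(self.matrix)
        aligner.open_gap_score = -self.gap_open
        aligner.extend_gap_score = -self.gap_extend
        return aligner


DEFAULT_SCORING = AlignmentConfig()


def _check_peptide(seq: str, name: str = "sequence") -> str:
    if not seq:
        raise ValueError(f"{name} is empty")
    bad = set(seq.upper()) - CANONICAL_AA
    if bad:
        raise ValueError(f"{name} contains non-amino-acid characters: {sorted(bad)}")
    return seq.upper()


def merge_filter_precursors(
    hits_a: Iterable[str],
    hits_b: Iterable[str],
    lengths: Mapping[str, int],
    max_len: int = MAX_PRECURSOR_LENGTH,
    sequences: Mapping[str, str] | None = None,
) -> list[PrecursorRecord]:
    """Union of the two detector hit sets minus sequences longer than ``max_len``.

    Detector provenance is preserved on every record.  The retained count is
    |A| + |B| - |A ∩ B| - n_oversize.
    """
    set_a, set_b = set(hits_a), set(hits_b)
    union = set_a | set_b
    missing = [h for h in union if h not in lengths]
    if missing:
        raise KeyError(f"hit ids without a length: {sorted(missing)[:5]}")
    records = []
    for hid in sorted(union):
        if lengths[hid] > max_len:
            continue
        seq = sequences.get(hid) if sequences else None
        records.append(
            PrecursorRecord(
                precursor_id=hid,
                sequence=seq,
                length=lengths[hid] if seq is None else None,
                detector_a=hid in set_a,
                detector_b=hid in set_b,
            )
        )
    return records


def global_identity(
    a: str, b: str, scoring: AlignmentConfig = DEFAULT_SCORING
) -> float:
    """Needleman-Wunsch percent identity: identical positions / alignment length."""
    a = _check_peptide(a, "first sequence")
    b = _check_peptide(b, "second sequence")
    alignment = scoring.aligner("global").align(a, b)[0]
    return 100.0 * alignment.counts().identities / alignment.length


def pairwise_stats(
    a: str, b: str, scoring: AlignmentConfig = DEFAULT_SCORING
) -> tuple[float, float]:
    """(identity over the shorter sequence, aligned fraction of the longer sequence)
    from one global alignment — the clustering criteria."""
    alignment = scoring.aligner("global").align(a.upper(), b.upper())[0]
    counts = alignment.counts()
    aligned_pairs = counts.identities + counts.mismatches
    return (
        counts.identities / min(len(a), len(b)),
        aligned_pairs / max(len(a), len(b)),
    )


def greedy_cluster(
    records: Sequence[PrecursorRecord],
    identity: float = 0.5,
    length_ratio: float = 0.95,
    cov_long: float = 0.95,
    scoring: AlignmentConfig = DEFAULT_SCORING,
) -> tuple[list[PrecursorCluster], dict[str, int]]:
    """Greedy incremental clustering of precursor peptides, longest first.

    Each sequence joins the best existing representative satisfying all of:
    identity >= ``identity`` (identical positions / shorter-sequence length,
    from a global alignment), shorter/longer length ratio >= ``length_ratio``,
    and alignment covering >= ``cov_long`` of the longer sequence; otherwise it
    founds a new cluster.  "Best" = highest identity, ties resolved toward the
    longer representative.  Returns clusters plus a member -> cluster_id map.
    """
    seqs = {}
    for r in records:
        if r.sequence is None:
            raise ValueError(f"{r.precursor_id}: clustering needs sequences")
        seqs[r.precursor_id] = _check_peptide(r.sequence, r.precursor_id)
    order = sorted(seqs, key=lambda i: (-len(seqs[i]), i))
    clusters: list[PrecursorCluster] = []
    assignment: dict[str, int] = {}
    for pid in order:
        seq = seqs[pid]
        best_idx, best_key = None, None
        for idx, cl in enumerate(clusters):
            rep_seq = seqs[cl.representative]
            if min(len(seq), len(rep_seq)) / max(len(seq), len(rep_seq)) < length_ratio:
                continue
            ident, cov = pairwise_stats(seq, rep_seq, scoring)
            if ident >= identity and cov >= cov_long:
                key = (ident, len(rep_seq), -idx)
                if best_key is None or key > best_key:
                    best_idx, best_key = idx, key
        if best_idx is None:
            assignment[pid] = len(clusters)
            clusters.append(PrecursorCluster(len(clusters), pid, [pid]))
        else:
            clusters[best_idx].members.append(pid)
            assignment[pid] = best_idx
    return clusters, assignment


def match_known(
    clusters: Sequence[PrecursorCluster],
    sequences: Mapping[str, str],
    known: Mapping[str, str],
    min_id: float = 0.90,
    min_cov: float = 0.95,
    scoring: AlignmentConfig = DEFAULT_SCORING,
) -> dict[str, object]:
    """Label clusters containing a homolog of a known class II bacteriocin.

    Each known bacteriocin (the query) is locally aligned (Smith-Waterman)
    against every member sequence; a member is homologous when identity over
    the aligned columns exceeds ``min_id`` and the aligned fraction of the
    query exceeds ``min_cov``.  A cluster is known-like when >= 1 member is
    homologous; its ``known_homolog`` is set to the best-identity known id.
    Returns summary counts alongside the per-member hit list.
    """
    if not known:
        raise ValueError("known bacteriocin set is empty")
    aligner = scoring.aligner("local")
    known_clean = {k: _check_peptide(v, k) for k, v in known.items()}
    hits = []  # (member, known_id, identity, coverage)
    homologous_members: set[str] = set()
    for cl in clusters:
        best: tuple[float, str] | None = None
        for member in cl.members:
            seq = _check_peptide(sequences[member], member)
            for kid, kseq in known_clean.items():
                alignments = aligner.align(kseq, seq)
                if len(alignments) == 0:
                    continue
                alignment = alignments[0]
                counts = alignment.counts()
                aligned_cols = counts.identities + counts.mismatches
                if aligned_cols == 0:
                    continue
                ident = counts.identities / alignment.length
                cov = aligned_cols / len(kseq)
                if ident > min_id and cov > min_cov:
                    hits.append((member, kid, ident, cov))
                    homologous_members.add(member)
                    if best is None or ident > best[0]:
                        best = (ident, kid)
        cl.known_homolog = best[1] if best else None
    known_like = [cl for cl in clusters if cl.known_homolog is not None]
    return {
        "hits": pd.DataFrame(
            hits, columns=["precursor_id", "known_id", "identity", "coverage"]
        ),
        "n_homologous_sequences": len(homologous_members),
        "n_known_like_clusters": len(known_like),
    }


def precursor_abundance(
    gene_counts: Mapping[str, int],
    gene_lengths: Mapping[str, int],
    library_size: float,
) -> pd.Series:
    """Per-precursor abundance in one sample: N_i / (L_i * N) * 1e6."""
    if library_size <= 0:
        raise ValueError("library size N must be positive")
    values = {}
    for gene_id, length in gene_lengths.items():
        if length <= 0:
            raise ValueError(f"gene {gene_id}: length must be positive")
        values[gene_id] = gene_counts.get(gene_id, 0) / (length * library_size) * 1e6
    return pd.Series(values, name="abundance")


def cluster_abundance(
    counts: pd.DataFrame,
    library_sizes: pd.Series,
    gene_lengths: Mapping[str, int],
    cluster_of: Mapping[str, int],
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Sample x precursor and sample x cluster abundance, plus cluster prevalence.

    ``counts`` is a wide sample x precursor-gene read-count frame.  A cluster's
    abundance in a sample is the sum of its member precursors' abundances;
    prevalence is the fraction of samples where that sum is positive.
    """
    per_precursor = pd.DataFrame(
        {
            s: precursor_abundance(
                counts.loc[s].to_dict(), gene_lengths, float(library_sizes.loc[s])
            )
            for s in counts.index
        }
    ).T
    per_precursor.index.name = "sample_id"
    groups = pd.Index([cluster_of[p] for p in per_precursor.columns])
    per_cluster = per_precursor.T.groupby(groups).sum().T
    per_cluster.index.name = "sample_id"
    prevalence = (per_cluster > 0).mean(axis=0).rename("prevalence")
    return per_precursor, per_cluster, prevalence
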