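"""Quantifying BGC presence and abundance in metagenome / metatranscriptome samples.

Per-gene mapped-read counts (produced upstream by read mapping) are combined
with BGC gene models carrying a ``gene_kind`` role per gene.  Only
biosynthetic-related genes — the core biosynthetic and additional biosynthetic
genes — enter the calculations; transporters, regulators and other accessory
genes are ignored.

A BGC is called *present* in a sample when strictly more than half of its
biosynthetic-related genes are detected (mapped-read count >= 1) and at least
one core biosynthetic gene is detected.  Its abundance is a length- and
depth-normalized rate::

    abundance = ( sum_i N_i / L_i ) / (k * N) * 1e6

over the k biosynthetic-related genes, with N_i mapped reads on gene i of
length L_i (bp) and N the sample's total high-quality non-host read count.
The same machinery applies unchanged to metatranscriptome samples (N then
counts non-rRNA, non-host reads).

Before quantification, BGC nucleotide sequences are dereplicated within each
gene cluster family at a 0.8 global nucleotide identity threshold so that
near-identical cluster copies do not split the read signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .gcf_clustering import ClusterAssignment

__all__ = [
    "Gene",
    "BGCGeneModel",
    "ReadCountTable",
    "UncallableBGCError",
    "DereplicationResult",
    "nucleotide_identity",
    "dereplicate_bgcs",
    "bgc_presence",
    "presence_matrix",
    "bgc_abundance",
    "abundance_matrix",
    "accumulation_curve",
    "niche_specificity",
    "niche_taxa_crosstab",
]

GENE_KINDS = ("biosynthetic", "biosynthetic-additional", "other")
ABUNDANCE_SCALE = 1e6


class UncallableBGCError(ValueError):
    """A BGC without core biosynthetic genes cannot be presence-called."""


@dataclass(frozen=True)
class Gene:
    gene_id: str
    length: int  # bp
    kind: str  # one of GENE_KINDS

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"gene {self.gene_id}: length must be positive")
        if self.kind not in GENE_KINDS:
            raise ValueError(f"gene {self.gene_id}: unknown gene_kind {self.kind!r}")


@dataclass
class BGCGeneModel:
    """Ordered genes of one BGC with lengths (bp) and biosynthetic roles."""

    bgc_id: str
    genes: list[Gene]

    @property
    def core_genes(self) -> list[Gene]:
        return [g for g in self.genes if g.kind == "biosynthetic"]

    @property
    def biosynthetic_related(self) -> list[Gene]:
        """Core + additional biosynthetic genes — the quantification substrate."""
        return [
            g for g in self.genes
            if g.kind in ("biosynthetic", "biosynthetic-additional")
        ]

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


@dataclass
class ReadCountTable:
    """Per-sample per-gene mapped-read counts plus per-sample library size N.

    ``counts`` is a wide integer frame (rows = samples, columns = genes);
    ``library_sizes`` holds each sample's total high-quality non-host read
    count N; ``sites`` optionally labels each sample's body site.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series
    sites: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(int)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("read counts must be nonnegative")
        self.library_sizes = self.library_sizes.reindex(self.counts.index)
        if self.library_sizes.isna().any():
            raise ValueError("every sample needs a library size N")
        if (self.library_sizes < 0).any():
            raise ValueError("library sizes must be nonnegative")
        if self.sites is not None:
            self.sites = self.sites.reindex(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)


# ---------------------------------------------------------------------------
# Within-GCF dereplication
# ---------------------------------------------------------------------------

def _nt_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -2
    return aligner


def nucleotide_identity(a: str, b: str) -> float:
    """Global nucleotide identity: aligned matches / length of the shorter sequence."""
    if not a or not b:
        raise ValueError("empty nucleotide sequence")
    alignment = _nt_aligner().align(a.upper(), b.upper())[0]
    identities = alignment.counts().identities
    return identities / min(len(a), len(b))


@dataclass
class DereplicationResult:
    representatives: list[str]
    member_to_rep: dict[str, str]

    def members_of(self, rep: str) -> list[str]:
        return [m for m, r in self.member_to_rep.items() if r == rep]


def dereplicate_bgcs(
    sequences: Mapping[str, str],
    assignment: ClusterAssignment,
    id_threshold: float = 0.8,
) -> DereplicationResult:
    """Greedy longest-first dereplication of BGC nucleotide sequences within each GCF.

    Sequences are visited longest-first within their family.  A sequence joins
    the existing representative with the highest global nucleotide identity
    (relative to the shorter sequence) if that identity is >= ``id_threshold``,
    otherwise it founds a new representative.  Identical sequences in
    different families stay separate: dereplication is within-family only.
    """
    gcf_of = assignment.gcf_of
    missing = [s for s in sequences if s not in gcf_of]
    if missing:
        raise KeyError(f"sequences absent from the cluster assignment: {missing[:5]}")
    by_gcf: dict[int, list[str]] = {}
    for bgc in sequences:
        by_gcf.setdefault(gcf_of[bgc], []).append(bgc)

    representatives: list[str] = []
    member_to_rep: dict[str, str] = {}
    for gcf_id in sorted(by_gcf):
        members = sorted(by_gcf[gcf_id], key=lambda b: (-len(sequences[b]), b))
        reps: list[str] = []
        for bgc in members:
            best, best_identity = None, -1.0
            for rep in reps:
                ident = nucleotide_identity(sequences[bgc], sequences[rep])
                if ident > best_identity:
                    best, best_identity = rep, ident
            if best is not None and best_identity >= id_threshold:
                member_to_rep[bgc] = best
            else:
                reps.append(bgc)
                member_to_rep[bgc] = bgc
        representatives.extend(reps)
    return DereplicationResult(representatives, member_to_rep)


# ---------------------------------------------------------------------------
# Presence calling and abundance
# ---------------------------------------------------------------------------

def bgc_presence(gene_counts: Mapping[str, int], model: BGCGeneModel) -> bool:
    """Presence call for one BGC in one sample.

    Present iff (detected biosynthetic-related genes) / (total
    biosynthetic-related genes) > 0.5 AND >= 1 core biosynthetic gene is
    detected, where a gene is detected when its mapped-read count is >= 1.
    ``other`` genes never enter the criterion.
    """
    related = model.biosynthetic_related
    if not related:
        raise ValueError(f"BGC {model.bgc_id} has no biosynthetic-related genes")
    if not model.core_genes:
        raise UncallableBGCError(
            f"BGC {model.bgc_id} has no core biosynthetic gene; presence is uncallable"
        )
    detected = sum(1 for g in related if gene_counts.get(g.gene_id, 0) >= 1)
    core_found = any(gene_counts.get(g.gene_id, 0) >= 1 for g in model.core_genes)
    return detected / len(related) > 0.5 and core_found


def presence_matrix(
    counts: ReadCountTable, models: Sequence[BGCGeneModel]
) -> tuple[pd.DataFrame, list[str]]:
    """Boolean sample x BGC presence matrix; BGCs without core genes are
    reported separately as uncallable (columns of <NA>), never silently absent."""
    data: dict[str, object] = {}
    uncallable: list[str] = []
    for model in models:
        try:
            col = [
                bgc_presence(counts.counts.loc[s].to_dict(), model)
                for s in counts.samples
            ]
            data[model.bgc_id] = pd.array(col, dtype="boolean")
        except UncallableBGCError:
            uncallable.append(model.bgc_id)
            data[model.bgc_id] = pd.array([pd.NA] * len(counts.samples), dtype="boolean")
    frame = pd.DataFrame(data, index=pd.Index(counts.samples, name="sample_id"))
    return frame, uncallable


def bgc_abundance(
    gene_counts: Mapping[str, int], library_size: float, model: BGCGeneModel
) -> float:
    """Length- and depth-normalized BGC abundance in one sample.

    abundance = [ sum_{i=1..k} N_i / L_i ] / (k * N) * 1e6, summing only over
    the k biosynthetic-related genes.
    """
    if library_size <= 0:
        raise ValueError(f"BGC {model.bgc_id}: library size N must be positive")
    related = model.biosynthetic_related
    if not related:
        raise ValueError(f"BGC {model.bgc_id} has no biosynthetic-related genes")
    total = 0.0
    for g in related:
        if g.gene_id not in gene_counts:
            raise KeyError(f"gene {g.gene_id} missing from the read-count table")
        total += gene_counts[g.gene_id] / g.length
    return total / (len(related) * library_size) * ABUNDANCE_SCALE


def abundance_matrix(
    counts: ReadCountTable,
    models: Sequence[BGCGeneModel],
    presence_mask: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sample x BGC abundance frame; optionally zeroed where presence is not called."""
    cols = {}
    for model in models:
        cols[model.bgc_id] = [
            bgc_abundance(
                counts.counts.loc[s].to_dict(),
                float(counts.library_sizes.loc[s]),
                model,
            )
            for s in counts.samples
        ]
    frame = pd.DataFrame(cols, index=pd.Index(counts.samples, name="sample_id"))
    if presence_mask is not None:
        mask = presence_mask.reindex(index=frame.index, columns=frame.columns)
        frame = frame.where(mask.fillna(False).astype(bool), 0.0)
    return frame


# ---------------------------------------------------------------------------
# Diversity summaries
# ---------------------------------------------------------------------------

def _to_gcf_presence(
    presence: pd.DataFrame, bgc_to_gcf: Mapping[str, int] | None
) -> pd.DataFrame:
    pres = presence.fillna(False).astype(bool)
    if bgc_to_gcf is None:
        return pres
    cols = pd.Index([bgc_to_gcf[b] for b in pres.columns])
    return pres.T.groupby(cols).any().T


def accumulation_curve(
    presence: pd.DataFrame,
    sites: pd.Series,
    bgc_to_gcf: Mapping[str, int] | None = None,
    n_permutations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean (+/- sd) cumulative distinct-GCF count versus number of samples, per site.

    For each of ``n_permutations`` random sample orders the running count of
    distinct detected GCFs is accumulated; the curve is non-decreasing and its
    final value equals the total number of distinct GCFs detected in the site
    for every permutation.
    """
    pres = _to_gcf_presence(presence, bgc_to_gcf)
    sites = sites.reindex(pres.index)
    rng = np.random.default_rng(seed)
    rows = []
    for site in sites.dropna().unique():
        sub = pres.loc[sites == site].to_numpy(bool)
        m = sub.shape[0]
        curves = np.empty((n_permutations, m), dtype=int)
        for p in range(n_permutations):
            order = rng.permutation(m)
            seen = np.logical_or.accumulate(sub[order], axis=0)
            curves[p] = seen.sum(axis=1)
        for j in range(m):
            rows.append(
                {
                    "site": site,
                    "n_samples": j + 1,
                    "mean_gcfs": float(curves[:, j].mean()),
                    "sd_gcfs": float(curves[:, j].std(ddof=1)) if n_permutations > 1 else 0.0,
                }
            )
    return pd.DataFrame(rows)


def niche_specificity(
    presence: pd.DataFrame,
    sites: pd.Series,
    bgc_to_gcf: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Number of body sites in which each GCF is detected; niche-specific = exactly one."""
    pres = _to_gcf_presence(presence, bgc_to_gcf)
    sites = sites.reindex(pres.index)
    per_site = pres.groupby(sites).any()
    n_sites = per_site.sum(axis=0).astype(int)
    detected = n_sites > 0
    out = pd.DataFrame(
        {
            "n_sites": n_sites,
            "detected": detected,
            "niche_specific": n_sites == 1,
        }
    )
    out.index.name = "gcf_id"
    return out


def niche_taxa_crosstab(
    niche_specific: pd.Series, taxa_specific: pd.Series
) -> np.ndarray:
    """2x2 table (niche-specific vs cross-niche) x (taxa-specific vs cross-taxa)
    over GCFs present in both series, ready for a chi-squared test."""
    idx = niche_specific.index.intersection(taxa_specific.index)
    a = niche_specific.loc[idx].astype(bool)
    b = taxa_specific.loc[idx].astype(bool)
    return np.array(
        [
            [int((a & b).sum()), int((a & ~b).sum())],
            [int((~a & b).sum()), int((~a & ~b).sum())],
        ]
    )
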