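"""Synthetic inputs with planted ground truth for every pipeline stage.

The real pipeline consumes downstream representations of large external
datasets: BGC biosynthetic-domain feature vectors, gene models with
biosynthetic roles, per-sample read counts, precursor peptides, detector hit
lists, and species relative-abundance profiles.  This module emulates each of
them with known planted structure — family prototypes with controlled
within-family noise, presence patterns with Poisson read counts proportional
to gene length, mutation-derived precursor clusters, and negative
cluster-species associations — so that clustering, presence calling,
precursor clustering and the correlation screen can all be validated against
truth without external downloads.

Every generator is a pure function of its configuration (including the seed):
the same config yields byte-identical outputs.  Sub-generators derive child
seeds deterministically from the one global seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .gcf_clustering import FeatureMatrix
from .metagenome_quant import BGCGeneModel, Gene, ReadCountTable
from .precursor_analysis import PrecursorRecord

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "DetectorHits",
    "EASY",
    "HARD",
    "gen_bgc_features",
    "gen_gene_models",
    "gen_metagenome_counts",
    "gen_precursors",
    "gen_detector_hits",
    "gen_community",
]

AMINO_ACIDS = np.array(list("ACDEFGHIKLMNPQRSTVWY"))

# fixed child-stream indices so each generator sees an independent stream
_STREAM = {
    "features": 0,
    "gene_models": 1,
    "counts": 2,
    "precursors": 3,
    "community": 5,
}


@dataclass(frozen=True)
class GeneratorConfig:
    """One knob set for all generators.

    ``within_family_noise`` is the fraction of feature-vector entries
    perturbed per BGC; ``mutation_rate`` the per-residue substitution
    probability within a precursor cluster; ``read_depth`` the expected
    mapped reads per kilobase of gene at unit abundance.
    """

    seed: int = 0
    n_families: int = 8
    bgcs_per_family: int = 6
    n_domains: int = 120
    within_family_noise: float = 0.05
    n_samples: int = 80
    n_species: int = 8
    read_depth: int = 30
    mutation_rate: float = 0.05
    n_precursor_clusters: int = 8
    precursors_per_cluster: int = 6
    n_planted_edges: int = 3
    community_noise: float = 0.15
    presence_prob: float = 0.5
    n_sites: int = 3

    def __post_init__(self) -> None:
        for name in (
            "n_families", "bgcs_per_family", "n_domains", "n_samples",
            "n_species", "read_depth", "n_precursor_clusters",
            "precursors_per_cluster",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not 0 <= self.within_family_noise <= 1:
            raise ValueError("within_family_noise must lie in [0, 1]")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.seed, spawn_key=(_STREAM[stream],))
        )


# "easy" is the default validation regime: well-separated families, shallow
# within-cluster mutation, comfortable sequencing depth.  "hard" stresses the
# same stages near their breaking points and carries no recovery guarantee.
EASY = GeneratorConfig()
HARD = GeneratorConfig(
    within_family_noise=0.35,
    mutation_rate=0.2,
    read_depth=4,
    community_noise=0.6,
)


@dataclass
class SyntheticTruth:
    """Planted ground truth; each generator fills its own slice.

    Labels are dense integers starting at 0; every generated entity appears in
    exactly one truth map.
    """

    family_labels: dict[str, int] = field(default_factory=dict)
    presence_truth: pd.DataFrame | None = None
    cluster_labels: dict[str, int] = field(default_factory=dict)
    planted_edges: list[tuple[str, str, int]] = field(default_factory=list)

    def merge(self, other: "SyntheticTruth") -> "SyntheticTruth":
        return SyntheticTruth(
            family_labels={**self.family_labels, **other.family_labels},
            presence_truth=(
                other.presence_truth
                if other.presence_truth is not None
                else self.presence_truth
            ),
            cluster_labels={**self.cluster_labels, **other.cluster_labels},
            planted_edges=self.planted_edges + other.planted_edges,
        )


def gen_bgc_features(cfg: GeneratorConfig) -> tuple[FeatureMatrix, SyntheticTruth]:
    """Feature vectors with planted family structure.

    Each family owns a disjoint block of domains carrying a positive
    prototype; members copy the prototype and have a fraction
    ``within_family_noise`` of their entries replaced by random nonnegative
    values.  Noise >= 0.5 would destroy family separability and is rejected.
    """
    if cfg.within_family_noise >= 0.5:
        raise ValueError(
            "within_family_noise >= 0.5: planted families would not be separable"
        )
    if cfg.n_domains < cfg.n_families:
        raise ValueError("need at least one domain per family")
    rng = cfg.rng("features")
    block = cfg.n_domains // cfg.n_families
    prototypes = np.zeros((cfg.n_families, cfg.n_domains))
    for f in range(cfg.n_families):
        prototypes[f, f * block : (f + 1) * block] = rng.uniform(0.5, 1.5, block)

    n_perturb = int(round(cfg.within_family_noise * cfg.n_domains))
    rows, family_labels = [], {}
    for f in range(cfg.n_families):
        # noise perturbs domains outside the family's own prototype block:
        # it models variable accessory domain content between family members,
        # while the class-defining biosynthetic domains stay conserved
        background = np.setdiff1d(
            np.arange(cfg.n_domains), np.arange(f * block, (f + 1) * block)
        )
        for _ in range(cfg.bgcs_per_family):
            vec = prototypes[f].copy()
            k = min(n_perturb, len(background))
            if k:
                pos = rng.choice(background, size=k, replace=False)
                # weights well below the prototype scale so a sub-0.5
                # perturbed fraction keeps families cosine-separable
                vec[pos] = rng.uniform(0.05, 0.25, k)
            rows.append(vec)
            family_labels[f"bgc_{len(rows) - 1:05d}"] = f
    matrix = FeatureMatrix.from_dense(np.vstack(rows))
    assert not matrix.featureless_ids(), "generator produced an all-zero row"
    return matrix, SyntheticTruth(family_labels=family_labels)


def gen_gene_models(
    cfg: GeneratorConfig, bgc_ids: Sequence[str]
) -> list[BGCGeneModel]:
    """A gene model per BGC: 1-2 core biosynthetic genes, a few additional
    biosynthetic genes, and accessory ``other`` genes, lengths 500-3000 bp."""
    rng = cfg.rng("gene_models")
    models = []
    for bgc in bgc_ids:
        n_core = int(rng.integers(1, 3))
        n_additional = int(rng.integers(2, 5))
        n_other = int(rng.integers(1, 4))
        kinds = (
            ["biosynthetic"] * n_core
            + ["biosynthetic-additional"] * n_additional
            + ["other"] * n_other
        )
        genes = [
            Gene(f"{bgc}_g{i:02d}", int(rng.integers(500, 3001)), kind)
            for i, kind in enumerate(kinds)
        ]
        models.append(BGCGeneModel(bgc, genes))
    return models


def gen_metagenome_counts(
    cfg: GeneratorConfig, gene_models: Sequence[BGCGeneModel]
) -> tuple[ReadCountTable, SyntheticTruth]:
    """Per-sample per-gene Poisson read counts with planted presence.

    Each (sample, BGC) pair is present with probability ``presence_prob``.
    When present, every gene of the BGC receives a Poisson count with mean
    ``read_depth * a * L/1000`` where ``a`` is a per-(sample, BGC) lognormal
    abundance factor — proportional to gene length, so the length-normalized
    abundance estimator is exact in expectation.  Absent pairs emit all-zero
    rows.  The library size N is drawn first (scaled to dominate the emitted
    counts) and reported with the table.
    """
    if not gene_models:
        raise ValueError("need at least one gene model")
    if cfg.read_depth <= 0:
        raise ValueError("read_depth must be positive")
    rng = cfg.rng("counts")
    samples = [f"sample_{i:04d}" for i in range(cfg.n_samples)]
    sites = pd.Series(
        [f"site_{i % cfg.n_sites}" for i in range(cfg.n_samples)],
        index=samples, name="site",
    )
    gene_ids = [g.gene_id for m in gene_models for g in m.genes]
    expected_total = sum(
        cfg.read_depth * g.length / 1000 for m in gene_models for g in m.genes
    )
    # library size drawn before the counts; an order of magnitude above the
    # expected emitted total so N >= sum(counts) in practice
    n_draw = rng.poisson(10 * expected_total, size=cfg.n_samples) + 1

    presence = rng.random((cfg.n_samples, len(gene_models))) < cfg.presence_prob
    counts = np.zeros((cfg.n_samples, len(gene_ids)), dtype=int)
    col = 0
    for j, model in enumerate(gene_models):
        k = len(model.genes)
        factors = np.exp(rng.normal(0.0, 0.3, size=cfg.n_samples))
        lengths = np.array([g.length for g in model.genes])
        mean = cfg.read_depth * np.outer(factors, lengths / 1000.0)
        drawn = rng.poisson(mean)
        drawn[~presence[:, j]] = 0
        counts[:, col : col + k] = drawn
        col += k
    library = np.maximum(n_draw, counts.sum(axis=1))
    table = ReadCountTable(
        counts=pd.DataFrame(counts, index=samples, columns=gene_ids),
        library_sizes=pd.Series(library, index=samples, name="N"),
        sites=sites,
    )
    truth = SyntheticTruth(
        presence_truth=pd.DataFrame(
            presence, index=samples, columns=[m.bgc_id for m in gene_models]
        )
    )
    return table, truth


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    for i in np.flatnonzero(hit):
        choices = AMINO_ACIDS[AMINO_ACIDS != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return out


def gen_precursors(cfg: GeneratorConfig) -> tuple[list[PrecursorRecord], SyntheticTruth]:
    """Precursor peptides in planted clusters derived from random seed peptides.

    Each cluster derives from one random seed of length 30-100 aa; members are
    copies with independent per-position substitutions at ``mutation_rate``
    (uniform over the 19 other residues), so member identity to the seed is
    (1 - rate) in expectation while unrelated clusters sit near random-match
    identity.  Each record carries detector provenance (A, B, or both).
    """
    if cfg.mutation_rate >= 0.25:
        raise ValueError("mutation_rate must be < 0.25 to keep clusters recoverable")
    rng = cfg.rng("precursors")
    records, labels = [], {}
    for c in range(cfg.n_precursor_clusters):
        length = int(rng.integers(30, 101))
        seed_seq = AMINO_ACIDS[rng.integers(len(AMINO_ACIDS), size=length)]
        for m in range(cfg.precursors_per_cluster):
            seq = _mutate(seed_seq, cfg.mutation_rate, rng)
            provenance = rng.integers(3)  # 0: A only, 1: B only, 2: both
            pid = f"prec_{len(records):05d}"
            records.append(
                PrecursorRecord(
                    precursor_id=pid,
                    sequence="".join(seq),
                    gene_length=3 * (length + 1),
                    detector_a=provenance in (0, 2),
                    detector_b=provenance in (1, 2),
                    bgc_id=f"bgc_{c:05d}",
                )
            )
            labels[pid] = c
    return records, SyntheticTruth(cluster_labels=labels)


@dataclass
class DetectorHits:
    """Two detector hit-id sets with per-id lengths and oversize flags."""

    hits_a: set[str]
    hits_b: set[str]
    lengths: dict[str, int]
    oversize: set[str]

    @property
    def union(self) -> set[str]:
        return self.hits_a | self.hits_b


def gen_detector_hits(
    size_a: int, size_b: int, overlap: int, n_oversize: int, seed: int = 0
) -> DetectorHits:
    """Hit-id sets of prescribed sizes, overlap, and oversize (> 150 aa) count.

    |A| = size_a, |B| = size_b, |A ∩ B| = overlap; exactly ``n_oversize``
    union members get lengths above 150 aa, the rest at most 150 aa.
    """
    if overlap > min(size_a, size_b):
        raise ValueError("overlap cannot exceed the smaller hit set")
    if min(size_a, size_b, overlap, n_oversize) < 0:
        raise ValueError("sizes must be nonnegative")
    n_union = size_a + size_b - overlap
    if n_oversize > n_union:
        raise ValueError("more oversize members than union members")
    rng = np.random.default_rng(seed)
    ids = [f"prec_{i:06d}" for i in range(n_union)]
    hits_a = set(ids[:size_a])
    hits_b = set(ids[size_a - overlap :])
    oversize_idx = rng.choice(n_union, size=n_oversize, replace=False)
    oversize = {ids[i] for i in oversize_idx}
    lengths = {}
    for i, hid in enumerate(ids):
        if hid in oversize:
            lengths[hid] = int(rng.integers(151, 301))
        else:
            lengths[hid] = int(rng.integers(20, 151))
    return DetectorHits(hits_a, hits_b, lengths, oversize)


def gen_community(
    cfg: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Species relative-abundance profile plus precursor-cluster abundances
    with planted negative associations.

    Species abundances are lognormal draws normalized per sample.  For each
    planted edge (cluster, species, -) the cluster's abundance is a strictly
    decreasing affine function of the species' abundance plus Gaussian noise
    scaled by ``community_noise`` (noise 0 gives a sample Spearman rho of
    exactly -1).  All other cluster columns are generated independently.
    """
    if cfg.n_samples < 10:
        raise ValueError("need at least 10 samples for the community generator")
    rng = cfg.rng("community")
    samples = [f"sample_{i:04d}" for i in range(cfg.n_samples)]
    species = [f"species_{j:02d}" for j in range(cfg.n_species)]
    clusters = [f"cluster_{c:03d}" for c in range(cfg.n_precursor_clusters)]

    raw = np.exp(rng.normal(0.0, 1.0, size=(cfg.n_samples, cfg.n_species)))
    profile = raw / raw.sum(axis=1, keepdims=True)

    n_edges = min(cfg.n_planted_edges, cfg.n_precursor_clusters, cfg.n_species)
    target_species = rng.choice(cfg.n_species, size=n_edges, replace=False)
    abund = np.exp(rng.normal(0.0, 0.5, size=(cfg.n_samples, cfg.n_precursor_clusters)))
    edges = []
    for c, s in enumerate(target_species):
        x = profile[:, s]
        y = (x.max() + 1e-6) - x  # strictly decreasing in x
        if cfg.community_noise > 0:
            y = y + rng.normal(0.0, cfg.community_noise * x.std(), size=len(y))
            y = np.maximum(y, 0.0)
        abund[:, c] = y
        edges.append((clusters[c], species[s], -1))

    profile_df = pd.DataFrame(profile, index=samples, columns=species)
    abund_df = pd.DataFrame(abund, index=samples, columns=clusters)
    return profile_df, abund_df, SyntheticTruth(planted_edges=edges)
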