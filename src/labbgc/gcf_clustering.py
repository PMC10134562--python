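"""Clustering of BGC feature vectors into gene cluster families (GCFs) and clans (GCCs).

Each biosynthetic gene cluster (BGC) is represented by a nonnegative vector of
biosynthetic-domain weights.  All-to-all cosine distances between these vectors
are clustered hierarchically with average linkage, and the dendrogram is cut at
two thresholds: a fine cut (default 0.2) defining families of BGCs expected to
encode similar products, and a coarse cut (default 0.8) defining clans grouping
families of a common chemical class.  The same tree yields both cuts, so the
family partition always refines the clan partition.

The module also measures the distance of each BGC (and each clan) to a set of
experimentally characterized reference BGCs, flagging clans that resemble known
chemistry, and classifies the taxonomic specificity of each family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist, squareform

__all__ = [
    "FeatureMatrix",
    "ClusterAssignment",
    "ReferenceDistance",
    "cosine_distance_matrix",
    "cluster_gcf_gcc",
    "reference_distance",
    "taxa_specificity",
    "specificity_summary",
]

GCF_THRESHOLD = 0.2
GCC_THRESHOLD = 0.8


@dataclass
class FeatureMatrix:
    """BGC x biosynthetic-domain weight matrix (rows = BGCs, sparse, nonnegative)."""

    bgc_ids: list[str]
    domain_ids: list[str]
    weights: sp.csr_matrix

    def __post_init__(self) -> None:
        self.weights = sp.csr_matrix(self.weights, dtype=float)
        if self.weights.shape != (len(self.bgc_ids), len(self.domain_ids)):
            raise ValueError(
                f"weights shape {self.weights.shape} does not match "
                f"{len(self.bgc_ids)} BGCs x {len(self.domain_ids)} domains"
            )
        if self.weights.nnz and self.weights.data.min() < 0:
            raise ValueError("feature weights must be nonnegative")

    @classmethod
    def from_dense(
        cls,
        weights: np.ndarray,
        bgc_ids: Sequence[str] | None = None,
        domain_ids: Sequence[str] | None = None,
    ) -> "FeatureMatrix":
        weights = np.asarray(weights, dtype=float)
        n, m = weights.shape
        if bgc_ids is None:
            bgc_ids = [f"bgc_{i:05d}" for i in range(n)]
        if domain_ids is None:
            domain_ids = [f"domain_{j:04d}" for j in range(m)]
        return cls(list(bgc_ids), list(domain_ids), sp.csr_matrix(weights))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "FeatureMatrix":
        return cls.from_dense(
            frame.to_numpy(dtype=float),
            bgc_ids=list(frame.index.astype(str)),
            domain_ids=list(frame.columns.astype(str)),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.weights.toarray(), index=self.bgc_ids, columns=self.domain_ids
        )

    @property
    def n_bgcs(self) -> int:
        return len(self.bgc_ids)

    def featureless_ids(self) -> list[str]:
        """BGCs whose feature vector is all-zero (excluded from clustering)."""
        row_sums = np.asarray(self.weights.sum(axis=1)).ravel()
        return [b for b, s in zip(self.bgc_ids, row_sums) if s == 0]

    def drop_featureless(self) -> tuple["FeatureMatrix", list[str]]:
        """Split into (clusterable matrix, featureless BGC ids)."""
        dropped = set(self.featureless_ids())
        if not dropped:
            return self, []
        keep = [i for i, b in enumerate(self.bgc_ids) if b not in dropped]
        kept = FeatureMatrix(
            [self.bgc_ids[i] for i in keep], list(self.domain_ids),
            self.weights[keep],
        )
        return kept, sorted(dropped)


@dataclass
class ClusterAssignment:
    """Per-BGC family (GCF) and clan (GCC) labels from one average-linkage tree.

    Labels are dense integers starting at 0, numbered by first appearance in
    ``bgc_ids`` order.  The GCF partition refines the GCC partition.
    """

    bgc_ids: list[str]
    gcf: np.ndarray
    gcc: np.ndarray
    gcf_threshold: float = GCF_THRESHOLD
    gcc_threshold: float = GCC_THRESHOLD
    linkage_method: str = "average"
    featureless: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.gcf = np.asarray(self.gcf, dtype=int)
        self.gcc = np.asarray(self.gcc, dtype=int)
        if not (len(self.bgc_ids) == len(self.gcf) == len(self.gcc)):
            raise ValueError("bgc_ids, gcf and gcc must have equal length")
        # family partition must refine the clan partition
        for f in np.unique(self.gcf):
            if len(np.unique(self.gcc[self.gcf == f])) != 1:
                raise ValueError(f"GCF {f} spans multiple GCCs")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gcf_id": self.gcf, "gcc_id": self.gcc},
            index=pd.Index(self.bgc_ids, name="bgc_id"),
        )

    @property
    def gcf_of(self) -> dict[str, int]:
        return dict(zip(self.bgc_ids, self.gcf.tolist()))

    @property
    def gcc_of(self) -> dict[str, int]:
        return dict(zip(self.bgc_ids, self.gcc.tolist()))

    @property
    def n_gcfs(self) -> int:
        return len(np.unique(self.gcf))

    @property
    def n_gccs(self) -> int:
        return len(np.unique(self.gcc))

    def gcf_members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for b, f in zip(self.bgc_ids, self.gcf):
            out.setdefault(int(f), []).append(b)
        return out


@dataclass
class ReferenceDistance:
    """Cosine distance of BGCs and clans to a reference (known-BGC) set.

    ``per_bgc`` is the minimum cosine distance from each BGC to any reference
    vector; ``per_gcc`` aggregates member BGC values by arithmetic mean; a clan
    is "known-like" when its aggregate is below ``threshold``.
    """

    per_bgc: pd.Series
    per_gcc: pd.Series
    known_like: pd.Series
    threshold: float = 0.2


def cosine_distance_matrix(features: FeatureMatrix) -> np.ndarray:
    """All-to-all cosine distance matrix, d(i,j) = 1 - cos(v_i, v_j).

    For nonnegative vectors the distances lie in [0, 1].  All-zero rows have
    undefined direction and are rejected; strip them first with
    :meth:`FeatureMatrix.drop_featureless`.
    """
    zero = features.featureless_ids()
    if zero:
        raise ValueError(
            f"feature matrix has all-zero (featureless) rows: {zero[:5]}"
            + ("..." if len(zero) > 5 else "")
        )
    dense = features.weights.toarray()
    dist = squareform(pdist(dense, metric="cosine"))
    np.clip(dist, 0.0, 1.0, out=dist)
    np.fill_diagonal(dist, 0.0)
    return dist


def _validate_distance_matrix(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if (dist < 0).any():
        raise ValueError("distance matrix must be nonnegative")
    if not np.allclose(np.diag(dist), 0.0):
        raise ValueError("distance matrix must have zero diagonal")
    return dist


def _dense_labels(raw: np.ndarray) -> np.ndarray:
    """Relabel cluster ids as dense integers by first appearance."""
    mapping: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, r in enumerate(raw):
        out[i] = mapping.setdefault(int(r), len(mapping))
    return out


def _strict_cut(tree: np.ndarray, threshold: float) -> np.ndarray:
    # fcluster's "distance" criterion is <= t; the family/clan definition is
    # strict (< t), so cut at the largest float below the threshold.
    return fcluster(tree, t=np.nextafter(threshold, 0.0), criterion="distance")


def cluster_gcf_gcc(
    dist: np.ndarray,
    bgc_ids: Sequence[str] | None = None,
    t_gcf: float = GCF_THRESHOLD,
    t_gcc: float = GCC_THRESHOLD,
    featureless: Sequence[str] = (),
) -> ClusterAssignment:
    """Average-linkage clustering with two flat cuts of one dendrogram.

    Any two BGCs in the same flat cluster have cophenetic (merge-height)
    distance strictly below the threshold: < ``t_gcf`` within a family,
    < ``t_gcc`` within a clan.  Because both cuts come from the same tree the
    family partition refines the clan partition.
    """
    dist = _validate_distance_matrix(dist)
    n = dist.shape[0]
    if bgc_ids is None:
        bgc_ids = [f"bgc_{i:05d}" for i in range(n)]
    if len(bgc_ids) != n:
        raise ValueError("bgc_ids length does not match distance matrix")
    if t_gcf > t_gcc:
        raise ValueError("family threshold must not exceed clan threshold")
    if n == 1:
        gcf = gcc = np.zeros(1, dtype=int)
    else:
        tree = linkage(squareform(dist, checks=False), method="average")
        gcf = _dense_labels(_strict_cut(tree, t_gcf))
        gcc = _dense_labels(_strict_cut(tree, t_gcc))
    return ClusterAssignment(
        list(bgc_ids), gcf, gcc, t_gcf, t_gcc, "average", list(featureless)
    )


def cluster_features(
    features: FeatureMatrix,
    t_gcf: float = GCF_THRESHOLD,
    t_gcc: float = GCC_THRESHOLD,
) -> ClusterAssignment:
    """Convenience wrapper: drop featureless rows, compute distances, cluster."""
    kept, dropped = features.drop_featureless()
    if kept.n_bgcs == 0:
        raise ValueError("no BGCs with features to cluster")
    dist = cosine_distance_matrix(kept)
    return cluster_gcf_gcc(dist, kept.bgc_ids, t_gcf, t_gcc, featureless=dropped)


def _align_domains(
    features: FeatureMatrix, refs: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Project both matrices onto the union domain vocabulary (missing = 0)."""
    vocab = list(dict.fromkeys(list(features.domain_ids) + list(refs.domain_ids)))
    pos = {d: j for j, d in enumerate(vocab)}

    def project(fm: FeatureMatrix) -> np.ndarray:
        out = np.zeros((fm.n_bgcs, len(vocab)))
        cols = [pos[d] for d in fm.domain_ids]
        out[:, cols] = fm.weights.toarray()
        return out

    return project(features), project(refs)


def reference_distance(
    features: FeatureMatrix,
    refs: FeatureMatrix,
    assignment: ClusterAssignment,
    threshold: float = 0.2,
) -> ReferenceDistance:
    """Minimum cosine distance of each BGC to the reference set, aggregated per clan.

    Per-BGC value is the minimum over reference vectors; the clan value is the
    mean of its members' values; clans under ``threshold`` are "known-like".
    """
    if refs.n_bgcs == 0:
        raise ValueError("reference set is empty")
    feat, ref = _align_domains(features, refs)
    dist = cdist(feat, ref, metric="cosine")
    np.clip(dist, 0.0, 1.0, out=dist)
    per_bgc = pd.Series(
        dist.min(axis=1), index=pd.Index(features.bgc_ids, name="bgc_id"),
        name="min_ref_distance",
    )
    gcc = pd.Series(assignment.gcc_of, name="gcc_id")
    per_gcc = per_bgc.groupby(gcc.reindex(per_bgc.index)).mean()
    per_gcc.index.name = "gcc_id"
    per_gcc.name = "mean_ref_distance"
    known_like = (per_gcc < threshold).rename("known_like")
    return ReferenceDistance(per_bgc, per_gcc, known_like, threshold)


def taxa_specificity(
    assignment: ClusterAssignment,
    taxonomy: pd.DataFrame,
    bgc_to_genome: Mapping[str, str],
) -> pd.DataFrame:
    """Classify each GCF by the taxonomic spread of its member BGCs.

    ``taxonomy`` is indexed by genome_id with columns genus / species / strain.
    Labels are cumulative: a species-specific family is also genus-specific,
    and a strain-singleton (exactly one member BGC) is both.  ``cross_genus``
    flags families spanning two or more genera.
    """
    for col in ("genus", "species"):
        if col not in taxonomy.columns:
            raise ValueError(f"taxonomy table lacks required column {col!r}")
    rows = []
    for gcf_id, members in sorted(assignment.gcf_members().items()):
        genera, species = set(), set()
        for bgc in members:
            genome = bgc_to_genome.get(bgc)
            if genome is None:
                raise KeyError(f"BGC {bgc} has no genome mapping")
            if genome not in taxonomy.index:
                raise KeyError(f"genome {genome} missing from taxonomy table")
            rec = taxonomy.loc[genome]
            genera.add(rec["genus"])
            species.add((rec["genus"], rec["species"]))
        rows.append(
            {
                "gcf_id": gcf_id,
                "n_bgcs": len(members),
                "n_genera": len(genera),
                "n_species": len(species),
                "genus_specific": len(genera) == 1,
                "species_specific": len(species) == 1,
                "strain_singleton": len(members) == 1,
                "cross_genus": len(genera) >= 2,
            }
        )
    return pd.DataFrame(rows).set_index("gcf_id")


def specificity_summary(spec_table: pd.DataFrame) -> dict[str, float]:
    """Headline shares (percent, 1 dp) of genus/species/strain-specific GCFs."""
    n = len(spec_table)
    if n == 0:
        raise ValueError("empty specificity table")

    def pct(count: int) -> float:
        return round(100.0 * count / n, 1)

    counts = {
        "n_gcfs": n,
        "n_genus_specific": int(spec_table["genus_specific"].sum()),
        "n_species_specific": int(spec_table["species_specific"].sum()),
        "n_strain_singleton": int(spec_table["strain_singleton"].sum()),
        "n_cross_genus": int(spec_table["cross_genus"].sum()),
    }
    return {
        **counts,
        "pct_genus_specific": pct(counts["n_genus_specific"]),
        "pct_species_specific": pct(counts["n_species_specific"]),
        "pct_strain_singleton": pct(counts["n_strain_singleton"]),
        "pct_cross_genus": pct(counts["n_cross_genus"]),
    }
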