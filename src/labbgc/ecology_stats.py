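"""Ecological statistics: alpha diversity, rank correlations, FDR control and
the negative-association screen between bacteriocin precursor clusters and
community members.

The screen tests every precursor cluster against every species' relative
abundance (and against the sample Shannon index) with Spearman correlations,
adjusts p-values per test family with Benjamini-Hochberg, and retains edges
with rho below a negative cutoff (-0.3 against species, -0.4 against the
Shannon index) at adjusted p < 0.05.  Retained edges are candidate
antagonistic relationships; the screen computes associations only and makes
no causal claim.
"""

from __future__ import annotations

import warnings
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "shannon",
    "spearman",
    "bh_adjust",
    "correlation_network",
    "network_graph",
    "chisq_2x2",
]

RHO_SPECIES = -0.3
RHO_SHANNON = -0.4
Q_MAX = 0.05


def shannon(profile_row: np.ndarray | pd.Series) -> float:
    """Shannon diversity H = -sum p_i ln p_i (nats) over nonzero entries.

    The row is renormalized to sum to 1 first, so absolute abundances are
    accepted.  H lies in [0, ln S] for S observed species.
    """
    p = np.asarray(profile_row, dtype=float)
    if (p < 0).any():
        raise ValueError("relative abundances must be nonnegative")
    total = p.sum()
    if total <= 0:
        raise ValueError("all-zero abundance row: Shannon index undefined")
    p = p[p > 0] / total
    return float(-(p * np.log(p)).sum())


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    rho is the Pearson correlation of mid-ranks (ties averaged); p comes from
    t = rho sqrt((n-2)/(1-rho^2)) on n-2 df.  |rho| = 1 gives p = 0.  A
    constant input leaves rho undefined: (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length vectors")
    if len(x) < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant vector: Spearman rho undefined", stacklevel=2)
        return (float("nan"), float("nan"))
    rho, p = stats.spearmanr(x, y)
    # perfect rank agreement can land at 1 - eps through the Pearson-of-ranks
    # arithmetic; snap it so the |rho| = 1 -> p = 0 contract holds exactly
    if abs(abs(rho) - 1.0) < 1e-12:
        return (float(np.sign(rho)), 0.0)
    return (float(rho), float(p))


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (clipped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _rank_matrix(x: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(stats.rankdata, 0, x)


def _spearman_block(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Spearman rho and two-sided t-approximation p for all column
    pairs of a (n x ka) against b (n x kb).  Constant columns give nan."""
    n = a.shape[0]
    ra, rb = _rank_matrix(a), _rank_matrix(b)
    ra = ra - ra.mean(axis=0)
    rb = rb - rb.mean(axis=0)
    sa = np.sqrt((ra**2).sum(axis=0))
    sb = np.sqrt((rb**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ra.T @ rb) / np.outer(sa, sb)
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(rho) >= 1.0, 0.0, p)
    return rho, p


def correlation_network(
    cluster_abund: pd.DataFrame,
    profile: pd.DataFrame,
    rho_species: float = RHO_SPECIES,
    rho_shannon: float = RHO_SHANNON,
    q_max: float = Q_MAX,
) -> pd.DataFrame:
    """Screen all precursor-cluster x species pairs (plus cluster x Shannon
    index) for negative monotone association.

    Both frames are sample-indexed; the intersection of samples is used and
    must hold >= 4 samples.  Species tests and Shannon tests form separate
    Benjamini-Hochberg families.  The returned edge list keeps every tested
    pair, flagging which edges pass (rho < cutoff and q < ``q_max``); pairs
    with an undefined rho (constant input) carry NaN statistics and are never
    retained.
    """
    shared = cluster_abund.index.intersection(profile.index)
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared samples; need >= 4")
    ca = cluster_abund.loc[shared].to_numpy(float)
    pr = profile.loc[shared].to_numpy(float)
    shannon_vec = np.array([shannon(row) for row in pr])[:, None]

    rows = []
    for target_block, targets, cutoff, family in (
        (pr, list(profile.columns), rho_species, "species"),
        (shannon_vec, ["shannon"], rho_shannon, "shannon"),
    ):
        rho, p = _spearman_block(ca, target_block)
        for i, cluster in enumerate(cluster_abund.columns):
            for j, target in enumerate(targets):
                rows.append(
                    {
                        "cluster": cluster,
                        "target": target,
                        "family": family,
                        "rho": rho[i, j],
                        "p": p[i, j],
                        "rho_cutoff": cutoff,
                    }
                )
    edges = pd.DataFrame(rows)
    edges["q"] = np.nan
    for family in ("species", "shannon"):
        mask = (edges["family"] == family) & edges["p"].notna()
        if mask.any():
            edges.loc[mask, "q"] = bh_adjust(edges.loc[mask, "p"].to_numpy())
    edges["retained"] = (
        edges["rho"].notna()
        & (edges["rho"] < edges["rho_cutoff"])
        & (edges["q"] < q_max)
    )
    return edges


def network_graph(edges: pd.DataFrame) -> nx.Graph:
    """Graph of retained edges (clusters and targets as nodes) for GraphML export."""
    g = nx.Graph()
    for _, row in edges[edges["retained"]].iterrows():
        g.add_node(str(row["cluster"]), kind="precursor_cluster")
        g.add_node(str(row["target"]), kind=row["family"])
        g.add_edge(
            str(row["cluster"]), str(row["target"]),
            rho=float(row["rho"]), q=float(row["q"]),
        )
    return g


def chisq_2x2(table: np.ndarray, correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test on a 2x2 count table (1 df, no continuity
    correction by default); both margins must be positive."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ValueError("table entries must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("all row and column margins must be positive")
    stat, p, _, _ = stats.chi2_contingency(t, correction=correction)
    return float(stat), float(p)
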