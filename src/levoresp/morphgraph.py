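"""Individual morphological brain networks from divergences between ROI
intensity distributions, and graph-metric feature vectors.

Each subject's network has one node per atlas ROI. Edge weights are a
similarity transform of the Jensen-Shannon divergence between the two ROIs'
intensity histograms, w = exp(-JS), which is bounded in (0.5, 1] because
JS <= ln 2 (natural logs throughout). Per-node features are the Onnela
weighted clustering coefficient and strength-based degree centrality.
"""
from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.special import rel_entr

from .grids import AtlasLabels, VolumeGrid

__all__ = [
    "ROIDistribution",
    "MorphNetwork",
    "roi_density",
    "kl_divergence",
    "js_divergence",
    "build_network",
    "nodal_clustering_coefficient",
    "degree_centrality",
    "graph_feature_vector",
]


@dataclass
class ROIDistribution:
    masses: np.ndarray  # probabilities over shared bins, sum 1
    edges: np.ndarray  # shared bin edges (common intensity range)

    def __post_init__(self) -> None:
        if np.any(self.masses < 0) or abs(self.masses.sum() - 1.0) > 1e-9:
            raise ValueError("masses must be a probability vector")


@dataclass
class MorphNetwork:
    roi_names: list[str]
    adjacency: np.ndarray  # symmetric, zero diagonal, weights in (0, 1]

    def __post_init__(self) -> None:
        A = self.adjacency
        if A.shape[0] != A.shape[1] or A.shape[0] != len(self.roi_names):
            raise ValueError("adjacency shape does not match node list")
        if not np.allclose(A, A.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(A) != 0):
            raise ValueError("self-weights must be 0")


def roi_density(
    v: VolumeGrid,
    atlas: AtlasLabels,
    roi_id: int,
    n_bins: int = 64,
    epsilon: float = 1e-10,
    edges: np.ndarray | None = None,
) -> ROIDistribution:
    """Epsilon-smoothed histogram of one ROI over bins shared across ROIs.

    The shared edges span the whole-volume intensity range so any two ROI
    distributions of one volume live on a common support.
    """
    atlas.check_aligned(v)
    mask = atlas.mask(roi_id)
    if not mask.any():
        raise ValueError(f"ROI {roi_id} is empty")
    if edges is None:
        lo, hi = float(v.data.min()), float(v.data.max())
        if hi == lo:
            hi = lo + 1.0
        edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(v.data[mask], bins=edges)
    p = counts.astype(np.float64) + epsilon
    return ROIDistribution(p / p.sum(), edges)


def _check_support(P: ROIDistribution, Q: ROIDistribution) -> None:
    if P.masses.shape != Q.masses.shape or not np.allclose(P.edges, Q.edges):
        raise ValueError("distributions are not on the same support")


def kl_divergence(P: ROIDistribution, Q: ROIDistribution) -> float:
    """Kullback-Leibler divergence in nats; p=0 terms contribute 0."""
    _check_support(P, Q)
    return float(rel_entr(P.masses, Q.masses).sum())


def js_divergence(P: ROIDistribution, Q: ROIDistribution) -> float:
    """Jensen-Shannon divergence in nats, bounded by ln 2."""
    _check_support(P, Q)
    m = ROIDistribution((P.masses + Q.masses) / 2.0, P.edges)
    return 0.5 * kl_divergence(P, m) + 0.5 * kl_divergence(Q, m)


def build_network(
    v: VolumeGrid,
    atlas: AtlasLabels,
    roi_ids: list[int] | None = None,
    n_bins: int = 64,
    epsilon: float = 1e-10,
) -> MorphNetwork:
    """Fully connected weighted graph with w(a, b) = exp(-JS(Pa, Pb))."""
    if roi_ids is None:
        roi_ids = atlas.roi_ids
    if len(roi_ids) < 3:
        raise ValueError("need at least 3 ROIs to build a network")
    lo, hi = float(v.data.min()), float(v.data.max())
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    dists = [roi_density(v, atlas, r, n_bins, epsilon, edges) for r in roi_ids]
    K = len(roi_ids)
    A = np.zeros((K, K))
    for a in range(K):
        for b in range(a + 1, K):
            w = np.exp(-js_divergence(dists[a], dists[b]))
            A[a, b] = A[b, a] = w
    return MorphNetwork([atlas.name_of(r) for r in roi_ids], A)


def _to_nx(g: MorphNetwork) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(range(len(g.roi_names)))
    K = len(g.roi_names)
    for a in range(K):
        for b in range(a + 1, K):
            if g.adjacency[a, b] > 0:
                G.add_edge(a, b, weight=float(g.adjacency[a, b]))
    return G


def nodal_clustering_coefficient(g: MorphNetwork) -> np.ndarray:
    """Onnela weighted clustering: geometric-mean triangle intensity with
    weights normalized by the network maximum; nodes of degree < 2 get 0."""
    if len(g.roi_names) < 3:
        raise ValueError("need at least 3 nodes")
    cc = nx.clustering(_to_nx(g), weight="weight")
    return np.array([cc[i] for i in range(len(g.roi_names))])


def degree_centrality(g: MorphNetwork) -> np.ndarray:
    """Node strength sum_v w(u, v) normalized by K - 1."""
    K = len(g.roi_names)
    if K < 2:
        raise ValueError("need at least 2 nodes")
    return g.adjacency.sum(axis=1) / (K - 1)


def graph_feature_vector(g: MorphNetwork) -> pd.Series:
    """Length-2K named vector: clustering coefficients then centralities."""
    cc = nodal_clustering_coefficient(g)
    dc = degree_centrality(g)
    out: dict[str, float] = {}
    for name, val in zip(g.roi_names, cc):
        out[f"NodalClusteringCoefficient {name}"] = float(val)
    for name, val in zip(g.roi_names, dc):
        out[f"DegreeCentrality {name}"] = float(val)
    return pd.Series(out)
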