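"""Whole-network metrics, degree distributions, hubs and overlap maps.

Path length uses the harmonic-mean (global-efficiency) form

    L = 1 / mean_{i != j} (1 / d(i, j)),   1/inf = 0,

over all ordered pairs of the full node set, so disconnected pairs
raise L rather than being dropped. The clustering coefficient averages
the Watts-Strogatz local coefficient; by default the average runs over
nodes of degree >= 2 (nodes that can close a triangle), with the
all-node denominator available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import shortest_path

from .netbuild import BinaryNetwork, components

__all__ = [
    "MetricSet", "OverlapMap",
    "clustering_coefficient", "path_length", "global_efficiency",
    "degree_distribution", "DegreeDistribution",
    "hub_mask", "overlap_map", "metric_set",
]


def local_clustering(network: BinaryNetwork) -> np.ndarray:
    """Per-node triangles / (k(k-1)/2); zero for degree < 2."""
    a = network.adjacency.astype(np.int64)
    tri = np.asarray((a @ a).multiply(a).sum(axis=1)).ravel() / 2.0
    k = network.degrees.astype(float)
    denom = k * (k - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1.0), 0.0)
    return c


def clustering_coefficient(network: BinaryNetwork,
                           denominator: str = "deg2") -> float:
    """Mean local clustering; ``denominator`` is ``"deg2"`` (nodes with
    degree >= 2, default) or ``"all"`` (isolated/leaf nodes count 0)."""
    c = local_clustering(network)
    if denominator == "all":
        return float(c.mean())
    if denominator != "deg2":
        raise ValueError(f"unknown denominator {denominator!r}")
    mask = network.degrees >= 2
    if not mask.any():
        return 0.0
    return float(c[mask].mean())


def _pairwise_inverse_distance_sum(network: BinaryNetwork,
                                   block: int = 512) -> float:
    """Sum over ordered pairs of 1/d(i,j), BFS in row blocks."""
    n = network.n
    total = 0.0
    adj = network.adjacency
    for start in range(0, n, block):
        idx = np.arange(start, min(start + block, n))
        d = shortest_path(adj, method="D", unweighted=True, indices=idx)
        with np.errstate(divide="ignore"):
            inv = 1.0 / d
        inv[~np.isfinite(inv)] = 0.0
        inv[np.arange(len(idx)), idx] = 0.0
        total += inv.sum()
    return total


def global_efficiency(network: BinaryNetwork) -> float:
    """Mean over ordered node pairs of 1 / geodesic distance."""
    n = network.n
    if n < 2:
        raise ValueError("need at least 2 nodes")
    return _pairwise_inverse_distance_sum(network) / (n * (n - 1))


def path_length(network: BinaryNetwork) -> float:
    """Harmonic-mean path length L = 1 / global efficiency."""
    if network.n_edges == 0:
        raise ValueError("path length undefined for an edgeless network")
    return 1.0 / global_efficiency(network)


@dataclass(frozen=True)
class DegreeDistribution:
    """Empirical node-degree histogram."""

    counts: np.ndarray     # counts[d] = number of nodes with degree d
    max_degree: int

    def __post_init__(self):
        if self.counts[self.max_degree] == 0 and self.max_degree != 0:
            raise ValueError("max_degree inconsistent with counts")


def degree_distribution(network: BinaryNetwork) -> DegreeDistribution:
    k = network.degrees
    return DegreeDistribution(counts=np.bincount(k),
                              max_degree=int(k.max()) if len(k) else 0)


def hub_mask(network: BinaryNetwork, top_fraction: float = 0.2) -> np.ndarray:
    """Boolean mask of the floor(top_fraction * n) highest-degree nodes.

    Ties broken by ascending node index, so the selection is
    deterministic.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    n = network.n
    k = int(np.floor(top_fraction * n))
    order = np.lexsort((np.arange(n), -network.degrees))
    mask = np.zeros(n, dtype=bool)
    mask[order[:k]] = True
    return mask


@dataclass(frozen=True)
class OverlapMap:
    """Per-node count of subjects whose mask/module contains the node."""

    counts: np.ndarray
    n_subjects: int

    def __post_init__(self):
        if self.counts.min() < 0 or self.counts.max() > self.n_subjects:
            raise ValueError("overlap counts must lie in [0, n_subjects]")


def overlap_map(masks: list[np.ndarray]) -> OverlapMap:
    """Sum boolean node masks across subjects."""
    if not masks:
        raise ValueError("need at least one mask")
    n = len(masks[0])
    for m in masks:
        if len(m) != n:
            raise ValueError("masks must cover the same node set")
    counts = np.sum([np.asarray(m, dtype=bool) for m in masks], axis=0)
    return OverlapMap(counts=counts.astype(int), n_subjects=len(masks))


@dataclass(frozen=True)
class MetricSet:
    """The whole-network metrics reported per (subject, method)."""

    C: float
    L: float
    Nc: int
    connected_fraction: float
    degrees: np.ndarray
    max_degree: int

    def __post_init__(self):
        if not (0 <= self.C <= 1):
            raise ValueError("C must lie in [0, 1]")
        if self.L < 1:
            raise ValueError("L must be >= 1 for a network with edges")


def metric_set(network: BinaryNetwork, *,
               c_denominator: str = "deg2") -> MetricSet:
    """Compute C, L, Nc, connected fraction and degrees in one pass."""
    comp = components(network)
    return MetricSet(
        C=clustering_coefficient(network, denominator=c_denominator),
        L=path_length(network),
        Nc=comp.giant_size,
        connected_fraction=comp.connected_fraction,
        degrees=network.degrees,
        max_degree=int(network.degrees.max()))
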