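"""Threshold a correlation matrix into a binary undirected network.

The threshold is not chosen as a fixed correlation value but so that
the density ratio S = log(N) / log(K) — N the total node count, K the
mean degree — hits a target (default 3.0). Only positive correlations
are eligible as edges, the edge rule is strict (r > threshold), and
candidate thresholds are the distinct observed values, which makes the
search exact: S is monotone in the threshold, so a binary search over
the sorted distinct positive values plus a local scan resolves the
discrete minimum of |S - S_target|.

N counts all mask nodes, connected or not: disconnection is a result
of thresholding, not an input restriction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .corrstats import CorrelationMatrix

__all__ = ["BinaryNetwork", "ComponentLabeling", "threshold_for_S",
           "components", "network_from_adjacency"]


class ThresholdingError(ValueError):
    """No admissible threshold (no positive values, or best K <= 1)."""


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected simple graph over the full node set.

    ``adjacency`` is a symmetric sparse boolean matrix with empty
    diagonal; ``threshold`` and ``S_achieved`` record how the network
    was produced (NaN for networks built directly from an adjacency).
    """

    adjacency: sp.csr_matrix
    threshold: float = float("nan")
    S_achieved: float = float("nan")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz // 2)

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel().astype(int)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / self.n

    def edge_list(self) -> np.ndarray:
        coo = sp.triu(self.adjacency, k=1).tocoo()
        order = np.lexsort((coo.col, coo.row))
        return np.column_stack([coo.row[order], coo.col[order]])

    def subgraph(self, keep: np.ndarray) -> "BinaryNetwork":
        adj = self.adjacency[keep][:, keep].tocsr()
        return BinaryNetwork(adjacency=adj, threshold=self.threshold,
                             S_achieved=float("nan"))

    def to_networkx(self):
        import networkx as nx
        g = nx.Graph()
        g.add_nodes_from(range(self.n))
        g.add_edges_from(map(tuple, self.edge_list()))
        return g

    def __post_init__(self):
        a = self.adjacency
        if a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if a.diagonal().any():
            raise ValueError("self-loops are not allowed")
        if (a != a.T).nnz != 0:
            raise ValueError("adjacency must be symmetric")


def network_from_adjacency(adj) -> BinaryNetwork:
    """Wrap a dense or sparse 0/1 adjacency as a BinaryNetwork."""
    a = sp.csr_matrix(adj, dtype=np.int8)
    a.setdiag(0)
    a.eliminate_zeros()
    a = ((a + a.T) > 0).astype(np.int8).tocsr()
    return BinaryNetwork(adjacency=a)


@dataclass(frozen=True)
class ComponentLabeling:
    """Connected-component ids plus giant size and connected fraction."""

    labels: np.ndarray
    giant_size: int
    connected_fraction: float
    n_components: int
    giant_label: int = field(default=0)

    def giant_mask(self) -> np.ndarray:
        return self.labels == self.giant_label


def _edge_counts_for_thresholds(pos_sorted: np.ndarray,
                                candidates: np.ndarray) -> np.ndarray:
    """Number of upper-triangle values strictly above each candidate."""
    return len(pos_sorted) - np.searchsorted(pos_sorted, candidates,
                                             side="right")


def _s_value(n: int, n_edges: int) -> float:
    k = 2.0 * n_edges / n
    if k <= 1.0:
        return np.inf
    return np.log(n) / np.log(k)


def threshold_for_S(matrix: CorrelationMatrix, S_target: float = 3.0
                    ) -> BinaryNetwork:
    """Pick the realizable threshold whose S ratio is closest to target.

    Among the distinct positive off-diagonal values (as strict
    thresholds), returns the one minimizing |log(n)/log(K) - S_target|,
    ties broken toward the larger threshold (sparser network). Errors
    when there is no positive value or no threshold achieves K > 1.
    """
    if S_target <= 1:
        raise ValueError("S_target must exceed 1")
    n = matrix.n
    offdiag = matrix.offdiagonal()
    pos = np.sort(offdiag[offdiag > 0])
    if pos.size == 0:
        raise ThresholdingError("no positive off-diagonal correlations")
    # strict edge rule r > threshold: candidates are 0 (all positive
    # values become edges) plus every distinct positive value
    cands = np.concatenate([[0.0], np.unique(pos)])
    edge_counts = _edge_counts_for_thresholds(pos, cands)
    svals = np.array([_s_value(n, e) for e in edge_counts])
    valid = np.isfinite(svals)
    if not valid.any():
        raise ThresholdingError(
            "every admissible threshold leaves mean degree K <= 1")
    vidx = np.flatnonzero(valid)
    vs = svals[vidx]  # nondecreasing in threshold

    # binary search for the first S >= target, then local scan
    pos_ins = int(np.searchsorted(vs, S_target, side="left"))
    window = range(max(0, pos_ins - 2), min(len(vidx), pos_ins + 3))
    best = None
    for w in window:
        i = vidx[w]
        gap = abs(vs[w] - S_target)
        # tie toward the larger threshold = larger candidate index
        key = (gap, -i)
        if best is None or key < best[0]:
            best = (key, i)
    i = best[1]
    thr = float(cands[i])

    vals = matrix.values
    adj_dense = (vals > thr)
    np.fill_diagonal(adj_dense, False)
    adj = sp.csr_matrix(adj_dense, dtype=np.int8)
    net = BinaryNetwork(adjacency=adj, threshold=thr,
                        S_achieved=float(svals[i]))
    return net


def components(network: BinaryNetwork) -> ComponentLabeling:
    """Connected components, giant size and connected-node fraction."""
    n_comp, labels = connected_components(network.adjacency, directed=False)
    sizes = np.bincount(labels)
    giant_label = int(sizes.argmax())
    connected = float(np.mean(network.degrees >= 1)) if network.n else 0.0
    return ComponentLabeling(labels=labels, giant_size=int(sizes.max()),
                             connected_fraction=connected,
                             n_components=int(n_comp),
                             giant_label=giant_label)


def export_network(network: BinaryNetwork, edges_path, sidecar_path=None,
                   mtx_path=None):
    """TSV edge list (0-based), optional JSON sidecar and Matrix Market
    sparse adjacency."""
    np.savetxt(edges_path, network.edge_list(), fmt="%d", delimiter="\t",
               header="i\tj", comments="")
    if mtx_path is not None:
        from scipy.io import mmwrite
        mmwrite(str(mtx_path), network.adjacency, field="integer",
                symmetry="symmetric")
    if sidecar_path is not None:
        import json
        meta = {"n": network.n, "n_edges": network.n_edges,
                "threshold": None if np.isnan(network.threshold) else network.threshold,
                "S_achieved": None if np.isnan(network.S_achieved) else network.S_achieved,
                "edge_rule": "r > threshold (strict)"}
        with open(sidecar_path, "w") as fh:
            json.dump(meta, fh, indent=2)
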