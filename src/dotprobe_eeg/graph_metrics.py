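"""Nodal graph metrics of weighted EEG connectivity networks.

Nodes are electrodes; edge weights are PLV values (diagonal removed). Four
nodal metrics are computed:

* degree ``Dc_i = sum_j A_ij`` on a binarised graph (proportional threshold);
* strength ``Ne_i = sum_j W_ij`` on the full weighted graph;
* betweenness centrality ``Bc_i = sum_{j != i != k} sigma_jk(i) / sigma_jk``
  (unnormalised), by default on the weighted graph with distance ``1/w``;
* lateralization ``Nlp_i = (S_iL - S_iR) / (S_iL + S_iR)`` where ``S_iL``
  (``S_iR``) is node *i*'s summed weight to left- (right-) hemisphere nodes,
  midline nodes excluded from both sums.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "WeightedNetwork",
    "BinaryNetwork",
    "NodalMetrics",
    "proportional_threshold",
    "node_degree",
    "node_strength",
    "node_betweenness",
    "node_lateralization",
    "compute_nodal_metrics",
    "read_hemisphere_map",
    "write_hemisphere_map",
]


@dataclass
class WeightedNetwork:
    """Symmetric non-negative weighted graph with hemisphere tags."""

    weights: np.ndarray
    node_labels: list[str]
    hemisphere_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float).copy()
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weight matrix must be square")
        if w.shape[0] != len(self.node_labels):
            raise ValueError("node_labels length mismatch")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        np.fill_diagonal(w, 0.0)
        self.weights = w

    @classmethod
    def from_connectivity(cls, matrix, hemisphere_map: dict[str, str] | None = None
                          ) -> "WeightedNetwork":
        """Build from a ConnectivityMatrix (drops the unit diagonal)."""
        from .synthetic_data import hemisphere_of
        labels = list(matrix.node_labels)
        if hemisphere_map is None:
            hemisphere_map = {lab: hemisphere_of(lab) for lab in labels}
        return cls(weights=matrix.values, node_labels=labels,
                   hemisphere_map=dict(hemisphere_map))

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)


@dataclass
class BinaryNetwork:
    """0/1 adjacency with provenance of the thresholding rule."""

    adjacency: np.ndarray
    node_labels: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if not np.isin(a, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        if not (a == a.T).all():
            raise ValueError("adjacency must be symmetric")
        if np.diag(a).any():
            raise ValueError("adjacency diagonal must be 0")
        self.adjacency = a.astype(int)


@dataclass
class NodalMetrics:
    """Per-node Dc, Ne, Bc, Nlp bundled as a tidy DataFrame."""

    table: pd.DataFrame          # columns: node, dc, ne, bc, nlp, nlp_defined
    sparsity: float
    bc_mode: str


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def proportional_threshold(net: WeightedNetwork, sparsity: float) -> BinaryNetwork:
    """Keep the strongest fraction of possible edges as a binary graph.

    Retains the top ``floor(sparsity * n(n-1)/2)`` off-diagonal weights;
    zero-weight pairs are never promoted to edges. Ties are broken by
    stable (row-major upper-triangle) node-index order, so equal weights
    are kept in ascending (i, j) order.
    """
    if not (0.0 < sparsity <= 1.0):
        raise ValueError("sparsity must be in (0, 1]")
    n = net.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    w = net.weights[iu, ju]
    k = min(math.floor(sparsity * n * (n - 1) / 2), int((w > 0).sum()))
    order = np.argsort(-w, kind="stable")[:k]
    adj = np.zeros((n, n), dtype=int)
    adj[iu[order], ju[order]] = 1
    adj += adj.T
    return BinaryNetwork(adjacency=adj, node_labels=list(net.node_labels),
                         provenance=f"proportional_threshold(sparsity={sparsity})")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def node_degree(net: BinaryNetwork) -> np.ndarray:
    """Edge count per node (row sums of the adjacency matrix)."""
    return net.adjacency.sum(axis=1)


def node_strength(net: WeightedNetwork) -> np.ndarray:
    """Summed edge weight per node (row sums of the weight matrix)."""
    return net.weights.sum(axis=1)


def node_betweenness(net: WeightedNetwork | BinaryNetwork,
                     distance_rule: str = "inverse_weight",
                     normalized: bool = False) -> np.ndarray:
    """Betweenness centrality per node.

    ``distance_rule="inverse_weight"`` treats each edge as having length
    1/w (strong connections are short); ``"unit"`` uses hop counts on the
    (binary) adjacency. Unreachable pairs contribute 0. Values are
    unnormalised unless ``normalized`` is set.
    """
    if isinstance(net, BinaryNetwork):
        mat = net.adjacency.astype(float)
        if distance_rule != "unit":
            raise ValueError("binary networks support only the 'unit' rule")
    else:
        mat = net.weights
        if (mat < 0).any():
            raise ValueError("negative weights not allowed")
    n = len(net.node_labels)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.nonzero(np.triu(mat, k=1))
    if distance_rule == "inverse_weight":
        g.add_weighted_edges_from(
            (int(i), int(j), 1.0 / mat[i, j]) for i, j in zip(iu, ju))
        bc = nx.betweenness_centrality(g, normalized=normalized, weight="weight")
    elif distance_rule == "unit":
        g.add_edges_from(zip(iu.tolist(), ju.tolist()))
        bc = nx.betweenness_centrality(g, normalized=normalized)
    else:
        raise ValueError(f"unknown distance rule {distance_rule!r}")
    return np.array([bc[i] for i in range(n)])


def node_lateralization(net: WeightedNetwork) -> tuple[np.ndarray, np.ndarray]:
    """Left/right connection asymmetry per node.

    Returns ``(nlp, defined)``: ``nlp[i] = (S_iL - S_iR) / (S_iL + S_iR)``
    with midline nodes excluded from both sums; where ``S_iL + S_iR = 0``
    the value is NaN and ``defined[i]`` is False.
    """
    for lab in net.node_labels:
        if lab not in net.hemisphere_map:
            raise ValueError(f"missing hemisphere tag for node {lab!r}")
    hemi = np.array([net.hemisphere_map[lab] for lab in net.node_labels])
    left = net.weights[:, hemi == "left"].sum(axis=1)
    right = net.weights[:, hemi == "right"].sum(axis=1)
    total = left + right
    defined = total > 0
    nlp = np.full(net.n_nodes, np.nan)
    nlp[defined] = (left[defined] - right[defined]) / total[defined]
    return nlp, defined


def compute_nodal_metrics(net: WeightedNetwork, sparsity: float = 0.2,
                          bc_mode: str = "weighted") -> NodalMetrics:
    """Bundle the four nodal metrics for one network.

    Dc is computed on the proportionally thresholded binary graph; Ne and
    Nlp on the full weighted graph; Bc by default on the weighted graph
    with distance 1/w (``bc_mode="binary"`` computes hop-count betweenness
    on the thresholded graph instead).
    """
    binary = proportional_threshold(net, sparsity)
    dc = node_degree(binary)
    ne = node_strength(net)
    if bc_mode == "weighted":
        bc = node_betweenness(net, distance_rule="inverse_weight")
    elif bc_mode == "binary":
        bc = node_betweenness(binary, distance_rule="unit")
    else:
        raise ValueError(f"unknown bc_mode {bc_mode!r}")
    nlp, defined = node_lateralization(net)
    table = pd.DataFrame({
        "node": net.node_labels, "dc": dc, "ne": ne, "bc": bc,
        "nlp": nlp, "nlp_defined": defined})
    return NodalMetrics(table=table, sparsity=sparsity, bc_mode=bc_mode)


# ---------------------------------------------------------------------------
# hemisphere-map I/O (two-column text file: label <whitespace> hemisphere)
# ---------------------------------------------------------------------------

def read_hemisphere_map(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        label, hemi = line.split()
        if hemi not in ("left", "right", "midline"):
            raise ValueError(f"invalid hemisphere {hemi!r} for {label!r}")
        out[label] = hemi
    return out


def write_hemisphere_map(hemi: dict[str, str], path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(f"{lab}\t{h}" for lab, h in hemi.items()) + "\n")
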