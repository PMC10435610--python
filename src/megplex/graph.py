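"""Spanning-tree backbones, multiplex assembly, and multilayer centrality.

Each weighted connectivity matrix is binarized to its maximum-total-weight
spanning tree (Kruskal on distance 1 - w, i.e. strongest links kept), the
per-band trees become the diagonal blocks of an (L*N) x (L*N)
supra-adjacency matrix with identity interlayer coupling, and nodal
importance is the leading eigenvector of that supra matrix with layer
replicas aggregated per node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import connected_components

from .spectral import ConnectivityMatrix

__all__ = [
    "SpanningTreeLayer",
    "MultiplexNetwork",
    "CentralityVector",
    "SubnetworkDefinition",
    "spanning_backbone",
    "build_multiplex",
    "multilayer_eigenvector_centrality",
    "subnetwork_mean",
]


@dataclass
class SpanningTreeLayer:
    """Binary symmetric adjacency of a spanning tree: N-1 links, no cycles."""

    adjacency: np.ndarray
    band: str
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n = self.adjacency.shape[0]
        if self.adjacency.shape != (n, n):
            raise ValueError("adjacency must be square")
        if not self.region_labels:
            self.region_labels = [f"region_{i:03d}" for i in range(n)]

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_links(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, 1)))


@dataclass
class MultiplexNetwork:
    """(L*N) x (L*N) supra-adjacency with identity interlayer blocks.

    Node replica (layer l, node i) sits at supra index ``l * N + i``.
    """

    supra: np.ndarray
    n_layers: int
    n_nodes: int
    layer_order: list[str]
    interlayer_weight: float = 1.0
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.supra = np.asarray(self.supra, dtype=float)
        ln = self.n_layers * self.n_nodes
        if self.supra.shape != (ln, ln):
            raise ValueError(
                f"supra matrix shape {self.supra.shape} inconsistent with "
                f"L={self.n_layers}, N={self.n_nodes}"
            )
        if not self.region_labels:
            self.region_labels = [f"region_{i:03d}" for i in range(self.n_nodes)]

    def intralayer_link_count(self) -> int:
        total = 0
        for l in range(self.n_layers):
            block = self.supra[
                l * self.n_nodes : (l + 1) * self.n_nodes,
                l * self.n_nodes : (l + 1) * self.n_nodes,
            ]
            total += int(np.count_nonzero(np.triu(block, 1)))
        return total

    def interlayer_link_count(self) -> int:
        total = int(np.count_nonzero(np.triu(self.supra, 1)))
        return total - self.intralayer_link_count()


@dataclass
class CentralityVector:
    """Nodal multilayer eigenvector centrality, max-normalized to 1."""

    values: np.ndarray
    aggregation: str
    eigenvalue: float
    region_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not self.region_labels:
            self.region_labels = [
                f"region_{i:03d}" for i in range(self.values.size)
            ]


@dataclass
class SubnetworkDefinition:
    """A named node subset, by index or by label resolved at use time."""

    name: str
    node_indices: list[int]

    def __post_init__(self) -> None:
        if not self.node_indices:
            raise ValueError(f"subnetwork {self.name!r} is empty")
        if len(set(self.node_indices)) != len(self.node_indices):
            raise ValueError(f"subnetwork {self.name!r} has duplicate indices")

    @classmethod
    def from_labels(
        cls, name: str, labels: list[str], region_labels: list[str]
    ) -> "SubnetworkDefinition":
        index = {lab: i for i, lab in enumerate(region_labels)}
        missing = [lab for lab in labels if lab not in index]
        if missing:
            raise ValueError(
                f"subnetwork {name!r}: labels not found in region list: {missing}"
            )
        return cls(name, [index[lab] for lab in labels])


def _components(adjacency: np.ndarray) -> list[list[int]]:
    n_comp, labels = connected_components(adjacency != 0, directed=False)
    return [np.flatnonzero(labels == c).tolist() for c in range(n_comp)]


def spanning_backbone(conn: ConnectivityMatrix) -> SpanningTreeLayer:
    """Maximum-total-weight spanning tree of a weighted connectivity matrix.

    Kruskal's algorithm on the nonzero entries, taking the strongest links
    first. Equal weights are broken lexicographically on
    (min node index, max node index), which makes the result deterministic.

    Raises
    ------
    ValueError
        If the nonzero-weight graph is disconnected; the message lists the
        components.
    """
    w = conn.weights
    n = w.shape[0]
    iu, ju = np.triu_indices(n, 1)
    keep = w[iu, ju] != 0
    iu, ju, wu = iu[keep], ju[keep], w[iu, ju][keep]
    # sort by descending weight, then (i, j) for deterministic tie-breaks
    order = np.lexsort((ju, iu, -wu))

    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    adjacency = np.zeros((n, n))
    n_links = 0
    for k in order:
        a, b = find(int(iu[k])), find(int(ju[k]))
        if a != b:
            parent[a] = b
            adjacency[iu[k], ju[k]] = adjacency[ju[k], iu[k]] = 1.0
            n_links += 1
            if n_links == n - 1:
                break
    if n_links != n - 1:
        comps = _components(w)
        raise ValueError(
            f"weight graph is disconnected ({len(comps)} components): {comps}"
        )
    return SpanningTreeLayer(
        adjacency=adjacency,
        band=conn.band.name,
        region_labels=list(conn.region_labels),
    )


def build_multiplex(
    layers: list[SpanningTreeLayer], interlayer_weight: float = 1.0
) -> MultiplexNetwork:
    """Assemble the supra-adjacency matrix of a node-aligned multiplex.

    Layer adjacencies form the diagonal blocks; every off-diagonal block is
    ``interlayer_weight`` times the identity, linking each node only to its
    own replicas. For L spanning-tree layers of N nodes the result carries
    L*(N-1) intralayer and N*L*(L-1)/2 interlayer undirected links.
    """
    if not layers:
        raise ValueError("need at least one layer")
    n = layers[0].n_nodes
    for lay in layers:
        if lay.n_nodes != n:
            raise ValueError(
                f"layer {lay.band!r} has {lay.n_nodes} nodes, expected {n}"
            )
        if lay.region_labels != layers[0].region_labels:
            raise ValueError(f"layer {lay.band!r} node ordering differs")
    L = len(layers)
    supra = np.kron(
        np.ones((L, L)) - np.eye(L), interlayer_weight * np.eye(n)
    )
    for l, lay in enumerate(layers):
        supra[l * n : (l + 1) * n, l * n : (l + 1) * n] = lay.adjacency
    return MultiplexNetwork(
        supra=supra,
        n_layers=L,
        n_nodes=n,
        layer_order=[lay.band for lay in layers],
        interlayer_weight=interlayer_weight,
        region_labels=list(layers[0].region_labels),
    )


def multilayer_eigenvector_centrality(
    mplex: MultiplexNetwork, aggregation: str = "mean"
) -> CentralityVector:
    """Nodal centrality from the leading eigenvector of the supra matrix.

    The supra matrix is symmetric and, when connected, Perron-Frobenius
    guarantees a strictly positive leading eigenvector. Replicas of each
    node are combined across layers by ``aggregation`` ('mean' or 'sum' —
    identical up to scale) and the result is rescaled so its maximum is 1.

    Raises
    ------
    ValueError
        If the supra matrix is disconnected.
    """
    if aggregation not in ("mean", "sum"):
        raise ValueError(f"unknown aggregation rule {aggregation!r}")
    supra = mplex.supra
    n_comp, _ = connected_components(supra != 0, directed=False)
    if n_comp != 1:
        raise ValueError(
            f"supra matrix is disconnected ({n_comp} components); "
            "eigenvector centrality is only defined on connected networks"
        )
    eigenvalues, eigenvectors = np.linalg.eigh(supra)
    lam = float(eigenvalues[-1])
    v = eigenvectors[:, -1]
    # Perron vector has one sign; orient it positive.
    if v.sum() < 0:
        v = -v
    v = np.abs(v)  # scrub tiny negative round-off
    replicas = v.reshape(mplex.n_layers, mplex.n_nodes)
    agg = replicas.mean(axis=0) if aggregation == "mean" else replicas.sum(axis=0)
    agg = agg / agg.max()
    return CentralityVector(
        values=agg,
        aggregation=aggregation,
        eigenvalue=lam,
        region_labels=list(mplex.region_labels),
    )


def subnetwork_mean(ec: CentralityVector, subnet: SubnetworkDefinition) -> float:
    """Arithmetic mean of the centrality values over a node subset."""
    n = ec.values.size
    bad = [i for i in subnet.node_indices if not 0 <= i < n]
    if bad:
        raise ValueError(
            f"subnetwork {subnet.name!r}: indices {bad} out of range for "
            f"{n} nodes"
        )
    return float(ec.values[subnet.node_indices].mean())
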