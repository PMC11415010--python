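"""Graph ingestion, random-walk matrices, neighborhoods, and the farness screen.

A :class:`Network` is an undirected, simple, connected graph whose vertices
carry stable original labels plus a dense integer index 0..n-1 assigned in
sorted-label order.  All matrix-valued quantities (transition matrices,
absorbing blocks) use the dense index order; all reported vertex sets can be
mapped back to original labels with :meth:`Network.to_labels`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "Network",
    "VertexSet",
    "TransitionMatrix",
    "GraphFormatError",
    "load_graph",
    "from_nx",
    "transition_matrix",
    "neighborhood",
    "farness",
    "write_edgelist",
]


class GraphFormatError(ValueError):
    """Raised when an input file cannot be parsed as a graph."""


def _sort_key(label):
    # ints sort numerically before any string labels; mixed inputs stay stable
    return (0, label, "") if isinstance(label, int) else (1, 0, str(label))


@dataclass(frozen=True)
class Network:
    """Undirected simple connected graph with dense 0..n-1 vertex indices.

    ``labels[i]`` is the original label of dense vertex ``i``; labels are
    assigned in sorted order so the indexing is deterministic for a given
    vertex set.
    """

    graph: nx.Graph
    labels: tuple
    _index: dict = field(repr=False)

    def __post_init__(self):
        n = self.graph.number_of_nodes()
        if n < 2:
            raise ValueError("a Network needs at least 2 vertices")
        if not nx.is_connected(self.graph):
            raise ValueError("Network must be connected")
        if any(self.graph.has_edge(v, v) for v in self.graph):
            raise ValueError("Network must be simple (no self-loops)")

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def m(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degrees(self) -> np.ndarray:
        return np.asarray([self.graph.degree(i) for i in range(self.n)])

    @property
    def degree_ratio(self) -> float:
        """Max degree over mean degree, the heavy-tail indicator."""
        deg = self.degrees
        return float(deg.max() / deg.mean())

    def index_of(self, label) -> int:
        return self._index[label]

    def to_labels(self, vertices: Iterable[int]) -> list:
        return [self.labels[v] for v in vertices]

    def neighbors(self, v: int) -> list[int]:
        return sorted(self.graph.neighbors(v))

    def adjacency_csr(self) -> sp.csr_matrix:
        return nx.to_scipy_sparse_array(
            self.graph, nodelist=range(self.n), format="csr"
        )


@dataclass(frozen=True)
class VertexSet:
    """A candidate influencer/target set A, held as dense vertex indices."""

    members: frozenset

    @classmethod
    def of(cls, net: Network, members: Iterable[int]) -> "VertexSet":
        mem = frozenset(int(v) for v in members)
        if not mem:
            raise ValueError("vertex set must be non-empty")
        if not mem <= set(range(net.n)):
            raise ValueError(f"members {sorted(mem)} not all in 0..{net.n - 1}")
        return cls(mem)

    @classmethod
    def from_labels(cls, net: Network, labels: Iterable) -> "VertexSet":
        return cls.of(net, (net.index_of(l) for l in labels))

    @property
    def k(self) -> int:
        return len(self.members)

    def sorted(self) -> tuple:
        return tuple(sorted(self.members))

    def __iter__(self):
        return iter(self.sorted())

    def __contains__(self, v):
        return v in self.members


def _as_members(net: Network, A) -> frozenset:
    if isinstance(A, VertexSet):
        return A.members
    return VertexSet.of(net, A).members


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic random-walk matrix, standard (P) or lazy ((I+P)/2)."""

    P: sp.csr_matrix
    flavor: str  # "standard" | "lazy"


def _simplify(g: nx.Graph) -> nx.Graph:
    """Undirected simple graph restricted to its largest connected component."""
    g = nx.Graph(g)  # collapses multi-edges, drops directions
    g.remove_edges_from(nx.selfloop_edges(g))
    if g.number_of_nodes() == 0:
        raise GraphFormatError("empty graph after simplification")
    comp = max(nx.connected_components(g), key=lambda c: (len(c),))
    return g.subgraph(comp).copy()


def from_nx(g: nx.Graph) -> Network:
    """Build a Network from any networkx graph (simplify + take the LCC)."""
    g = _simplify(g)
    labels = tuple(sorted(g.nodes(), key=_sort_key))
    index = {lab: i for i, lab in enumerate(labels)}
    dense = nx.relabel_nodes(g, index, copy=True)
    return Network(graph=dense, labels=labels, _index=index)


def _parse_edgelist(path: str) -> nx.Graph:
    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",") if "," in line else line.split()
            parts = [p.strip() for p in parts if p.strip()]
            if len(parts) != 2:
                raise GraphFormatError(
                    f"{path}:{lineno}: expected two vertex labels, got {len(parts)}"
                )
            g.add_edge(parts[0], parts[1])
    if g.number_of_nodes() == 0:
        raise GraphFormatError(f"{path}: no edges found")
    # edge lists with all-numeric labels get integer labels
    if all(str(v).lstrip("-").isdigit() for v in g.nodes()):
        g = nx.relabel_nodes(g, {v: int(v) for v in g.nodes()})
    return g


def load_graph(path: str, format: str = "edgelist") -> Network:
    """Load a graph file and reduce it to a simple connected Network.

    Self-loops and duplicate edges are dropped and only the largest
    connected component is kept.  ``format`` is ``"edgelist"`` (two
    whitespace- or comma-separated labels per line, ``#`` comments) or
    ``"graphml"``.  Directed inputs are symmetrized.
    """
    if format == "edgelist":
        g = _parse_edgelist(path)
    elif format == "graphml":
        g = nx.read_graphml(path)
        if g.is_directed():
            g = g.to_undirected()
    else:
        raise ValueError(f"unknown format {format!r}")
    return from_nx(g)


def write_edgelist(net: Network, path: str) -> None:
    """Write the network as a two-column edge list in original labels."""
    with open(path, "w") as fh:
        for u, v in sorted(net.graph.edges()):
            fh.write(f"{net.labels[u]} {net.labels[v]}\n")


def transition_matrix(net: Network, lazy: bool = False) -> TransitionMatrix:
    """Uniform random-walk matrix P(i,j) = 1/deg(i) for j ~ i; lazy = (I+P)/2."""
    adj = net.adjacency_csr().astype(float)
    inv_deg = 1.0 / net.degrees
    P = sp.diags(inv_deg) @ adj
    if lazy:
        P = 0.5 * (sp.eye(net.n, format="csr") + P)
    return TransitionMatrix(P=sp.csr_matrix(P), flavor="lazy" if lazy else "standard")


def neighborhood(net: Network, A, p: int) -> set:
    """The p-th level neighborhood N^p[A] = {v : d(A, v) <= p} (includes A)."""
    members = _as_members(net, A)
    if p < 0:
        raise ValueError("p must be >= 0")
    reached = set(members)
    frontier = set(members)
    for _ in range(p):
        frontier = {
            w for v in frontier for w in net.graph.neighbors(v)
        } - reached
        if not frontier:
            break
        reached |= frontier
    return reached


def farness(net: Network, A) -> float:
    """Farness C(A) = sum over v outside A of the hop distance d(A, v).

    Computed by one multi-source BFS.  For any proper subset,
    C(A)/(|V|-|A|) >= 1, with equality exactly when A dominates the graph.
    A = V returns 0 by convention.
    """
    members = _as_members(net, A)
    if members == set(range(net.n)):
        return 0.0
    total = 0
    for depth, layer in enumerate(nx.bfs_layers(net.graph, sorted(members))):
        total += depth * len(layer)
    return float(total)


def all_k_subsets(vertices: Sequence[int], k: int):
    """Sorted k-subsets of a vertex collection, in lexicographic order."""
    return itertools.combinations(sorted(vertices), k)
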