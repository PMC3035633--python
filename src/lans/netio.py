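"""Graph container, validation, and edge-list / adjacency readers and writers.

The central object is :class:`WeightedNetwork`, a node-labelled graph with
strictly positive edge weights.  A weight of zero is synonymous with "no
edge": a node's neighbours are the nodes it shares positive weight with, and
its (out-)degree is the count of those positive-weight edges.  Undirected
networks store each edge once under a canonical (lexicographically sorted)
node pair; directed networks store ordered pairs.

File formats are deliberately minimal: TSV/CSV edge lists with columns
``source, target, weight`` (``#`` comments allowed), and dense labelled CSV
adjacency matrices.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

Edge = Tuple[str, str]

__all__ = [
    "WeightedNetwork",
    "BackboneResult",
    "read_edgelist",
    "read_adjacency",
    "write_backbone",
]


class WeightedNetwork:
    """A weighted graph with nonnegative (stored: strictly positive) weights.

    Parameters
    ----------
    directed:
        If True, edges are ordered pairs and a node's weight distribution is
        taken over its outgoing edges.  If False, each edge is stored once
        under the canonical sorted-label key and contributes to both
        endpoints' distributions.
    """

    def __init__(self, directed: bool = False):
        self.directed = directed
        self._nodes: Dict[str, None] = {}  # insertion-ordered set
        self._edges: Dict[Edge, float] = {}
        self._succ: Dict[str, Dict[str, float]] = {}

    # -- construction -----------------------------------------------------

    def add_node(self, u: str) -> None:
        if u not in self._nodes:
            self._nodes[u] = None
            self._succ[u] = {}

    def edge_key(self, u: str, v: str) -> Edge:
        """Canonical storage key for the edge between u and v."""
        if self.directed:
            return (u, v)
        return (u, v) if u <= v else (v, u)

    def add_edge(self, u: str, v: str, w: float) -> None:
        """Add an edge with positive weight ``w``.

        Zero-weight edges are ignored (zero weight means "absent"); negative
        weights, self-loops, and duplicate edges are errors.
        """
        w = float(w)
        if u == v:
            raise ValueError(f"self-loop not allowed: ({u!r}, {v!r})")
        if w < 0:
            raise ValueError(f"negative weight {w} on edge ({u!r}, {v!r})")
        if w == 0:
            return
        key = self.edge_key(u, v)
        if key in self._edges:
            raise ValueError(f"duplicate edge ({u!r}, {v!r})")
        self.add_node(u)
        self.add_node(v)
        self._edges[key] = w
        self._succ[u][v] = w
        if not self.directed:
            self._succ[v][u] = w

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> List[str]:
        return list(self._nodes)

    @property
    def n_nodes(self) -> int:
        return len(self._nodes)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, node: str) -> bool:
        return node in self._nodes

    def has_edge(self, u: str, v: str) -> bool:
        return self.edge_key(u, v) in self._edges

    def weight(self, u: str, v: str) -> float:
        return self._edges[self.edge_key(u, v)]

    def edges(self) -> Iterator[Tuple[str, str, float]]:
        """Iterate stored edges as (u, v, weight) under canonical keys."""
        for (u, v), w in self._edges.items():
            yield u, v, w

    def edge_dict(self) -> Dict[Edge, float]:
        return dict(self._edges)

    def out_items(self, u: str) -> List[Tuple[str, float]]:
        """Positive-weight (out-)neighbours of ``u`` with their weights."""
        return list(self._succ[u].items())

    def out_degree(self, u: str) -> int:
        return len(self._succ[u])

    def total_out_weight(self, u: str) -> float:
        return float(sum(self._succ[u].values()))

    # -- conversions -------------------------------------------------------

    def to_networkx(self) -> "nx.Graph | nx.DiGraph":
        g = nx.DiGraph() if self.directed else nx.Graph()
        g.add_nodes_from(self._nodes)
        for u, v, w in self.edges():
            g.add_edge(u, v, weight=w)
        return g

    def adjacency_matrix(self) -> Tuple[List[str], np.ndarray]:
        """Dense weight matrix with zero diagonal, rows/cols in node order."""
        labels = self.nodes
        idx = {u: i for i, u in enumerate(labels)}
        a = np.zeros((len(labels), len(labels)))
        for u, v, w in self.edges():
            a[idx[u], idx[v]] = w
            if not self.directed:
                a[idx[v], idx[u]] = w
        return labels, a

    def __eq__(self, other) -> bool:
        if not isinstance(other, WeightedNetwork):
            return NotImplemented
        return (
            self.directed == other.directed
            and set(self._nodes) == set(other._nodes)
            and self._edges == other._edges
        )

    def __repr__(self) -> str:
        kind = "directed" if self.directed else "undirected"
        return f"<WeightedNetwork {kind}, {self.n_nodes} nodes, {self.n_edges} edges>"


@dataclass
class BackboneResult:
    """A retained edge set with per-edge scores and method metadata.

    ``kept_edges`` holds canonical edge keys of the parent network;
    ``edge_score`` maps every kept edge to the score the method filtered on
    (an upper-tail probability for the significance filters, a transformed
    weight for the bistochastic filter, the raw weight for threshold/MST).
    """

    parent: WeightedNetwork
    kept_edges: Set[Edge]
    edge_score: Dict[Edge, float]
    method: str
    params: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        parent_edges = set(self.parent.edge_dict())
        if not self.kept_edges <= parent_edges:
            raise ValueError("kept_edges must be a subset of parent edges")
        missing = self.kept_edges - set(self.edge_score)
        if missing:
            raise ValueError(f"kept edges without scores: {sorted(missing)[:5]}")

    @property
    def n_kept(self) -> int:
        return len(self.kept_edges)

    def retention(self) -> float:
        """Fraction of the parent's edges retained."""
        if self.parent.n_edges == 0:
            return 0.0
        return len(self.kept_edges) / self.parent.n_edges

    def subnetwork(self) -> WeightedNetwork:
        net = WeightedNetwork(directed=self.parent.directed)
        for u in self.parent.nodes:
            net.add_node(u)
        for u, v in sorted(self.kept_edges):
            net.add_edge(u, v, self.parent.weight(u, v))
        return net

    def to_networkx(self):
        return self.subnetwork().to_networkx()

    def n_components(self) -> int:
        g = self.to_networkx()
        if self.parent.directed:
            return nx.number_weakly_connected_components(g)
        return nx.number_connected_components(g)

    def isolated_nodes(self) -> List[str]:
        """Parent nodes with no incident kept edge."""
        touched: Set[str] = set()
        for u, v in self.kept_edges:
            touched.add(u)
            touched.add(v)
        return [u for u in self.parent.nodes if u not in touched]


def _parse_weight(text: str, row_num: int) -> float:
    try:
        w = float(text)
    except ValueError as exc:
        raise ValueError(f"row {row_num}: unparseable weight {text!r}") from exc
    if not np.isfinite(w):
        raise ValueError(f"row {row_num}: non-finite weight {text!r}")
    return w


def read_edgelist(
    path,
    directed: bool = False,
    delimiter: str = "\t",
) -> WeightedNetwork:
    """Read a ``source, target, weight`` edge list.

    Lines starting with ``#`` are comments.  A first row whose third field is
    not numeric is treated as a header.  Zero-weight rows are dropped (with a
    logged count); negative weights, self-loops, and duplicate edges raise
    ``ValueError`` with the offending row number.
    """
    net = WeightedNetwork(directed=directed)
    n_zero = 0
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        first_data_row = True
        for row_num, row in enumerate(reader, start=1):
            if not row or row[0].lstrip().startswith("#"):
                continue
            if len(row) < 3:
                raise ValueError(
                    f"row {row_num}: expected source, target, weight; got {row!r}"
                )
            u, v, wtext = row[0].strip(), row[1].strip(), row[2].strip()
            if first_data_row:
                first_data_row = False
                try:
                    float(wtext)
                except ValueError:
                    continue  # header row
            w = _parse_weight(wtext, row_num)
            if w == 0:
                n_zero += 1
                continue
            try:
                net.add_edge(u, v, w)
            except ValueError as exc:
                raise ValueError(f"row {row_num}: {exc}") from exc
    if n_zero:
        logger.info("dropped %d zero-weight rows from %s", n_zero, path)
    return net


def read_adjacency(path, directed: bool = False) -> WeightedNetwork:
    """Read a dense labelled CSV adjacency matrix.

    The first row and first column carry node labels; the matrix must be
    square with a zero diagonal.  Undirected input must be symmetric within
    relative tolerance 1e-9.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"adjacency matrix is not square: {df.shape}")
    if list(df.index) != list(df.columns):
        raise ValueError("row labels do not match column labels")
    a = df.to_numpy(dtype=float)
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency diagonal must be zero (no self-loops)")
    if np.any(a < 0):
        raise ValueError("negative weights not allowed")
    if not directed:
        scale = max(np.abs(a).max(), 1.0)
        if not np.allclose(a, a.T, rtol=1e-9, atol=1e-9 * scale):
            raise ValueError("undirected adjacency matrix must be symmetric")
    labels = list(df.index)
    net = WeightedNetwork(directed=directed)
    for u in labels:
        net.add_node(u)
    n = len(labels)
    for i in range(n):
        cols = range(n) if directed else range(i + 1, n)
        for j in cols:
            if i != j and a[i, j] > 0:
                net.add_edge(labels[i], labels[j], a[i, j])
    return net


def write_backbone(result: BackboneResult, path) -> None:
    """Write a backbone as TSV: source, target, weight, score.

    A ``#`` comment header records the method and its parameters, so the file
    re-reads through :func:`read_edgelist` (which skips comments and the
    extra score column is ignored by the weight parser's first three fields
    -- the file simply carries four columns, the reader uses the first
    three).
    """
    with open(path, "w", newline="") as fh:
        fh.write(f"# method: {result.method}\n")
        for k, v in sorted(result.params.items(), key=lambda kv: kv[0]):
            fh.write(f"# {k}: {v}\n")
        fh.write("source\ttarget\tweight\tscore\n")
        for u, v in sorted(result.kept_edges):
            w = result.parent.weight(u, v)
            s = result.edge_score[(u, v)]
            fh.write(f"{u}\t{v}\t{w:.17g}\t{s:.17g}\n")
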