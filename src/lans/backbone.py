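"""Locally adaptive network sparsification (LANS).

LANS keeps an edge when it is *locally* significant: for each node i the
weights of its outgoing edges are normalised to fractional weights

    p_ij = w_ij / sum_m w_im,

and the empirical CDF of the node's fractional weights is evaluated at each
edge,

    F_ij = (1/k_i) * |{m : p_im <= p_ij}|        (inclusive of j itself),

where k_i is the number of positive-weight out-edges of i.  The upper-tail
probability q_ij = 1 - F_ij plays the role of a per-edge p-value under the
node's own empirical weight distribution; the edge (i, j) is kept whenever

    q_ij < alpha.

No parametric form is assumed for the local weight distribution -- the test
is distribution-free, which is what lets the filter adapt to networks whose
per-node weight distributions are heterogeneous across nodes and scales.

Because the CDF count is inclusive, each node's maximum-weight out-edge has
q = 0 and is kept at every alpha > 0, so a connected undirected network
never loses a node entirely under union symmetrization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Set, Tuple

import numpy as np

from .netio import BackboneResult, Edge, WeightedNetwork

__all__ = [
    "FractionalWeights",
    "LansSignificance",
    "fractional_weights",
    "empirical_significance",
    "lans_backbone",
]


@dataclass
class FractionalWeights:
    """Per-node normalised out-weight distributions.

    ``p[i][j]`` is the fractional weight of the edge from i to j; for every
    node with at least one out-edge the fractions sum to one.  Nodes with no
    out-edges are absent.
    """

    p: Dict[str, Dict[str, float]] = field(default_factory=dict)

    def degree(self, i: str) -> int:
        return len(self.p[i])

    @property
    def nodes(self) -> List[str]:
        return list(self.p)

    def fractions(self, i: str) -> np.ndarray:
        return np.asarray(list(self.p[i].values()))


@dataclass
class LansSignificance:
    """Empirical-CDF values F and upper-tail probabilities q per directed pair.

    For undirected networks both orientations of every edge are present,
    each evaluated under its own source node's distribution.
    """

    F: Dict[Tuple[str, str], float] = field(default_factory=dict)
    q: Dict[Tuple[str, str], float] = field(default_factory=dict)


def fractional_weights(net: WeightedNetwork) -> FractionalWeights:
    """Normalise each node's out-weights to a probability distribution.

    For undirected networks every incident edge contributes to both
    endpoints' distributions.
    """
    fw = FractionalWeights()
    for i in net.nodes:
        items = net.out_items(i)
        if not items:
            continue
        total = sum(w for _, w in items)
        fw.p[i] = {j: w / total for j, w in items}
    return fw


def empirical_significance(fw: FractionalWeights) -> LansSignificance:
    """Evaluate each node's empirical CDF at each of its out-edges.

    Uses an O(k log k) sort-and-searchsorted path per node; ``searchsorted``
    with ``side='right'`` on the sorted fractions reproduces the inclusive
    less-or-equal count exactly, ties included.
    """
    sig = LansSignificance()
    for i, dist in fw.p.items():
        nbrs = list(dist)
        p = np.asarray([dist[j] for j in nbrs])
        k = len(p)
        order = np.sort(p)
        counts = np.searchsorted(order, p, side="right")
        F = counts / k
        # single division keeps q on the exact grid m/k: an edge whose
        # upper-tail count is m compares against alpha the way the rational
        # m/k would, so the strict q < alpha rule has no rounding slack
        q = (k - counts) / k
        for j, fij, qij in zip(nbrs, F, q):
            sig.F[(i, j)] = float(fij)
            sig.q[(i, j)] = float(qij)
    return sig


def _validate_alpha(alpha: float) -> None:
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1); got {alpha}")


def _assemble_backbone(
    net: WeightedNetwork,
    q: Dict[Tuple[str, str], float],
    alpha: float,
    symmetrize: str,
    method: str,
) -> BackboneResult:
    """Keep edges with upper-tail score q < alpha under the requested mode.

    Shared by the LANS and disparity filters, which differ only in how q is
    computed.  ``union`` keeps an edge significant from either endpoint and
    scores it with the smaller q; ``directed`` keeps each directed edge on
    its own source-side score and requires a directed parent.
    """
    if symmetrize not in ("union", "directed"):
        raise ValueError(f"unknown symmetrize mode {symmetrize!r}")
    if symmetrize == "directed" and not net.directed:
        raise ValueError("symmetrize='directed' requires a directed network")

    kept: Set[Edge] = set()
    score: Dict[Edge, float] = {}
    if net.directed and symmetrize == "directed":
        for u, v, _ in net.edges():
            if q[(u, v)] < alpha:
                kept.add((u, v))
                score[(u, v)] = q[(u, v)]
    elif net.directed:  # union: symmetric backbone from a directed network
        for u, v, _ in net.edges():
            best = min(q[(u, v)], q.get((v, u), np.inf))
            if best < alpha:
                kept.add((u, v))
                score[(u, v)] = best
                if net.has_edge(v, u):
                    kept.add((v, u))
                    score[(v, u)] = best
    else:
        for u, v, _ in net.edges():
            best = min(q[(u, v)], q[(v, u)])
            if best < alpha:
                key = net.edge_key(u, v)
                kept.add(key)
                score[key] = best
    return BackboneResult(
        parent=net,
        kept_edges=kept,
        edge_score=score,
        method=method,
        params={"alpha": alpha, "symmetrize": symmetrize},
    )


def lans_backbone(
    net: WeightedNetwork,
    alpha: float,
    symmetrize: str = "union",
) -> BackboneResult:
    """Extract the LANS backbone at significance level ``alpha``.

    Parameters
    ----------
    net:
        The weighted network to sparsify.
    alpha:
        Significance level in (0, 1).  An edge is kept when its upper-tail
        empirical probability q is strictly below alpha; alpha is also a
        lower bound on the per-node fraction of edges retained.
    symmetrize:
        ``"union"`` (default, required for undirected input) keeps an edge
        significant from either endpoint; ``"directed"`` filters each
        directed edge under its source node's distribution only.
    """
    _validate_alpha(alpha)
    fw = fractional_weights(net)
    sig = empirical_significance(fw)
    return _assemble_backbone(net, sig.q, alpha, symmetrize, method="lans")
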