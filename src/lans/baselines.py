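"""Comparator sparsifiers: disparity filter, bistochastic filter, global
threshold, and maximum spanning tree.

The disparity filter tests each fractional edge weight p against a
stick-breaking null: k - 1 uniform points partition the unit interval into k
weights, under which the probability that a given weight exceeds p is

    alpha_ij = (1 - p_ij)^(k_i - 1).

The bistochastic filter first rescales the weight matrix to a doubly
stochastic one by Sinkhorn-Knopp iteration (alternating row and column
normalisation), then admits edges in order of non-increasing transformed
weight until a stopping criterion (edge budget or weight threshold) is met.
When the iteration does not converge -- some support patterns admit no
doubly stochastic scaling -- the standard remedy is to augment the matrix
with a small positive weight on the zero off-diagonal entries and rescale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Set, Tuple

import networkx as nx
import numpy as np

from .backbone import FractionalWeights, _assemble_backbone, _validate_alpha, fractional_weights
from .netio import BackboneResult, Edge, WeightedNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "BistochasticScaling",
    "disparity_significance",
    "disparity_backbone",
    "sinkhorn_matrix",
    "sinkhorn_scale",
    "bistochastic_backbone",
    "threshold_backbone",
    "max_spanning_tree",
]


def disparity_significance(fw: FractionalWeights) -> Dict[Tuple[str, str], float]:
    """Upper-tail probability of each fractional weight under the
    stick-breaking null, ``(1 - p)^(k - 1)``.

    A degree-1 node's single edge has p = 1 yet alpha_ij = 1 by convention:
    with k - 1 = 0 break points the null puts all mass at 1, so the edge can
    never look significant from that side.
    """
    out: Dict[Tuple[str, str], float] = {}
    for i, dist in fw.p.items():
        k = len(dist)
        for j, p in dist.items():
            if k == 1:
                out[(i, j)] = 1.0
            else:
                out[(i, j)] = float((1.0 - p) ** (k - 1))
    return out


def disparity_backbone(
    net: WeightedNetwork,
    alpha: float,
    symmetrize: str = "union",
) -> BackboneResult:
    """Disparity-filter backbone: keep (i, j) iff (1-p_ij)^(k_i-1) < alpha.

    Symmetrization modes match :func:`lans.backbone.lans_backbone`.
    """
    _validate_alpha(alpha)
    fw = fractional_weights(net)
    sig = disparity_significance(fw)
    return _assemble_backbone(net, sig, alpha, symmetrize, method="disparity")


@dataclass
class BistochasticScaling:
    """Result of Sinkhorn-Knopp scaling of a network's weight matrix.

    ``b`` maps each original edge to its transformed weight (for undirected
    networks, the mean of the two symmetric matrix entries).  ``row_factors``
    and ``col_factors`` reconstruct the scaled matrix as
    diag(row_factors) @ W @ diag(col_factors).
    """

    labels: List[str]
    matrix: np.ndarray
    b: Dict[Edge, float]
    row_factors: np.ndarray
    col_factors: np.ndarray
    converged: bool
    iterations: int
    epsilon_applied: float = 0.0

    def max_residual(self) -> float:
        r = np.abs(self.matrix.sum(axis=1) - 1.0).max()
        c = np.abs(self.matrix.sum(axis=0) - 1.0).max()
        return float(max(r, c))


def sinkhorn_matrix(
    a: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, bool, int]:
    """Alternate row and column normalisation of a nonnegative matrix.

    Returns ``(scaled, row_factors, col_factors, converged, iterations)``
    with ``scaled == diag(row_factors) @ a @ diag(col_factors)``.  Stops as
    soon as every row and column sum is within ``tol`` of one.  Matrices
    with an all-zero row or column are rejected: no scaling exists.
    """
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {a.shape}")
    if np.any(a < 0):
        raise ValueError("matrix entries must be nonnegative")
    rowsum = a.sum(axis=1)
    colsum = a.sum(axis=0)
    if np.any(rowsum == 0) or np.any(colsum == 0):
        zr = list(np.flatnonzero(rowsum == 0))
        zc = list(np.flatnonzero(colsum == 0))
        raise ValueError(
            "matrix has all-zero rows/columns and cannot be scaled "
            f"(zero rows {zr}, zero columns {zc}); consider augmentation"
        )
    n = a.shape[0]
    r = np.ones(n)
    c = np.ones(n)
    m = a.copy()
    converged = False
    it = 0
    # check first: an already doubly stochastic matrix takes zero iterations
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        for it in range(max_iter + 1):
            rowsum = m.sum(axis=1)
            colsum = m.sum(axis=0)
            if max(np.abs(rowsum - 1.0).max(), np.abs(colsum - 1.0).max()) <= tol:
                converged = True
                break
            if it == max_iter or not np.isfinite(m).all():
                break  # diverging scaling factors: no DS limit on this support
            r /= rowsum
            m /= rowsum[:, None]
            colsum = m.sum(axis=0)
            c /= colsum
            m /= colsum[None, :]
    return m, r, c, converged, it


def sinkhorn_scale(
    net: WeightedNetwork,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    epsilon: Optional[float] = None,
) -> BistochasticScaling:
    """Scale the network's weight matrix to doubly stochastic form.

    ``epsilon`` controls augmentation on non-convergence: if the iteration
    fails to converge and ``epsilon`` is given, the scaling restarts once on
    the matrix with ``epsilon`` added to every off-diagonal zero entry.
    ``epsilon="auto"`` uses 1e-6 times the smallest positive weight.
    """
    labels, a = net.adjacency_matrix()
    if epsilon == "auto":
        epsilon = 1e-6 * min(w for _, _, w in net.edges())
    eps_applied = 0.0

    def attempt(mat: np.ndarray):
        return sinkhorn_matrix(mat, tol=tol, max_iter=max_iter)

    def augmented(mat: np.ndarray, eps: float) -> np.ndarray:
        out = mat.copy()
        off = ~np.eye(len(mat), dtype=bool)
        out[off & (out == 0)] = eps
        return out

    try:
        m, r, c, converged, iters = attempt(a)
    except ValueError:
        if epsilon is None:
            raise
        eps_applied = float(epsilon)
        m, r, c, converged, iters = attempt(augmented(a, eps_applied))
    else:
        if not converged and epsilon is not None:
            eps_applied = float(epsilon)
            m, r, c, converged, iters = attempt(augmented(a, eps_applied))

    idx = {u: i for i, u in enumerate(labels)}
    b: Dict[Edge, float] = {}
    for u, v, _ in net.edges():
        if net.directed:
            b[(u, v)] = float(m[idx[u], idx[v]])
        else:
            key = net.edge_key(u, v)
            b[key] = float(0.5 * (m[idx[u], idx[v]] + m[idx[v], idx[u]]))
    return BistochasticScaling(
        labels=labels,
        matrix=m,
        b=b,
        row_factors=r,
        col_factors=c,
        converged=converged,
        iterations=iters,
        epsilon_applied=eps_applied,
    )


def bistochastic_backbone(
    net: WeightedNetwork,
    edge_budget: Optional[int] = None,
    weight_threshold: Optional[float] = None,
    tol: float = 1e-8,
    max_iter: int = 10_000,
    epsilon: Optional[float] = None,
) -> BackboneResult:
    """Bistochastic-filter backbone.

    Edges are sorted by transformed weight b (descending; ties broken by
    larger original weight, then canonical key) and admitted until the edge
    budget ``m`` is reached or the next edge's b falls to or below the
    threshold ``t``.  Exactly one stopping criterion must be given.  Only
    original edges are ever admitted; augmentation entries exist solely to
    make the scaling converge.
    """
    if (edge_budget is None) == (weight_threshold is None):
        raise ValueError("give exactly one of edge_budget or weight_threshold")
    if edge_budget is not None and edge_budget > net.n_edges:
        raise ValueError(
            f"edge budget {edge_budget} exceeds edge count {net.n_edges}"
        )
    scaling = sinkhorn_scale(net, tol=tol, max_iter=max_iter, epsilon=epsilon)
    if not scaling.converged:
        raise RuntimeError(
            "Sinkhorn iteration did not converge; pass epsilon to augment "
            "the zero entries and retry"
        )
    order = sorted(
        scaling.b.items(),
        key=lambda kv: (-kv[1], -net.weight(*kv[0]), kv[0]),
    )
    kept: Set[Edge] = set()
    score: Dict[Edge, float] = {}
    for key, bval in order:
        if edge_budget is not None and len(kept) >= edge_budget:
            break
        if weight_threshold is not None and bval <= weight_threshold:
            break
        kept.add(key)
        score[key] = bval
    params: Dict[str, object] = {
        "tol": tol,
        "max_iter": max_iter,
        "epsilon": scaling.epsilon_applied,
        "iterations": scaling.iterations,
    }
    if edge_budget is not None:
        params["edge_budget"] = edge_budget
    else:
        params["weight_threshold"] = weight_threshold
    return BackboneResult(
        parent=net, kept_edges=kept, edge_score=score,
        method="bistochastic", params=params,
    )


def threshold_backbone(net: WeightedNetwork, t: float) -> BackboneResult:
    """Global hard threshold: keep edges whose weight strictly exceeds t."""
    if t < 0:
        raise ValueError(f"threshold must be nonnegative; got {t}")
    kept = {net.edge_key(u, v) for u, v, w in net.edges() if w > t}
    score = {key: net.weight(*key) for key in kept}
    return BackboneResult(
        parent=net, kept_edges=kept, edge_score=score,
        method="threshold", params={"t": t},
    )


def max_spanning_tree(net: WeightedNetwork) -> BackboneResult:
    """Maximum-weight spanning tree (forest on disconnected input).

    Kruskal on weights sorted descending, ties broken by canonical edge key,
    so the output is deterministic.  Equivalent to negating the weights and
    running a minimum spanning tree.
    """
    if net.directed:
        raise ValueError("maximum spanning tree requires an undirected network")
    uf = nx.utils.UnionFind(net.nodes)
    kept: Set[Edge] = set()
    score: Dict[Edge, float] = {}
    for u, v, w in sorted(net.edges(), key=lambda e: (-e[2], e[0], e[1])):
        if uf[u] != uf[v]:
            uf.union(u, v)
            key = net.edge_key(u, v)
            kept.add(key)
            score[key] = w
    n_components = len({uf[u] for u in net.nodes})
    if n_components > 1:
        logger.warning(
            "input network is disconnected; returning a %d-component "
            "maximum spanning forest", n_components,
        )
    return BackboneResult(
        parent=net, kept_edges=kept, edge_score=score,
        method="mst", params={"n_components": n_components},
    )
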