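"""Generators for toy star/ring networks and random weighted fixtures.

The two star networks encode a known "important geometry" (the red edge
set) against a background (gray edges), so a sparsifier can be scored by
whether its backbone recovers exactly the red edges:

* ``simple_star`` -- a hub joined to a ring of outer nodes.  Spokes (red)
  carry weight 2, ring edges (gray) weight 1, emphasising the star geometry.
* ``complex_star`` -- a central star/ring whose weights are two orders of
  magnitude larger (200/100), with a peripheral copy of the simple star
  (weights 2/1) hanging off each central ring node via a weight-100
  connector.  The red set is the central spokes, the connectors, and the
  peripheral spokes: geometry spread across weight scales, the regime where
  a single global threshold must fail.

``random_weighted`` produces seeded random fixtures, including a
stick-breaking mode whose per-node out-fractions are drawn exactly from the
uniform-partition null of the disparity filter (useful for calibration
studies).
"""

from __future__ import annotations

from typing import FrozenSet, Optional, Tuple

import numpy as np

from .netio import Edge, WeightedNetwork

__all__ = [
    "simple_star",
    "complex_star",
    "random_weighted",
    "stick_breaking_fractions",
]


def simple_star(
    n_outer: int = 20,
    w_spoke: float = 2.0,
    w_ring: float = 1.0,
) -> Tuple[WeightedNetwork, FrozenSet[Edge]]:
    """Hub-plus-ring toy network; returns (network, red spoke-edge set).

    The hub connects to each of ``n_outer`` ring nodes with weight
    ``w_spoke`` (red); consecutive ring nodes are joined with ``w_ring``
    (gray).  2 * n_outer edges in total.
    """
    if n_outer < 3:
        raise ValueError(f"n_outer must be >= 3; got {n_outer}")
    if w_spoke <= 0 or w_ring <= 0:
        raise ValueError("weights must be positive")
    net = WeightedNetwork(directed=False)
    hub = "hub"
    ring = [f"r{i:02d}" for i in range(n_outer)]
    red = set()
    for r in ring:
        net.add_edge(hub, r, w_spoke)
        red.add(net.edge_key(hub, r))
    for i, r in enumerate(ring):
        net.add_edge(r, ring[(i + 1) % n_outer], w_ring)
    return net, frozenset(red)


def complex_star(
    n_outer: int = 10,
    scale: float = 100.0,
) -> Tuple[WeightedNetwork, FrozenSet[Edge]]:
    """Multiscale star-of-stars; returns (network, red edge set).

    Central star/ring with weights (2*scale, scale); one peripheral simple
    star (weights 2/1) per central ring node, its hub attached to that ring
    node by a connector of weight ``scale``.  Red = central spokes +
    connectors + peripheral spokes.
    """
    if n_outer < 3:
        raise ValueError(f"n_outer must be >= 3; got {n_outer}")
    if scale <= 0:
        raise ValueError("scale must be positive")
    net = WeightedNetwork(directed=False)
    red = set()
    hub = "hub"
    ring = [f"c{i:02d}" for i in range(n_outer)]
    for r in ring:
        net.add_edge(hub, r, 2.0 * scale)
        red.add(net.edge_key(hub, r))
    for i, r in enumerate(ring):
        net.add_edge(r, ring[(i + 1) % n_outer], scale)
    for i, r in enumerate(ring):
        phub = f"p{i:02d}h"
        net.add_edge(r, phub, scale)
        red.add(net.edge_key(r, phub))
        pring = [f"p{i:02d}r{j:02d}" for j in range(n_outer)]
        for pr in pring:
            net.add_edge(phub, pr, 2.0)
            red.add(net.edge_key(phub, pr))
        for j, pr in enumerate(pring):
            net.add_edge(pr, pring[(j + 1) % n_outer], 1.0)
    return net, frozenset(red)


def stick_breaking_fractions(k: int, rng: np.random.Generator) -> np.ndarray:
    """Draw k weights summing to one from the uniform-partition null.

    k - 1 uniform points are dropped on [0, 1]; the gaps between consecutive
    order statistics (and the interval ends) are the weights.  Each weight's
    marginal tail probability is (1 - p)^(k - 1).
    """
    if k < 1:
        raise ValueError(f"k must be >= 1; got {k}")
    cuts = np.sort(rng.uniform(size=k - 1))
    return np.diff(np.concatenate(([0.0], cuts, [1.0])))


def random_weighted(
    n_nodes: int,
    density: float,
    weight_law: str = "lognormal",
    seed: Optional[int] = None,
    mu: float = 0.0,
    sigma: float = 1.0,
    directed: bool = False,
) -> WeightedNetwork:
    """Seeded random weighted network fixture.

    ``weight_law="lognormal"`` places each possible edge independently with
    probability ``density`` and draws its weight from LogNormal(mu, sigma)
    -- a heavy-tailed law typical of similarity and traffic weights.

    ``weight_law="stickbreaking"`` builds a directed network in which every
    node sends out-edges to ``round(density * (n_nodes - 1))`` random
    targets with weights drawn exactly from the uniform-partition
    (stick-breaking) null, so each node's out-fraction distribution matches
    the disparity filter's null model by construction.
    """
    if seed is None:
        raise ValueError("seed is required for reproducibility")
    if not (0.0 < density <= 1.0):
        raise ValueError(f"density must lie in (0, 1]; got {density}")
    if n_nodes < 2:
        raise ValueError(f"n_nodes must be >= 2; got {n_nodes}")
    rng = np.random.default_rng(seed)
    labels = [f"n{i:04d}" for i in range(n_nodes)]

    if weight_law == "lognormal":
        net = WeightedNetwork(directed=directed)
        for u in labels:
            net.add_node(u)
        for i, u in enumerate(labels):
            others = labels if directed else labels[i + 1:]
            for v in others:
                if v == u:
                    continue
                if rng.uniform() < density:
                    net.add_edge(u, v, float(rng.lognormal(mu, sigma)))
        return net

    if weight_law == "stickbreaking":
        net = WeightedNetwork(directed=True)
        for u in labels:
            net.add_node(u)
        k = max(1, round(density * (n_nodes - 1)))
        for u in labels:
            targets = rng.choice(
                [v for v in labels if v != u], size=k, replace=False
            )
            weights = stick_breaking_fractions(k, rng)
            for v, w in zip(targets, weights):
                net.add_edge(u, str(v), float(w))
        return net

    raise ValueError(f"unknown weight_law {weight_law!r}")
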