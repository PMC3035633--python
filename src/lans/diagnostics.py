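"""Heterogeneity and retention diagnostics.

These tools quantify *why* a local, distribution-free filter matters for a
given network:

* pairwise symmetrized Kullback-Leibler divergences between the per-node
  fractional-weight distributions, embedded in 2-D by classical MDS -- if
  the points scatter widely, the local distributions are heterogeneous and
  no single parametric null fits them all;
* one-sample Kolmogorov-Smirnov tests of each node's fractional weights
  against the stick-breaking null CDF F(x) = 1 - (1 - x)^(k-1), counting
  how many nodes the parametric model is rejected for;
* retention curves: the fraction of edges a filter keeps as a function of
  its significance level alpha.  The empirical-CDF filter retains at least
  a fraction alpha of each node's edges, so its curve is near-linear with
  slope one; the parametric filter's curve can be nearly a step function.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import special, stats

from .backbone import FractionalWeights, fractional_weights, lans_backbone
from .baselines import disparity_backbone
from .netio import WeightedNetwork

__all__ = [
    "DivergenceMatrix",
    "RetentionCurve",
    "KsReport",
    "node_distributions",
    "symmetrized_kl",
    "divergence_matrix",
    "mds_embed",
    "parametric_null_cdf",
    "ks_heterogeneity",
    "retention_curve",
]


@dataclass
class DivergenceMatrix:
    """Pairwise symmetrized KL distances between per-node distributions."""

    nodes: List[str]
    matrix: np.ndarray
    bins: int
    pseudocount: float


@dataclass
class RetentionCurve:
    """Fraction of edges retained as a function of significance level."""

    method: str
    alphas: np.ndarray
    fractions: np.ndarray


@dataclass
class KsReport:
    """Per-node KS tests of fractional weights against the parametric null.

    ``rows`` holds one (node, degree, n_unique, statistic, pvalue) tuple per
    tested node; nodes with fewer than ``min_unique`` unique fractional
    weights are skipped (few unique values make the test unreliable) and
    listed in ``untested``.
    """

    levels: Tuple[float, ...]
    min_unique: int
    rows: List[Tuple[str, int, int, float, float]] = field(default_factory=list)
    untested: List[str] = field(default_factory=list)

    @property
    def n_tested(self) -> int:
        return len(self.rows)

    def n_rejected(self, level: float) -> int:
        return sum(1 for *_, p in self.rows if p < level)

    def rejection_rate(self, level: float) -> float:
        return self.n_rejected(level) / self.n_tested if self.rows else float("nan")


def node_distributions(
    fw: FractionalWeights,
    bins: int = 32,
    pseudocount: Optional[float] = None,
) -> Dict[str, np.ndarray]:
    """Histogram each node's fractional weights on [0, 1].

    Equal-width bins, left-inclusive except the last bin which includes 1.
    ``pseudocount`` mass is added to every bin before renormalising
    (default 1/(2*bins)), keeping vectors strictly positive so KL stays
    finite; pass 0 to disable smoothing.
    """
    if bins < 2:
        raise ValueError(f"bins must be >= 2; got {bins}")
    if pseudocount is None:
        pseudocount = 1.0 / (2 * bins)
    if pseudocount < 0:
        raise ValueError("pseudocount must be nonnegative")
    out: Dict[str, np.ndarray] = {}
    edges = np.linspace(0.0, 1.0, bins + 1)
    for i in fw.p:
        counts, _ = np.histogram(fw.fractions(i), bins=edges)
        vec = counts.astype(float) + pseudocount
        out[i] = vec / vec.sum()
    return out


def symmetrized_kl(p: np.ndarray, q: np.ndarray) -> float:
    """(KL(p||q) + KL(q||p)) / 2 in nats.

    Both arguments must be strictly positive probability vectors of equal
    length; smooth first (see :func:`node_distributions`) if zeros may occur.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("distributions must have equal length")
    if np.any(p <= 0) or np.any(q <= 0):
        raise ValueError("distributions must be strictly positive (smooth first)")
    if not (np.isclose(p.sum(), 1.0) and np.isclose(q.sum(), 1.0)):
        raise ValueError("distributions must each sum to one")
    return float(0.5 * (special.rel_entr(p, q).sum() + special.rel_entr(q, p).sum()))


def divergence_matrix(
    fw: FractionalWeights,
    bins: int = 32,
    pseudocount: Optional[float] = None,
) -> DivergenceMatrix:
    """All-pairs symmetrized KL between smoothed per-node histograms."""
    dists = node_distributions(fw, bins=bins, pseudocount=pseudocount)
    nodes = list(dists)
    n = len(nodes)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d[a, b] = d[b, a] = symmetrized_kl(dists[nodes[a]], dists[nodes[b]])
    if pseudocount is None:
        pseudocount = 1.0 / (2 * bins)
    return DivergenceMatrix(nodes=nodes, matrix=d, bins=bins, pseudocount=pseudocount)


def mds_embed(dm: DivergenceMatrix, dim: int = 2) -> Dict[str, np.ndarray]:
    """Classical (Torgerson) multidimensional scaling of a distance matrix.

    Double-centres the squared distances, takes the top ``dim`` eigenpairs,
    and returns origin-centred coordinates per node.  Negative eigenvalues
    (non-Euclidean distances) are clipped to zero.
    """
    d = np.asarray(dm.matrix, dtype=float)
    n = d.shape[0]
    if n < 3:
        raise ValueError("need at least 3 nodes to embed")
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d ** 2) @ j
    evals, evecs = np.linalg.eigh(b)
    # negative and numerically-zero eigenvalues carry no coordinates
    cutoff = n * np.finfo(float).eps * max(np.abs(evals).max(), 1.0)
    evals[np.abs(evals) < cutoff] = 0.0
    order = np.argsort(evals)[::-1][:dim]
    lam = np.clip(evals[order], 0.0, None)
    coords = evecs[:, order] * np.sqrt(lam)
    return {u: coords[i] for i, u in enumerate(dm.nodes)}


def parametric_null_cdf(x, k: int):
    """Stick-breaking null CDF, F(x) = 1 - (1 - x)^(k - 1).

    The distribution of a single fractional weight at a degree-k node when
    k - 1 uniform points partition the unit interval.  As k grows the CDF
    approaches a step at zero.  Vectorised in ``x``.
    """
    if k < 2:
        raise ValueError(f"k must be >= 2; got {k}")
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x must lie in [0, 1]")
    out = 1.0 - (1.0 - x) ** (k - 1)
    return float(out) if out.ndim == 0 else out


def _ks_pvalue(d: float, n: int) -> float:
    """Asymptotic Kolmogorov p-value with the standard finite-n correction.

    Uses the effective statistic (sqrt(n) + 0.12 + 0.11/sqrt(n)) * D.
    """
    rt = np.sqrt(n)
    return float(special.kolmogorov((rt + 0.12 + 0.11 / rt) * d))


def ks_heterogeneity(
    net: WeightedNetwork,
    levels: Sequence[float] = (0.05, 0.01),
    min_unique: int = 40,
) -> KsReport:
    """One-sample KS test of each node's fractional weights vs. the null.

    Each node with at least ``min_unique`` unique nonzero fractional
    weights is tested against ``parametric_null_cdf(. , k)`` at its own
    degree k.  The statistic is the sup-distance of the full empirical CDF
    (ties appear as taller steps); the unique-value count serves as the
    eligibility filter, since heavily tied samples make the test
    unreliable.  Rejection counts at each requested level summarise how
    heterogeneous the network is relative to the parametric model.
    """
    for lv in levels:
        if not (0.0 < lv < 1.0):
            raise ValueError(f"levels must lie in (0, 1); got {lv}")
    fw = fractional_weights(net)
    report = KsReport(levels=tuple(levels), min_unique=min_unique)
    for i in fw.p:
        fractions = fw.fractions(i)
        n_unique = len(np.unique(fractions))
        k = fw.degree(i)
        if n_unique < min_unique or k < 2:
            report.untested.append(i)
            continue
        d = float(stats.kstest(fractions, lambda x: parametric_null_cdf(x, k)).statistic)
        p = _ks_pvalue(d, k)
        report.rows.append((i, k, n_unique, d, p))
    return report


def retention_curve(
    net: WeightedNetwork,
    method: str,
    alphas: Sequence[float],
) -> RetentionCurve:
    """Fraction of edges retained at each significance level.

    ``method`` is ``"lans"`` or ``"disparity"``; symmetrization follows the
    method default (union for undirected input, per-direction for directed).
    """
    alphas = np.asarray(list(alphas), dtype=float)
    if np.any((alphas <= 0) | (alphas >= 1)):
        raise ValueError("alphas must lie in (0, 1)")
    if np.any(np.diff(alphas) < 0):
        raise ValueError("alphas must be sorted ascending")
    extract = {"lans": lans_backbone, "disparity": disparity_backbone}.get(method)
    if extract is None:
        raise ValueError(f"unknown method {method!r}")
    mode = "directed" if net.directed else "union"
    fractions = np.array(
        [extract(net, alpha=a, symmetrize=mode).retention() for a in alphas]
    )
    return RetentionCurve(method=method, alphas=alphas, fractions=fractions)
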