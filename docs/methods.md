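# Methods

## The problem

Similarity, correlation, and traffic networks are typically dense: almost
every pair of nodes carries a positive weight. Analysis and visualisation
need a sparse *backbone* that keeps the meaningful structure. A global hard
threshold keeps only the largest weights, so any community whose internal
weights live on a smaller scale is wiped out. The methods implemented here
instead judge each edge *locally*, against the weight distribution of its
own endpoint.

## Local significance under the empirical distribution

For a node $i$ with positive out-weights $w_{ij}$, define fractional
weights

$$p_{ij} = \frac{w_{ij}}{\sum_m w_{im}},$$

and let $k_i$ be the number of positive out-edges. The empirical CDF of
node $i$'s fractions, evaluated at edge $(i,j)$ with an inclusive count, is

$$F_{ij} = \frac{1}{k_i}\,\bigl|\{m : p_{im} \le p_{ij}\}\bigr|,$$

and $q_{ij} = 1 - F_{ij}$ is the upper-tail probability of the edge under
its own node's distribution. The edge is **locally significant** at level
$\alpha$ when $q_{ij} < \alpha$ (strict). For undirected networks the
default *union* symmetrization keeps an edge significant from either
endpoint; for directed networks each edge can instead be filtered under its
source distribution alone.

Consequences of the inclusive count and strict rule:

* every node's maximum-weight out-edge has $q = 0$ and is kept at any
  $\alpha > 0$, so a connected undirected network keeps every node attached
  (union mode);
* a node whose $k$ fractions are distinct keeps exactly
  $\lceil \alpha k \rceil$ out-edges, so $\alpha$ is a lower bound on the
  per-node retained fraction and network-level retention lies within
  $\max_i (1/k_i)$ of $\alpha$ — the retention curve is near-linear with
  slope one;
* no parametric assumption is made about the shape of the local weight
  distribution, so the filter adapts when those shapes differ across nodes.

Complexity is $O(N k_{\max} \log k_{\max})$ with the sort-based CDF used
here; the sort reproduces the inclusive-$\le$ counting semantics exactly,
ties included (this is asserted against an $O(k^2)$ pairwise-counting
oracle in the tests).

### Numerical note on the significance comparison

$q$ is computed as `(k - count) / k` in one division, so each score is the
correctly rounded float of the rational $m/k$. When $m/k$ happens to equal
the decimal value of $\alpha$ (for example $3/60$ and $\alpha = 0.05$), the
two round to the same float and the strict inequality excludes the edge,
exactly as the rational comparison would. Computing $1 - F$ in two steps
would instead leak boundary edges through rounding.

## Comparator filters

**Disparity filter.** Parametric counterpart: the null for a degree-$k$
node throws $k-1$ uniform points on $[0,1]$ and takes the gaps as weights
(stick breaking). A single gap then has tail probability

$$\Pr(P > p) = (1-p)^{k-1},$$

and an edge is kept when this is below $\alpha$. Degree-1 nodes get tail
probability 1 from their own side (with zero break points the null mass
sits at 1); under union symmetrization their edge may still enter from the
other endpoint.

**Bistochastic filter.** The weight matrix is rescaled to doubly stochastic
form by Sinkhorn–Knopp iteration — alternately normalising rows and
columns — then edges are admitted in order of non-increasing transformed
weight until an edge budget is met or the next transformed weight falls to
or below a threshold. Defaults: tolerance $10^{-8}$ on the worst row/column
sum deviation, 10,000 iterations. Some support patterns admit no doubly
stochastic scaling; on non-convergence, if an augmentation weight
$\varepsilon$ is supplied (`"auto"` = $10^{-6}\times$ smallest positive
weight), the scaling restarts once on the matrix with $\varepsilon$ in the
off-diagonal zeros. Augmentation entries are never admitted as edges, and
the applied $\varepsilon$ is recorded in the result metadata. Undirected
networks are scaled as symmetric matrices; each undirected edge is scored
with the mean of its two (symmetric up to the tolerance) matrix entries.
Admission ties on the transformed weight break by larger original weight,
then canonical key, so output is deterministic.

**Hard threshold** keeps edges with $w > t$ (strict), and **maximum
spanning tree** is Kruskal on descending weight with ties broken by
canonical edge key (equivalent to negating weights and running a minimum
spanning tree); disconnected input yields a maximum spanning forest with a
logged warning.

## Heterogeneity diagnostics

*Distribution distances.* Each node's fractions are histogrammed on
$[0,1]$ with $B = 32$ equal-width bins and a pseudocount of $1/(2B)$ per
bin (renormalised). The histogram-plus-smoothing choice keeps the
symmetrized Kullback–Leibler divergence
$\tfrac12\,(\mathrm{KL}(p\|q) + \mathrm{KL}(q\|p))$ finite; bin count and
pseudocount are recorded in the output object. The pairwise divergence
matrix is embedded by classical (Torgerson) MDS — double-centre the
squared distances, take the top two eigenpairs — which is deterministic,
unlike stress-minimising MDS. Eigenvalues within machine precision of zero
are clipped so duplicate distribution rows land on coincident points.

*KS tests.* Each node with at least `min_unique` (default 40) unique
nonzero fractional weights is tested against the stick-breaking null CDF
$F(x) = 1-(1-x)^{k-1}$ at its own degree. The statistic is the sup-distance
of the full empirical CDF (ties appear as taller steps); the unique-value
count is an eligibility filter only, since heavily tied samples make the
test unreliable. P-values use the asymptotic Kolmogorov distribution with
the standard finite-sample correction
$(\sqrt{n} + 0.12 + 0.11/\sqrt{n})\,D$.

Known property, quantified in the test suite: applied to a node whose
weights are *drawn from* the stick-breaking null, this KS test is
conservative (measured rejection rate ≈ 0.005 at level 0.05 over 1,000
simulated degree-60 nodes). The $k$ gaps sum to one and are negatively
dependent, which pulls the empirical CDF toward the null; the same
machinery applied to iid draws from the null marginal
$\mathrm{Beta}(1, k-1)$ rejects at the nominal rate (measured 0.048 at
level 0.05). Rejection counts on real networks are therefore, if anything,
understatements of heterogeneity.

## Synthetic networks

The generators are the package's test bed and define its study conditions:

* `simple_star(n_outer=20)` — hub + ring, spokes weight 2 (red), ring
  weight 1 (gray). The star geometry is the planted signal.
* `complex_star(n_outer=10, scale=100)` — central star/ring at weights
  200/100, a weight-100 connector from each central ring node to the hub
  of a peripheral simple star at weights 2/1. Red = central spokes +
  connectors + peripheral spokes. The attachment topology (one peripheral
  star per central ring node, hub-to-ring-node connector) is fixed here as
  the minimal arrangement realising those weight roles; tier sizes and the
  scale are parameters.
* `random_weighted(n, density, law, seed)` — lognormal weights (heavy
  tail, the typical shape of similarity/traffic weights; continuous, so
  fractions are almost surely distinct, which the retention-law checks
  rely on) or stick-breaking out-fractions (each node's distribution drawn
  exactly from the disparity null, for calibration and homogeneity
  studies).

What these fixtures do *not* emulate: correlated weight structure,
degree–weight coupling, and the community structure of real similarity
networks. Passing the toy contrasts shows each filter's scale behaviour,
not performance on any particular real dataset.

On these toys, at $\alpha = 0.05$: the empirical-CDF filter returns
exactly the red set in both stars (single connected component in the
complex star); the disparity filter returns the empty backbone on the
simple star (spoke tail $0.25$, hub $0.95^{19} \approx 0.377$, ring
$0.5625$, all $\ge \alpha$) and isolates 101 of 121 nodes on the complex
star; the bistochastic filter with a 20-edge budget returns the ring, not
the star (after scaling, ring entries $\approx 0.475$ dominate spoke
entries $\approx 0.05$).

## Problem sizes and reproducibility

The bundled checks use: stars at tier sizes 20 (simple) and 10 (complex);
the retention law on a 200-node directed lognormal network at density
0.15; oracle cross-checks over $k \le 50$ (quadrature), 1,000 random
tied-weight nodes (CDF counting), 100 random graphs of $\le 7$ nodes
(spanning-tree enumeration); KS calibration over 1,000 degree-60
stick-breaking nodes. All randomness flows from explicit seeds;
`scripts/acceptance.py --seed S` derives independent child streams from
`S`.

## Limitations

* Directed networks are filtered on out-distributions only; an in-degree
  variant would be symmetric but is not implemented.
* No multiple-testing correction is applied across edges; $\alpha$ is a
  per-edge local level, and retention scales accordingly.
* Signed (negative-weight) networks, multigraphs, and self-loops are out
  of scope; correlation networks should be mapped to nonnegative
  similarities upstream.
* The bistochastic filter inherits the usual caveats of Sinkhorn scaling:
  convergence depends on the support pattern, and augmentation perturbs
  the geometry it is meant to reveal (the perturbation is recorded but not
  undone).
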