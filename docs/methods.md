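# Methods

## The distance

Let T and T′ be rooted binary trees over the same n leaves with a fixed
(here: lexicographic) leaf ordering, and let ξ, ξ′ assign a real value to
every vertex.  The cophenetic vector of (T, ξ) lists ξ(lca(x_i, x_j)) for
every i ≤ j, diagonal included, so it has n(n+1)/2 entries; d_p is the L_p
norm of the two vectors' difference, and d_∞ the maximum entry difference.
The implementation requires both contributions to be *path-monotone* — ξ is
either non-decreasing from the root toward every leaf (we call this
orientation *descending*, e.g. depth) or non-increasing (*ascending*, e.g.
subtree height and subtree leaf count) — and requires the two contributions
of a pair to share one orientation.  Same-orientation pairs of *different*
kinds (say height against size) are allowed; they yield asymmetric
cost functions rather than metrics but are useful when the two trees come
from different sources (e.g. a gene tree against a species tree).  Ascending
pairs are normalized by jointly negating both ξ and ξ′, which changes no
entry difference and preserves integer-valuedness; all internal algorithms
then assume descending contributions.

Contributions supported out of the box: depth (edges to the root), subtree
height (longest downward path, in edges), subtree size (leaf count), and
weighted depth/height (edge-weight sums) for trees with branch lengths.  A
tree may carry an extra rooting edge; its weight is added to every weighted
depth (the root then has nonzero depth) but not to heights, because a
subtree's height is internal to the subtree — the rooting edge lies above
every subtree.  Subtree size ignores weights; it is a purely combinatorial
quantity.  User-defined contributions are accepted through a hook that
checks per-edge monotonicity.

## The quadratic oracle

`naive` evaluates the definition directly.  The lca-value matrix M[i, j] =
ξ(lca(x_i, x_j)) is filled one internal vertex at a time (each vertex v
covers exactly the cross pairs of its two child subtrees), and the power sum
is taken over the upper triangle.  With integer contributions the distinct
absolute differences are tabulated first and Σ count·d^p is evaluated in
Python's arbitrary-precision integers, so the result is exact at any p; with
real contributions the sum runs in float64.  A second, deliberately naive
construction (per-leaf ancestor walks filling a dict) exists alongside the
matrix route and the two are cross-checked in the tests; the slower route is
the one simple enough to be obviously correct.

## The divide-and-conquer

**Median split.**  Descending from the root toward the child with the larger
subtree (ties: left) until the subtree size drops to ≤ n/2 yields a vertex t
whose lower tree T_t (the subtree at t) holds between n/4 and n/2 leaves and
whose upper tree T^t (T with T_t replaced by a placeholder leaf) holds
between n/2 and 3n/4 + 1; both bounds are property-tested.  A median vertex
is generally non-unique; the left-first tie-break makes runs reproducible.
We treat "median vertex" as *an output of this descent*, not as any vertex
satisfying the size sandwich (in (a,(b,c)) the leaf a also satisfies the
bounds, but only b and c are reachable by the descent).  B denotes the
labels below t, A the rest; every A-leaf hangs off exactly one median-path
vertex, which is its lca with t — this "hang map" is computed once per split
and also yields, for each x ∈ A, the value β(x) = ξ(lca(x, t)) used
throughout the mixed-category routines.

**Ten categories.**  Classifying each leaf of a pair as A/B in T and A′/B′
in T′ partitions the unordered pairs (diagonal included) into ten
categories: four non-mixed (both leaves in the same cell, e.g. both in
A∩B′), four single-mixed (the two leaves split across the median in exactly
one tree) and two double-mixed (split in both).  The ten pair sets are
verified to partition all n(n+1)/2 pairs exactly.

**Non-mixed.**  For each of the four cells K = X∩X′ the two trees are
*contracted* to K — the induced topology with degree-2 vertices suppressed —
and the algorithm recurses.  Each surviving vertex keeps the contribution of
the original vertex it corresponds to; this is what makes the recursion
correct, and it is enforced structurally: contraction is built from a single
DFS that identifies consecutive-leaf lcas (the minimum-depth vertex touched
between two kept-leaf visits) and then assembles the induced topology with
an ancestor stack, copying ξ from the original ids.  Empty cells contribute
nothing; singleton cells contribute their diagonal term |ξ(x) − ξ′(x)|^p
directly.  Diagonal pairs always fall in exactly one non-mixed cell and are
ultimately handled by the base case.

**Double-mixed, aligned (upper in both / lower in both).**  For x ∈ A∩A′
and y ∈ B∩B′ the lca of ⟨x, y⟩ is lca(x, t) in T and lca(x, t′) in T′ —
independent of y — so the category's sum is |B∩B′| · Σ_x |β_T(x) − β_{T′}(x)|^p,
one linear sweep.

**Double-mixed, crossed.**  For x ∈ A∩B′, y ∈ B∩A′ the relevant values are
the two counter sequences: the multiset of β_T(x) over x ∈ A∩B′, and of
β_{T′}(y) over y ∈ B∩A′.  Emitting each by walking the median path from the
root down makes them sorted (descending contributions grow along the path),
and the cross-pair power sum Σ_{i,j} |α_i − β_j|^p is evaluated by `seq_prd`
in O(p(k+m)): a two-pointer merge maintains, at each β_j, the prefix power
sums σ_{j,l} = Σ_{α_i ≤ β_j} α_i^l, and the binomial expansion of
(β_j − α_i)^p / (α_i − β_j)^p over the two prefix/suffix parts gives each
row in O(p).

**Single-mixed.**  For the representative variant (pair upper/upper in T,
upper/lower in T′) every pair ⟨x, y⟩ with x ∈ A∩A′, y ∈ A∩B′ determines the
unique upper-tree vertex v with x under v and y under v's sibling, so
lca_T(x, y) = v.parent, while ξ′(lca_{T′}(x, y)) = β(x).  The sweep
aggregates, bottom-up over the upper tree, per-vertex power sums of β(x)
over the A∩A′ leaves below v, and adds at each non-root v the closed-form
contribution |Y_v| · Σ_l C(p,l)(−1)^{p−l}(…σ…), where Y_v counts the A∩B′
leaves under v's sibling.  For even p, |a−b|^p = (a−b)^p and a single σ
vector per vertex suffices.  For odd p the sign of ξ(v.parent) − β(x)
matters: each leaf's β is tracked in a σ+ or σ− accumulator according to
whether β(x) ≤ ξ(v.parent), and the handover point ω_x (the highest ancestor
w with ξ(w) ≥ β(x)) is located by binary search in the sorted root-to-leaf
contribution array maintained during the DFS; δ vectors posted at ω_x move
each leaf between the two accumulators at the right moment of the bottom-up
pass.  When ξ ties along a path, ω_x is taken closest to the root, which
keeps the per-vertex transfer sets disjoint.  A δ posted at the sweep's root
is never consumed — harmless, since the root contributes no pairs.  The
other three variants reuse the same engines: the lower-tree variant sweeps
T_t instead of the upper tree, and the remaining two swap the roles of the
trees.  Every variant is tested against the naive double loop restricted to
its own pair set, which pins down any orientation ambiguity empirically.

The derivation of the odd-p per-vertex formula was re-done from scratch for
this implementation (the two published forms of it differ in a sign and an
index convention); with 0-indexed power vectors (entry l = Σ x^l) it reads
κ_v = |Y_v| Σ_l C(p,l)(−1)^{p−l}(ξ(par)^l σ+_{p−l} + ξ(par)^{p−l} σ−_l).

**Recursion.**  Each level contracts into four subproblems of total size n,
each at most 3n/4 + 1, plus O(p·n) of mixed-category work; trees with at
most 5 leaves (configurable) fall through to a direct double loop.  Median
vertices are recomputed per level on the contracted trees.

**L_∞.**  A separate code path reuses the p = 1 decomposition with every sum
replaced by a maximum: the aligned double-mixed category takes a max over
the A∩A′ sweep (guarded on B∩B′ being non-empty), the crossed one reduces to
max(α_k − β_1, β_m − α_1) on the sorted counter sequences, and the
single-mixed sweeps only need the minimum and maximum β below each vertex —
no power vectors, no ω search.

## Numerical policy

With integer contributions every quantity (power vectors, binomials via the
multiplicative recurrence, κ, partial sums) is an exact Python integer, and
the contract asserted throughout the tests is *bit-exact equality* of fast
and naive power sums — at p = 100 the summands exceed 2^600, far beyond
float64, and the alternating binomial expansions would otherwise suffer
catastrophic cancellation.  With real (weighted) contributions the same code
runs in float64 and p is capped at 15 by default: the expansions are then
subject to rounding, and the tests use a 1e−9 relative tolerance at p ≤ 10.
Raising the cap is possible (`float_p_cap=`) but accuracy degrades with p;
for large p on weighted trees the quadratic oracle (which never expands
binomials) is the safer route.  Distances are reported as power_sum^{1/p}
evaluated in log space, so they remain finite even when the power sum
overflows float range.

## Random models and what the simulations show

The Yule generator grows a cherry by repeatedly splitting a uniformly chosen
leaf and then assigns labels by a uniform random permutation (the labeling
scheme is the standard convention; the model's topology law does not depend
on it).  The uniform generator inserts leaf k+1 on one of the 2k−1 edge
positions (including above the root) uniformly, which yields every labeled
topology with probability 1/(2n−3)!! — verified by a chi-square test on all
15 four-leaf topologies.  Both emit unweighted trees, so depth and height
are edge counts and all three standard contributions are integers; the L_∞
distances are then integers and are tabulated exactly, while finite-p
distance samples are grouped into 200 equal-width bins over the observed
range (the bin count is configurable).

The distribution experiment reproduces, at reduced sample size, the
concentration phenomenon of the L_∞ subtree-size distance for 100-leaf
trees: random tree pairs almost always contain a leaf pair forming a cherry
(lca size 2) in one tree while straddling the root (lca size 100) in the
other, so the distance is 98 = 100 − 2, the largest value the construction
admits.  The acceptance script verifies this both on an explicit worst-case
construction and as the mode over 200 random pairs per model.  These
simulators emulate topology-only null models; they do not produce branch
lengths, rate variation, or any signal of shared ancestry between the two
trees of a pair, so passing distribution checks says nothing about distances
between *correlated* (e.g. bootstrap or gene-tree) samples on real data.

## Problem sizes and performance

The default test suite exercises the fast-vs-naive contract on 1000 random
pairs up to n = 256 with p up to 100 plus L_∞, and the structural invariants
on 1000 random trees up to n = 512; the whole suite runs in well under a
minute on one core.  The runtime comparison in the acceptance tests times a
single Yule pair at n = 2000, p = 2.  On the machines used during
development the divide-and-conquer overtakes the vectorized quadratic
reference somewhere around n ≈ 2000–4000 for small p (at n = 8000 it is
roughly 8× faster, 1.5 s vs 12 s), so the n = 2000 point sits near the
crossover and the comparison is deliberately a warning, never a failure —
the asymptotic claim is about scaling, not about a fixed size, and the
quadratic baseline here is numpy-vectorized rather than a scalar loop, which
shifts the crossover upward relative to scalar implementations.

## Design choices and limitations

* Newick I/O is delegated to dendropy; unquoted labels are restricted to
  `[A-Za-z0-9_.-]`, quoted labels are passed through, internal-node labels
  are ignored, and a tree must be fully weighted or fully unweighted —
  silently defaulting missing branch lengths to 0 would corrupt weighted
  contributions.
* The leaf ordering for cophenetic indexing is lexicographic; any fixed
  ordering gives the same distance, and lexicographic is machine-independent.
* Only binary rooted trees are supported; non-binary input is rejected at
  parse time with the offending clade named.  Unrooted trees, NEXUS,
  and tree rearrangements are out of scope.
* The base-case threshold (5 leaves) matches the recursion's natural floor;
  raising it toward a few hundred would give a hybrid algorithm that is
  faster in practice but identical in output (the tests confirm the result
  is threshold-independent).
* `coph bench` reports wall-clock timings and asserts nothing: crossover
  points are hardware- and implementation-dependent.
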