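# Methods

## Model and definitions

A character with state set S = {1, …, N} evolves down a rooted binary tree
under a symmetric Markov model: along a branch the state is conserved with
probability q and replaced by each particular other state with probability
p, with q = 1 − (N−1)p. Two parameterizations are supported per branch:

* **probability**: the Newick branch value is p itself, valid on
  [0, 1/N] (the range reachable from a branch length) — values in
  (1/N, 1/(N−1)] keep q ≥ 0 and are mathematically meaningful but are
  rejected unless explicitly allowed, because they usually indicate a
  length mistaken for a probability;
* **length**: the value is a branch length l, mapped through
  p = (1/N)(1 − e^(−Nλl)) with substitution rate λ > 0.

There is no autodetection between the two readings; the caller must choose.

The Fitch method's leaf-to-root stage produces a state set S_u at every node
(intersection of the children's sets if nonempty, else union; the number of
union events is the parsimony score). The root-to-leaf stage draws the root
state uniformly from S_r and propagates downward, keeping the parent's state
whenever the child's set allows it (uniform choice otherwise — the uniform
child rule is our reading; only the root rule affects the accuracies
analysed here). Accuracies at the root, conditioning the true root state to
1 (lossless, by symmetry):

* UA = P(S_r = {1}),
* AA = E[ 1{1 ∈ S_r} / |S_r| ].

Always UA ≤ AA ≤ 1, and both equal 1/N under complete randomization.

## The class recurrence

The distribution of S_u conditional on the node's true state is invariant
under permutations of the other N − 1 states. Hence it is determined by the
probabilities of the 2N − 1 classes (i, c): |S_u| = i and c = 1{true state
∈ S_u} (the class (N, 0) is empty — the full set contains everything).
Within a class, the set is uniform over the class's C(N−1, i−1) or
C(N−1, i) members. We store **class totals** (the vector sums to 1), which
gives a strong running invariant; a per-representative-set convention
differs only by the class cardinalities.

**Branch mixing.** Transporting a child's vector a(·) to its parent's
conditioning state: with probability q the child's true state equals the
parent's; with probability p each it is another state j, and by
exchangeability a size-i set containing j contains the parent state with
probability (i−1)/(N−1), a size-i set avoiding j with probability i/(N−1).
Summing over j:

    m(i,1) = q·a(i,1) + p·[(i−1)·a(i,1) + i·a(i,0)]
    m(i,0) = q·a(i,0) + p·[(N−i)·a(i,1) + (N−1−i)·a(i,0)]

The size marginal a(i,1) + a(i,0) is preserved (only the conditioning
changes, not the set). The map is valid on the full stochastic range
p ∈ [0, 1/(N−1)].

**Combination kernel.** For independent child sets uniform on classes
(i, c) and (j, c′), their non-true-state parts are independent uniform
subsets of sizes i′ = i − c and j′ = j − c′ of the N − 1 non-true states, so
their overlap m is hypergeometric,
P(m) = C(i′, m)·C(N−1−i′, j′−m) / C(N−1, j′). The true state is in the
intersection iff c·c′ = 1. Intersect-else-union then lands in class
(m + c·c′, c·c′) when the intersection is nonempty, else in the union class
(i + j, max(c, c′)). The kernel is assembled once per N with exact rational
arithmetic (integer binomials) and converted to floats at the end; row sums
are exactly 1.

One post-order sweep (leaf vector → mixing per branch → kernel per internal
node) yields the root vector; UA = A(1,1) and AA = Σ_k A(k,1)/k. Cost
O(#nodes · N³). Normalization is asserted (tolerance 1e−9), never silently
restored, so kernel or mixing bugs cannot hide.

**Validation.** The recurrence is tested for exact agreement (1e−10) with a
brute-force oracle that enumerates all N^L leaf configurations, computes
their probabilities by pruning, and applies the Fitch rule directly — over
every rooted binary shape with up to 5 leaves, N ∈ {2, 3, 4}, 20 random
branch assignments each, and spot checks at N up to 10 (agreement at
1e−14). The kernel is additionally checked against an exhaustive
enumeration of every subset pair per class pair for N ≤ 4.

## Extremal shapes

**Equal-branch complete binary tree** (2^n leaves, common p). Both root
subtrees are copies of the previous level, so the root vector follows the
iterated quadratic map A ← K(mix(A), mix(A)). Numerical note: being
quadratic, the map doubles any rounding error in the vector's total per
application — (1 + ε)^(2^t) explodes (or collapses to 0) after roughly 60
levels. The level map therefore rescales its output to total 1, guarded by
an assertion that the drift is at rounding magnitude (10⁻⁶), preserving the
bug-catching role of the normalization invariant.

**Equilibrium threshold b.** For q below a threshold b the iterated map
drives AA to 1/N; above b the limit is informative. b is located by
bisection on q: each candidate is iterated to stationarity (change < 10⁻¹³
between iterates two levels apart, cap 10⁴ iterations) and classified as
equilibrium when |AA − 1/N| < 10⁻⁵ on **both** the even and odd level
subsequences. Comparing two levels apart makes the test valid for N = 2,
where below a lower endpoint a the map is period-2 (states alternate with
level) and the two subsequences converge to different limits; a is located
by bisection on the divergence criterion |AA_even − AA_odd| > 10⁻⁵. For
N ≥ 3 the alternating regime vanishes; a = 0 is reported after verifying
the equilibrium classification at q ∈ {0.01, 0.05, 0.1}. Defaults
(max 10⁴ iterations, bisection width 10⁻⁴, detection tolerance 10⁻⁵)
resolve b to well within the ±0.005 band used by the reference checks;
near-critical slowing is absorbed by the iteration cap.

**Equal-branch comb** (caterpillar). The n-leaf comb is a pendant leaf plus
the (n−1)-leaf comb at the root, giving the linear step
A_n = K(mix(leaf), mix(A_{n−1})). Its limiting accuracies never exceed the
nearest root-to-leaf path's accuracy q when q ≥ 1/N.

**Root-to-leaf path.** Copying a leaf k branches below the root succeeds
with the k-step conservation probability 1/N + ((N−1)/N)(1 − Np)^k; UA and
AA coincide (singleton reconstruction).

**Hennigian comb.** The ultrametric caterpillar: interior edges of common
length l; the leaf of the k-th interior node (root = 1st) gets pendant
length (n−k)·l, so all n leaves sit at depth (n−1)·l. (The ultrametric
constraint fixes the pendant lengths; the indexing convention is ours.)
Accuracies are computed in O(n) kernel applications along the interior
path. As n grows, AA → 1/N for every N, while UA converges to the closed
form

    UA_∞(N) = N^(N−2) / Σ_{i=1..N} [ N^(N−i) · (N−1)! / (N−i)! ]

evaluated in exact integer arithmetic. The limit is independent of λl: the
recurrence at n = 2000 matches the closed form to 6 decimals for
λl ∈ {0.01, …, 1} across N up to 20 (tests assert 0.002 at
λl ∈ {0.05, 0.1, 0.3}). Published 4-decimal tabulations of this limit for
large N (≥ 10) differ from the converged recurrence value in the fourth
decimal; since the recurrence is validated against the definitional
enumeration oracle, the package reports the computed value.

## Simulation machinery

**Character simulation** walks the tree drawing each child state (stay with
probability q, else uniform among the other N − 1 states) from a seeded
generator.

**Monte-Carlo estimator**: root state fixed to 1, leaf states simulated,
Fitch set stage run with sets encoded as bit masks and vectorized over
replicates (N ≤ 63). Each replicate contributes 1{S_r = {1}} to UA and the
analytic 1{1 ∈ S_r}/|S_r| to AA — the exact conditional expectation of
sampling the top-down stage, with strictly lower variance. Standard errors
are sample standard deviations over replicates.

**Yule generator**: starting from a cherry, a uniformly chosen extant leaf
is split until the target leaf count — the pure-birth topology law.
Experiments assign one common conservation probability to every branch and
sweep it over a grid, mirroring how balanced-vs-random-tree comparisons are
tabulated; birth waiting times are deliberately not used for branch lengths
(documented alternative, out of scope). The packaged sweep runs 50 trees ×
256 leaves for N = 4 by default-scale tests (the qualitative behavior —
AA ≈ 1/N below b, rapid growth above, occasional trees beating the
balanced reference — is already clear at this size); the generator itself
handles 1024-leaf trees in milliseconds for larger studies.

What the synthetic data does *not* emulate: rate heterogeneity across
branches or sites, asymmetric substitution, tree-inference error (the tree
is taken as known), and alignment/site extraction. Passing tests therefore
validate the exact accuracy machinery and its asymptotics under the
symmetric single-parameter model, not robustness to model violations.

## Degenerate inputs and edge rules

* A root left with a single child by taxon-subset restriction is handled
  throughout (accuracy = branch-mixed child vector; Fitch set passes
  through); suppressed degree-2 nodes compose their incident branches by
  1 − N·p_out = (1 − N·p₁)(1 − N·p₂).
* p = 0 everywhere ⇒ UA = AA = 1; p = 1/N on all branches ⇒ AA = 1/N.
* Enumeration oracle is capacity-capped at N^L ≤ 10⁷ configurations.
* All operations are invariant to child order; stage-one Fitch is
  equivariant under state permutations (both tested).

## Known limitations

* The recurrence covers the root's accuracies; per-internal-node accuracies
  are not computed (the top-down child rule would then matter).
* Weighted (Sankoff) parsimony, asymmetric models and unrooted or
  multifurcating trees are out of scope.
* The closed-form Hennigian limit is numerically validated, not re-proved.
* Threshold estimation near b inherits critical slowing; accuracy beyond
  the default ±0.005 band would need larger iteration caps.
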