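# Methods

## Problem and model

The package estimates an unrooted species tree from k unrooted gene trees
over a taxon universe X of n labels. Gene trees may be non-binary
(polytomies) and incomplete (each tree a subset of X). The target
criterion is weighted quartet support: a species tree is good if, summed
over gene trees, the quartets it displays outweigh the quartets it
contradicts. Quartet-based summary estimation is statistically consistent
under the multispecies coalescent (MSC), which motivates the score below.

## Scoring a bipartition directly from gene trees

Each divide step works on a set S of *items*: real taxa plus *dummy taxa*
that stand for the rest of X. A dummy is a rooted recursive structure —
its root's children are the items of the opposite side at the step that
created it; earlier dummies appear as internal subtrees. Every real taxon
a covered by a dummy receives weight

    w(a) = 1 / prod(child counts along the root-to-a path),

and free real taxa have w(a) = 1, so each dummy's covered weights sum to
exactly 1 and the dummy contributes to scores like a single taxon. Weights
are exact `Fraction`s (products of small child counts), converted to
float64 only at the scoring kernel boundary; the per-dummy unit sum is
asserted (tolerance 1e-12) at every divide step.

Relative to a bipartition (A, B) with covered taxon sets FA, FB, a quartet
ab|cd of a gene tree is *satisfied* when its two pairs coincide with the
two sides, *violated* when two taxa sit on each side but mispaired,
*deferred* when three or more of its taxa share a side, and *excluded*
when any two of the four lie under the same current-subproblem dummy (a
dummy must not contribute twice to one quartet). Unresolved quartets of
non-binary trees with two taxa per side form U(g). With quartet weight
w(ab|cd) = w(a)w(b)w(c)w(d),

    Score(A,B,G) = sum_g [ w(S(g)) - w(V(g)) ]
                 = sum_g [ 2 w(S(g)) - w(S∪V∪U)(g) + w(U(g)) ],

and the three retained terms are computable without enumeration:

* **w(S(g))** decomposes over internal nodes ("anchors"): a satisfied
  quartet is counted exactly once, at the unique node whose removal puts
  its FA-side pair into two distinct components and its FB-side pair
  together in a third. One pass over nodes with this orientation covers
  both satisfied orientations — a quartet whose FA pair is the "cd" side
  is picked up at that pair's anchor — so no symmetric second pass is
  taken (a second pass would double-count; the enumeration oracle
  confirms the single-pass sums exactly). Per-node sums reduce to
  products of per-component weight sums; pairs under one dummy are removed
  by per-component, per-dummy subtotals (the (Σw)² − Σw² trick with
  per-dummy corrections).
* **w(S∪V∪U)(g)** = w(PA(g))·w(PB(g)), the product of dummy-excluded pair
  weights of the two sides restricted to the tree's taxa.
* **w(U(g))** is summed over polytomy nodes only, from cross-component
  pair weights of both sides (each unresolved two-per-side quartet has a
  unique node at which all four taxa separate).

The kernel operates on flat per-tree arrays (Euler-tour leaf intervals,
one component table row per node side) and is JIT-compiled with numba.
Accumulation order is fixed (tree order, then node order) so runs are
bit-reproducible. Taxa absent from the current subproblem or tree simply
carry zero weight. The independent ground truth is a Θ(n⁴) enumeration
oracle in exact rational arithmetic (guarded at n ≤ 14) that shares only
the classification function with the production path.

## Seeding and refining bipartitions

A greedy (majority-rule extended) consensus of the full input is computed
once: all non-trivial gene-tree splits are counted, sorted by decreasing
frequency, and inserted greedily into a star over X whenever the growing
tree can display them. For incomplete inputs, splits are partial; a tree
counts toward a split's frequency denominator only when informative for it
(two or more of the split's taxa on each side), and insertion pulls
nested unconstrained taxa along with a cluster. On complete inputs this
reduces to the classical majority-rule extended consensus. Ties are broken
by raw count, smaller-side size, then lexicographic order, making the
consensus deterministic.

Each consensus edge is projected onto the subproblem: real items follow
their side; a dummy follows the side holding the strictly larger weighted
share of its covered taxa, with exact ties to side B. Degenerate
projections (an empty side, or a singleton side when |S| > 3) are skipped;
if no edge projects usably (e.g. a star consensus), candidate splits are
tried in frequency order and finally the items are halved in stable
order. The highest-scoring projection seeds FM.

FM repeatedly applies the maximum-gain move (gain = exact difference of
two full score evaluations), locking each moved item, then rolls back to
the best prefix; passes repeat until no strict improvement (default cap
20 passes, configurable; ample at the problem sizes this tool targets).
Gain ties prefer the more balanced result, then stable item order. Because
gains are always full re-scores, the `fm.debug_full_rescore` mode and the
production path are the same computation.

**Minimum side size.** An accepted prefix (and the initial seed) must
leave at least two items per side. A singleton side always scores exactly
zero — one item forms no pair — so on conflicted subproblems isolating one
item can be the argmax; but accepting it makes no progress: the isolated
item is wrapped into a dummy that behaves identically inside a same-sized
remainder subproblem, and the recursion cycles. Requiring two items per
accepted side guarantees both subproblems strictly shrink (depth < n).
Intermediate pass states may still pass through singleton sides, as in
classical FM balance handling. Pendant attachments lost to this floor
carry no quartet information, so the restriction does not shrink the
reachable topology space.

## Recursion and merging

Subproblems of ≤ 3 items are rooted stars (quartet scores cannot
distinguish three-item resolutions). Otherwise the refined bipartition
(A, B) spawns subproblems A ∪ {X1} and B ∪ {X2}, with X1 wrapping B's
items and X2 wrapping A's. Merging replaces the X1 leaf of the solved A
side by the B-side solution re-rooted at its X2 leaf (unary nodes
suppressed) — the unique interpretation consistent with X1 standing for
"everything in B". The A side recurses first, fixing the output
deterministically. The final tree is emitted rooted but documents an
unrooted estimate; no dummy identifiers can survive merging, and the leaf
set is asserted equal to X.

`--resolve-polytomies` resolves each gene-tree polytomy into a random
caterpillar (seeded) before analysis. Scoring handles polytomies natively,
so the flag is purely a speed strategy; it is a no-op on binary inputs.

## Synthetic data

The simulator emulates topology-level ILS only: a Yule species tree
(pure-birth, exponential waiting times, unit birth rate, time-unit branch
lengths) and a minimal MSC within it — one sampled lineage per species,
pairwise coalescence at rate C(j,2) per coalescent unit, branch lengths
converted by a discordance scaler `ils_scale` (coalescent length =
time / ils_scale). Defaults: n = 16 taxa, 0.2 for moderate discordance
(typical internal branches around 0.5–1 coalescent units, per-triple
match probabilities roughly 0.6–0.9) and 0.02 for weak discordance;
optional independent leaf deletion (`missing_fraction`) and independent
internal-edge contraction (`polytomy_prob`, 0.3 in the polytomy studies).
Its correctness anchor is the standard MSC rooted-triple identity
P(match) = 1 − (2/3)e^(−t), checked by simulation at 10,000 genes.

The simulator omits gene duplication/loss, migration, sequence evolution
and gene-tree estimation error. Passing tests therefore demonstrate
correctness of the algorithm under clean topology-level discordance, not
robustness to estimation error in real pipelines.

## Numerical choices and problem sizes

Scores are float64; all cross-checks against the exact oracle use an
absolute tolerance of 1e-9 (observed discrepancies are below 1e-13). FM
accepts an improvement only beyond 1e-12 to keep tie handling stable.
Evaluation uses normalized Robinson–Foulds distance (symmetric difference
over the total non-trivial bipartitions of both trees) and two-sided
paired Wilcoxon signed-rank tests (α = 0.05) via scipy; an all-zero
difference vector is reported as undefined rather than p = 1.

The verification suite and `scripts/acceptance.py` use: 500 randomized
scoring instances (n ∈ [4,12], k ∈ [1,20], ≤ 40% missing taxa, polytomies,
dummy nesting depth ≤ 3) for oracle agreement; 100 instances with every
legal move for gain exactness; 20 concordant-input recovery cases
(n ∈ {8,16,32,50}, k = 10); and 10-replicate MSC studies at n = 16 with
k ∈ {25, 200}. These sizes exercise every code path (the oracle, not the
scale, is the limiting factor) and complete in a few minutes on one CPU.

## Known limitations

* Heuristic search: FM with a consensus seed has no optimality guarantee
  for the maximum quartet support problem (which is NP-hard).
* Single-copy gene trees only; no support-value weighting of quartets and
  no branch-support annotation on the output.
* The greedy consensus on heavily incomplete inputs uses informative-tree
  frequencies and cluster insertion; other extended-majority conventions
  exist and can seed FM differently (the refinement step reduces the
  sensitivity to this choice).
* The output root placement is arbitrary; only the unrooted topology is
  estimated.
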