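# wqfmtree

Quartet-based species tree estimation from gene trees, for phylogenomics
practitioners summarizing many single-copy gene trees — possibly
non-binary and missing taxa — into one species tree under gene-tree
discordance caused by incomplete lineage sorting (ILS).

## The method

Given unrooted gene trees *G* = {g₁…g_k} on taxon set *X* (|X| = n), the
estimator searches for a species tree maximizing weighted quartet support.
Instead of materializing the Θ(n⁴) induced quartets, it recursively
bipartitions the taxon set with the Fiduccia–Mattheyses (FM) heuristic,
scoring each candidate bipartition (A, B) directly from the gene trees:

    Score(A, B, G) = Σ_g [ w(S(g)) − w(V(g)) ]
                   = Σ_g [ 2·w(S(g)) − w(S(g) ∪ V(g) ∪ U(g)) + w(U(g)) ]

where S(g), V(g) are the satisfied and violated resolved quartets of g
relative to (A, B), U(g) the two-per-side unresolved quartets of non-binary
trees, and quartet weights are products of per-taxon weights. Each divide
step replaces the opposite side by a recursive "dummy taxon" whose covered
taxa share one unit of weight (w(a) is the reciprocal of the product of
child counts along the root-to-leaf path of the dummy structure). The
satisfied weight decomposes over internal nodes of each gene tree (each
satisfied quartet is counted once at the anchor node adjacent to its
A-side pair), the total S ∪ V ∪ U weight is a closed-form pair-weight
product, and the unresolved weight is accumulated over polytomy nodes
only. A greedy (majority-rule extended) consensus of the input seeds every
divide step; FM moves with exact gains refine it; solved subproblems are
spliced together at their dummy leaves. With resolved gene trees and
balanced subproblems the recursion runs in O(n³ k log n).

A Θ(n⁴) enumeration oracle (exact rational arithmetic) backs the entire
scoring path in the test suite, and a built-in Yule + multispecies
coalescent simulator generates test data with controllable ILS, missing
taxa, and polytomies.

## Worked example

Simulate a 12-taxon, 100-gene replicate with moderate ILS, infer, and
compare with the true tree:

```sh
$ wqfm-tree simulate --n 12 --k 100 --ils 0.3 --seed 42 -o demo/
wrote demo/truth.nwk and demo/genetrees.nwk
$ wqfm-tree infer -i demo/genetrees.nwk -o demo/species.nwk --seed 1
$ cat demo/species.nwk
(T11,T6,(T5,(T3,(((T10,T9),(T8,(T1,T4))),(T2,(T12,T7))))));
$ wqfm-tree eval demo/species.nwk demo/truth.nwk
0.000000
```

The inferred Newick tree is written rooted as produced by the recursion
but should be read as an unrooted topology. The `eval` output is the
normalized Robinson–Foulds distance (bipartition symmetric difference over
the total non-trivial bipartitions of both trees): `0.000000` means the
estimate is topologically identical to the generating species tree.

Useful options: `--resolve-polytomies` (arbitrarily resolves gene-tree
polytomies first — a speed strategy; scoring handles polytomies natively),
`--max-passes` (FM pass budget per divide step), `--dump-consensus FILE`
(inspect the greedy consensus seed). The same functionality is available
as a library (`wqfmtree.run`, `wqfmtree.score_bipartition`,
`wqfmtree.simulate_gene_trees`, ...).

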