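# gtcorrect

Gene-tree preprocessing for duplication–loss reconciliation and species-tree
inference.

## The problem

Reconciling a gene tree *T* with a species tree *S* under the
duplication–loss parsimony model explains their incongruence by gene
duplications and losses: every vertex of *T* is mapped to the lowest common
ancestor (LCA) in *S* of the genomes below it, a vertex *t* being a
**duplication** when one of its children maps to the same species vertex
(*d(T,S)* counts them), and each edge whose mapping jumps over species
vertices hiding **losses**. The weakness of reconciliation is its
sensitivity to gene-tree error: a single misplaced leaf can inflate the
inferred history dramatically.

Duplication vertices split into two classes:

* **AD** (apparent duplication): the child genome sets intersect — a
  duplication under *every* species tree, forced by the data.
* **NAD** (non-apparent duplication): disjoint child genome sets.  Every NAD
  vertex witnesses a species triplet {a,b;c} grouped one way by the gene
  tree and another way by the species tree — a phylogenetic contradiction
  that is *not* explained by duplicated copies, and hence a plausible
  footprint of a misplaced leaf.

A gene tree whose only duplications are AD vertices is **MD-consistent**
with *S*.  `gtcorrect` removes a minimum number of leaves (or species) to
reach MD-consistency:

* **Known species tree** — `correct_tree` collapses every maximal NAD-free
  subtree rooted at an AD vertex into a weighted leaf (the *induced weighted
  tree*, weights = copy numbers), then solves the **weighted maximum
  agreement subtree** (WMAST) problem between each maximal AD-free subtree
  and *S*, removing the leaves outside the agreement, and recurses.  The
  procedure is exact for uniquely leaf-labelled trees (it reduces to plain
  MAST) and for trees with no AD vertex above a NAD vertex; otherwise it is
  a near-optimal heuristic.
* **Unknown species tree** — group the forest's non-AD vertices into levels,
  record their child genome sets as hyperedges; all vertices of a level can
  be speciations iff the level hypergraph is disconnected.  Connected levels
  force the removal of a minimum species **vertex cut** (computed by s–t
  max-flow on the clique expansion).  The recursive component construction
  both decides the MD-forest property and produces a certifying species
  tree.  The known-species-tree variant reduces to this one by adding *S*
  to the forest.

## Worked example

The species tree for three genomes is `((1,2),3)` and the gene family has
one copy per genome.  If the copy from genome 3 attaches as the sibling of
copy 1 — gene tree `((1,3),2)` — the root becomes a NAD vertex:

```python
>>> import gtcorrect as gt
>>> S = gt.parse_newick("((1,2),3);")
>>> T = gt.parse_newick("((1,3),2);")
>>> ev = gt.classify_events(T, S)
>>> ev.dup_count, ev.ad_count, ev.nad_count
(1, 0, 1)
>>> gt.loss_cost(T, S), gt.mutation_cost(T, S)
(3, 4)
>>> gt.build_reconciliation(T, S).newick()
'(((1,LOSS:2),3),((LOSS:1,2),LOSS:3));'
>>> gt.wrong_triplet(T, S, T.root)
(('1', '2', '3'), frozenset({'1', '3'}), frozenset({'1', '2'}))
>>> gt.correct_tree(T, S).removals
1
```

One misplaced leaf turned a zero-event history into 1 duplication + 3
losses (mutation cost 4); the corrector recognises that removing a single
leaf restores MD-consistency.  The same is available from the shell:

```
gtcorrect classify -g gene.nwk -s species.nwk
gtcorrect correct  -g gene.nwk -s species.nwk --exact
gtcorrect minsri   -f forest.nwk --species-tree inferred.nwk
```

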