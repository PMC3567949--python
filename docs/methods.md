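# Methods

## Model

A gene tree is a rooted binary tree whose leaves are labelled by genomes
(labels may repeat: several copies of the gene in one genome); a species
tree is rooted binary and uniquely labelled.  The LCA mapping M sends each
gene-tree vertex to the lowest common ancestor in S of its genome set; t is
a duplication iff M(t_l) = M(t) or M(t_r) = M(t).  Duplications whose child
genome sets intersect are apparent (AD) — they are duplications under every
species tree; those with disjoint child genome sets are non-apparent (NAD)
and each exhibits a species triplet grouped differently by T and S.  A tree
(or forest) is MD-consistent with S when it has no NAD vertex, i.e.
d(T,S) equals its AD count, the minimum over all species trees.

Losses are counted on the LCA reconciliation: for each gene-tree edge
(p,u), dist_S(M(p),M(u)) − 1 lost lineages, plus one when p is a
duplication; nothing is charged above the gene-tree root.
`build_reconciliation` materializes the same count as grafted copies of
the missing species subtrees, and `is_ds_consistent` verifies the
resulting extension vertex by vertex, so the closed-form edge sum and the
explicit construction check each other in the tests.

## Correction with a known species tree

`correct_tree` iterates: (1) stop when MD-consistent; (2) build T^I by
replacing every maximal ONLY-AD subtree (rooted at an AD vertex, no NAD
inside) by its induced weighted tree — the species tree restricted to the
subtree's genomes, leaf weights = copy numbers; (3) for each root of a
maximal AD-free subtree of T^I, solve WMAST against S and delete the
leaves outside the agreement (deleting a weighted leaf deletes every copy
it stands for); (4) recurse.  Correctness of the stop condition is checked
on every run.  Two properties drive exactness on the tractable classes:
uniquely leaf-labelled trees reduce to one MAST call, and trees with no AD
above a NAD reduce to one WMAST call on T^I.

Degenerate cases: NAD-border elements that are leaves or already
MD-consistent subtrees are skipped (their WMAST would be the identity).  If
a full pass removed nothing while NADs remain — impossible when every
non-MD border subtree loses a leaf, which WMAST guarantees, but guarded
anyway — the highest NAD's wrong triplet is broken directly by deleting all
copies of its smallest species below that vertex, which removes at least
one leaf and so forces termination.

WMAST is the Steel–Warnow-style O(n²) subtree-pair dynamic program with
the leaf base case scoring the leaf weight.  The caterpillar expansion
(each weight-c leaf blown into c unit leaves in both trees) is implemented
independently and kept as a cross-check: the weighted DP and
compress∘MAST∘expand must agree, and an agreement subtree of the expansion
must keep all or none of each caterpillar.  Ties between equal-score
agreement sets are broken toward the lexicographically smallest kept label
set, making every output deterministic.  Tie-breaking can change *which*
leaves are removed, never how many on the exact classes; on general trees
the greedy, locally-tied choice is exactly where the heuristic can exceed
the optimum.

`exact_min_removals` is the reference optimum: ascending enumeration of
leaf subsets (k = 0, 1, 2, …) with a configurable cap on examined subsets;
it is used by the optimality study and as the oracle in the exactness
tests.  Plain enumeration was preferred over wrong-triplet-guided pruning
because the soundness of such pruning across recursive NAD creation is not
established, and at the study sizes (≤ 14 leaves) enumeration is cheap.

`min_species_removal_correct` handles species-level removal under
Constraint C (no AD above NAD): unweighted MAST on T^I, so whole species
are kept or dropped.

## Species-tree inference side

Levels: level 0 holds the highest non-AD vertices of every tree (AD-ness
here is species-tree-free: child genome sets intersect); level j holds the
closest non-AD internal descendants of level j−1.  The level-j hypergraph
has one hyperedge per child genome set of each level vertex; its vertex set
is the union of those hyperedges rather than the whole genome set —
species untouched by a level would otherwise disconnect it vacuously and
the cut condition would never fire.  Connectivity and cuts are computed on
the clique expansion (networkx); the minimum vertex cut scans all
non-adjacent s–t pairs with vertex-capacity max-flow and breaks ties toward
the lexicographically smallest cut.  When the expansion is a complete graph
no cut exists; the species with the fewest leaf occurrences (ties
lexicographic) is removed instead so the loop always progresses.

After the level sweep the result is certified by `infer_md_species_tree`:
recursively, the level-0 hyperedges of the restricted forest must leave the
species disconnected; components are solved recursively and joined by a
left-deep caterpillar backbone in lexicographic order (any resolution that
separates components turns the level's vertices into speciations).  The
certificate d(T_i, S*) = AD-count(T_i) is always evaluated; on failure the
construction returns null and the sweep re-runs on the smaller genome set.
Termination is guaranteed because every pass that fails certification
removes at least one species and every forest on ≤ 2 species is an
MD-forest (a NAD needs a triplet).

MINSRR (known S) runs MINSRI on the forest plus S itself: a certificate
for the enlarged forest must agree with S restricted to the kept species
(d(S|kept, S*) = 0 forces S* ≅ S|kept), so the restricted forest is
MD-consistent with the restricted S.

## Random generators

Random topologies use sequential uniform random-edge insertion (root edge
included), which is uniform over rooted binary labelled topologies; gene
trees draw labels uniformly with replacement.  MD-consistent trees start
from S and repeatedly replace a uniform leaf by a cherry of two copies —
every step adds one AD vertex, so validity holds by construction and the
size is controlled one leaf at a time.  Perturbations graft leaves with
uniform labels onto uniform edges.  All generators take an integer seed
and are bit-reproducible.

What the generators do not emulate: gene loss (generated MD trees contain
every species), subtree-scale duplications, any non-uniform tree shape
(e.g. Yule), and sequence-level error; passing simulations therefore show
the algorithmic claims (exactness, certificates, near-optimality) rather
than performance on real gene families.

## Study parameters

* Optimality study: genome set of 5, tree sizes 6–14 step 2, 100 trees per
  size, retaining trees with an AD vertex above a NAD vertex; reports the
  overall exact-match percentage (heuristic N = exhaustive N_opt) and the
  per-size mean error rate (N − N_opt)/N.  These sizes keep the
  exhaustive oracle exact on every retained trial.
* Detection study: genome set of 10, sizes 10–100 step 10, 20 trials per
  size, NbAdded = size/10 planted leaves; reports (N/NbAdded)×100 averaged
  with and without the trials whose perturbed tree stayed MD-consistent.

Both aggregates are sensitive to the random-tree model, which is part of
the study definition here.  Under these generators the exact-match
percentage sits around 65–75 % and the per-size mean error rate around
0.09–0.18 (largest at size 6, where a single excess removal weighs most);
the excluded-average detection percentage sits around 55–65 % and decreases
with tree size, the small-size end being pinned near 100 % because a
non-MD perturbed tree of size 10 has NbAdded = 1 and needs at least one
removal.  Alternative generators that were evaluated (subtree duplication
instead of leaf duplication for MD trees; Yule instead of uniform species
trees) both *raise* the detection average, so the defaults are kept as the
most conservative of the plausible models.

## Known limitations

* Correct-Tree is a heuristic on trees with AD above NAD; the error is
  concentrated in WMAST ties and repeated passes, not in tree size.
* Exact MINSRI/MINLRI are not attempted (the underlying problems are
  NP-hard); only the greedy level-cut heuristic with certificates.
* All optimal removal sets are not enumerated; one deterministic optimum
  is reported.
* Reconciliations are LCA-only; no transfer events, no non-binary trees.
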