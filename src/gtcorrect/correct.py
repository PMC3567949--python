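"""Gene-tree correction against a known species tree.

The goal is to delete as few leaves (or species) as possible so that the
gene tree has no NAD vertex with respect to the species tree S.  The engine
is the recursive procedure:

1. Stop if the tree is already MD-consistent with S.
2. Collapse every maximal subtree that is rooted at an AD vertex and
   contains no NAD (the *AD border*) into its *induced weighted tree*: the
   species tree restricted to the subtree's genomes, each leaf weighted by
   its copy number.  The result T^I is uniquely leaf-labelled wherever it
   was rewritten.
3. For every root x of a maximal AD-free subtree of T^I (the *NAD
   border*), solve weighted MAST between the subtree at x and S; drop the
   leaves outside the agreement (a weighted leaf stands for all copies of
   its species in the collapsed region), accumulating v(T_x^I) - v(W_x^MAX)
   removals.
4. Recurse on the reduced tree.

The procedure is exact when the tree is uniquely leaf-labelled (it is a
single MAST call) and, more generally, whenever no AD vertex lies above a
NAD vertex ("Constraint C"); otherwise it is a heuristic whose excess over
the exhaustive optimum is measured by the simulation experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

from .agreement import WeightedTree, mast, wmast
from .errors import ResourceError, TreeDomainError
from .reconcile import Event, classify_events, is_md_consistent, wrong_triplet
from .treeio import Tree

__all__ = [
    "CorrectionReport",
    "AnnotatedTree",
    "ad_border",
    "nad_border",
    "induced_weighted_tree",
    "build_TI",
    "satisfies_constraint_c",
    "correct_tree",
    "exact_min_removals",
    "min_species_removal_correct",
]


@dataclass
class CorrectionReport:
    removals: int
    removed_leaves: list[tuple[int, str]]  # (leaf node id in the input tree, label)
    corrected: Tree
    iterations: int


@dataclass
class AnnotatedTree:
    """T^I: the gene tree with AD-border subtrees collapsed to weighted leaves.

    ``origin`` maps every leaf of ``tree`` back to the input-tree leaf ids
    it stands for (a single id for untouched leaves, all copies of a
    species within the collapsed region for weighted leaves); ``weights``
    is the corresponding copy count.
    """

    tree: Tree
    weights: dict[int, int]
    origin: dict[int, tuple[int, ...]]
    replaced_roots: frozenset[int] = frozenset()

    @property
    def value(self) -> int:
        return sum(self.weights.values())


def _events(T: Tree, S: Tree):
    return classify_events(T, S)


def ad_border(T: Tree, S: Tree) -> list[int]:
    """Roots of the maximal subtrees rooted at an AD vertex with no NAD inside."""
    ev = _events(T, S)
    has_nad: dict[int, bool] = {}
    for v in T.postorder():
        if T.is_leaf(v):
            has_nad[v] = False
        else:
            a, b = T.children(v)
            has_nad[v] = (ev.events[v] is Event.NAD) or has_nad[a] or has_nad[b]
    border: list[int] = []

    def walk(v: int):
        if T.is_leaf(v):
            return
        if ev.events[v] is Event.AD and not has_nad[v]:
            border.append(v)
            return
        for c in T.children(v):
            walk(c)

    walk(T.root)
    return border


def nad_border(T: Tree, S: Tree) -> list[int]:
    """Roots of the maximal AD-free subtrees, in left-to-right order."""
    ev = _events(T, S)
    has_ad: dict[int, bool] = {}
    for v in T.postorder():
        if T.is_leaf(v):
            has_ad[v] = False
        else:
            a, b = T.children(v)
            has_ad[v] = (ev.events[v] is Event.AD) or has_ad[a] or has_ad[b]
    border: list[int] = []

    def walk(v: int):
        if not has_ad[v]:
            border.append(v)
            return
        for c in T.children(v):
            walk(c)

    walk(T.root)
    return border


def induced_weighted_tree(U: Tree, S: Tree) -> WeightedTree:
    """S restricted to L(U), each leaf weighted by its copy count in U."""
    shape = S.restrict_to(U.labels())
    assert shape is not None
    counts: dict[str, int] = {}
    for v in U.leaves():
        counts[U.label(v)] = counts.get(U.label(v), 0) + 1
    weights = {v: counts[shape.label(v)] for v in shape.leaves()}
    return WeightedTree(shape, weights)


def build_TI(T: Tree, S: Tree) -> AnnotatedTree:
    """Collapse every AD-border subtree of T into its induced weighted tree."""
    border = set(ad_border(T, S))

    children: dict[int, tuple[int, int]] = {}
    labels: dict[int, str] = {}
    weights: dict[int, int] = {}
    origin: dict[int, tuple[int, ...]] = {}
    replaced: set[int] = set()
    counter = [max(T.nodes()) + 1]

    def fresh() -> int:
        counter[0] += 1
        return counter[0] - 1

    def copy_weighted(w: WeightedTree, copies: dict[str, tuple[int, ...]], v: int) -> int:
        nid = fresh()
        if w.tree.is_leaf(v):
            lbl = w.tree.label(v)
            labels[nid] = lbl
            weights[nid] = w.weights[v]
            origin[nid] = copies[lbl]
        else:
            a, b = w.tree.children(v)
            children[nid] = (
                copy_weighted(w, copies, a),
                copy_weighted(w, copies, b),
            )
        return nid

    def build(v: int) -> int:
        if v in border:
            sub = T.subtree(v)
            w = induced_weighted_tree(sub, S)
            copies: dict[str, tuple[int, ...]] = {}
            for leaf in sub.leaves():
                copies.setdefault(sub.label(leaf), ())
                copies[sub.label(leaf)] += (leaf,)
            nid = copy_weighted(w, copies, w.tree.root)
            replaced.add(nid)
            return nid
        if T.is_leaf(v):
            labels[v] = T.label(v)
            weights[v] = 1
            origin[v] = (v,)
            return v
        a, b = T.children(v)
        children[v] = (build(a), build(b))
        return v

    root = build(T.root)
    if root in labels and not children:
        tree = Tree({}, {root: labels[root]}, root)
    else:
        tree = Tree(children, labels, root)
    return AnnotatedTree(tree, weights, origin, frozenset(replaced))


def satisfies_constraint_c(T: Tree, S: Tree) -> bool:
    """True iff no AD vertex is a proper ancestor of a NAD vertex."""
    ev = _events(T, S)
    has_nad: dict[int, bool] = {}
    for v in T.postorder():
        if T.is_leaf(v):
            has_nad[v] = False
        else:
            a, b = T.children(v)
            has_nad[v] = (ev.events[v] is Event.NAD) or has_nad[a] or has_nad[b]
    for v, e in ev.events.items():
        if e is Event.AD:
            a, b = T.children(v)
            if has_nad[a] or has_nad[b]:
                return False
    return True


def correct_tree(T: Tree, S: Tree) -> CorrectionReport:
    """Remove leaves until T is MD-consistent with S.

    Exact for uniquely leaf-labelled trees and for trees with no AD vertex
    above a NAD vertex; a heuristic otherwise.  Removed leaves are reported
    by their (stable) node id in the input tree together with their label.
    """
    removed: list[tuple[int, str]] = []
    current = T
    iterations = 0
    while not is_md_consistent(current, S):
        iterations += 1
        ti = build_TI(current, S)
        ev = classify_events(ti.tree, S)
        to_drop: set[int] = set()  # leaf ids of ti.tree
        for x in nad_border(ti.tree, S):
            if ti.tree.is_leaf(x):
                continue
            sub_nodes = set(ti.tree.preorder(x))
            if not any(ev.events.get(v) is Event.NAD for v in sub_nodes):
                continue  # already MD-consistent: the loop is a no-op here
            sub = ti.tree.subtree(x)
            res = wmast(WeightedTree(sub, {v: ti.weights[v] for v in sub.leaves()}), S)
            for leaf in sub.leaves():
                if sub.label(leaf) not in res.kept_leaves:
                    to_drop.add(leaf)
        if not to_drop:
            # Termination guard (cannot trigger when every non-MD border
            # subtree loses at least one leaf, which the weighted MAST
            # guarantees): break the highest NAD directly by deleting one
            # species of its wrong triplet below it.
            x = next(
                v for v in ti.tree.preorder() if ev.events.get(v) is Event.NAD
            )
            trip, t_pair, _ = wrong_triplet(ti.tree, S, x)
            target = min(trip)
            for leaf in ti.tree.leaves(x):
                if ti.tree.label(leaf) == target:
                    to_drop.add(leaf)
        gone: list[int] = []
        for leaf in to_drop:
            gone.extend(ti.origin[leaf])
        for g in sorted(gone):
            removed.append((g, current.label(g)))
        current = current.remove_leaves(gone)
        assert current is not None
    return CorrectionReport(
        removals=len(removed),
        removed_leaves=removed,
        corrected=current,
        iterations=iterations,
    )


def exact_min_removals(
    T: Tree, S: Tree, cap: int = 2_000_000
) -> tuple[int, tuple[int, ...]]:
    """Smallest number of leaf removals making T MD-consistent with S.

    Searches subsets of leaves in ascending cardinality; returns the count
    and one witness subset of leaf ids.  ``cap`` bounds the number of
    subsets examined.
    """
    if is_md_consistent(T, S):
        return 0, ()
    leaves = T.leaves()
    examined = 0
    for k in range(1, T.size - 1):
        for subset in combinations(leaves, k):
            examined += 1
            if examined > cap:
                raise ResourceError(
                    f"exhaustive search exceeded cap={cap} subsets (n={T.size}, k={k})"
                )
            r = T.remove_leaves(subset)
            if r is not None and is_md_consistent(r, S):
                return k, subset
    # removing all but two leaves always succeeds, so we never get here
    raise AssertionError("unreachable: a 2-leaf tree is MD-consistent")


def min_species_removal_correct(T: Tree, S: Tree) -> tuple[frozenset[str], Tree]:
    """Minimum species removal for a tree with no AD above a NAD.

    Runs unweighted MAST on T^I (weights ignored), so whole species are
    kept or dropped; exact under Constraint C.  Returns the removed species
    and the corrected tree.
    """
    if not satisfies_constraint_c(T, S):
        raise TreeDomainError(
            "tree has an AD vertex above a NAD vertex; use the species-removal "
            "inference reduction (minsrr_via_minsri) instead"
        )
    if is_md_consistent(T, S):
        return frozenset(), T
    ti = build_TI(T, S)
    res = mast(ti.tree, S)
    removed = frozenset(T.labels() - res.kept_leaves)
    corrected = T.restrict_to(res.kept_leaves)
    assert corrected is not None
    return removed, corrected
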