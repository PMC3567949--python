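"""Maximum agreement subtrees of two rooted binary trees.

``mast`` computes the classic maximum agreement subtree of a uniquely
leaf-labelled gene tree and a species tree with the quadratic subtree-pair
dynamic program (Steel–Warnow style): for every pair (u, v) of a gene-tree
node and a species-tree node the best agreement confined to leaves below
both is the maximum over descending into either child, or matching the two
child pairs straight or crossed.

``wmast`` is the weighted generalization: each leaf carries a positive
integer weight (the number of collapsed gene copies it stands for) and the
objective is total kept weight.  The same recurrence applies with the leaf
base case scoring the weight instead of 1.

``expand``/``compress`` give the independent reduction of WMAST to MAST: a
leaf of weight c is blown up into a caterpillar of c unit leaves in both
trees; a maximum agreement subtree of the expansion keeps all or none of
each caterpillar, so collapsing it back solves the weighted problem.  The
two routes are kept separate so they can check each other.

Ties between equal-score agreement sets are broken deterministically in
favour of the lexicographically smallest kept label set.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Optional

from .errors import TreeDomainError
from .treeio import Tree

__all__ = ["WeightedTree", "AgreementResult", "mast", "wmast", "expand", "compress"]


@dataclass
class WeightedTree:
    """A uniquely leaf-labelled tree with positive integer leaf weights."""

    tree: Tree
    weights: dict[int, int]  # leaf id -> weight

    def __post_init__(self):
        leaves = self.tree.leaves()
        if len({self.tree.label(v) for v in leaves}) != len(leaves):
            raise TreeDomainError("weighted trees must be uniquely leaf-labelled")
        for v in leaves:
            w = self.weights.setdefault(v, 1)
            if w < 1:
                raise TreeDomainError(f"leaf weight must be >= 1, got {w}")

    @property
    def value(self) -> int:
        """v(W): sum of the leaf weights."""
        return sum(self.weights[v] for v in self.tree.leaves())

    def weight_of(self, label: str) -> int:
        for v in self.tree.leaves():
            if self.tree.label(v) == label:
                return self.weights[v]
        raise KeyError(label)

    @classmethod
    def unit(cls, tree: Tree) -> "WeightedTree":
        return cls(tree, {v: 1 for v in tree.leaves()})

    def newick(self) -> str:
        return self.tree.newick(weights=self.weights)


@dataclass
class AgreementResult:
    kept_leaves: frozenset[str]
    subtree: Optional[Tree]  # None when nothing is kept
    score: int


def _agree(T: Tree, weight_by_label: Mapping[str, int], S: Tree) -> tuple[int, frozenset[str]]:
    """Core weighted agreement DP; returns (score, kept label set)."""
    t_nodes = list(T.postorder())
    s_nodes = list(S.postorder())
    t_gs = {u: T.genome_set(u) for u in t_nodes}
    s_gs = {v: S.genome_set(v) for v in s_nodes}

    score: dict[tuple[int, int], int] = {}
    for u in t_nodes:
        for v in s_nodes:
            common = t_gs[u] & s_gs[v]
            if not common:
                score[u, v] = 0
                continue
            if T.is_leaf(u):
                score[u, v] = weight_by_label[T.label(u)]
                continue
            if S.is_leaf(v):
                score[u, v] = weight_by_label[S.label(v)]
                continue
            u1, u2 = T.children(u)
            v1, v2 = S.children(v)
            score[u, v] = max(
                score[u1, v], score[u2, v], score[u, v1], score[u, v2],
                score[u1, v1] + score[u2, v2],
                score[u1, v2] + score[u2, v1],
            )

    @lru_cache(maxsize=None)
    def kept(u: int, v: int) -> tuple[str, ...]:
        """Kept labels realizing score[u,v]; lexicographically smallest."""
        best = score[u, v]
        if best == 0:
            return ()
        if T.is_leaf(u):
            return (T.label(u),)
        if S.is_leaf(v):
            return (S.label(v),)
        u1, u2 = T.children(u)
        v1, v2 = S.children(v)
        candidates = []
        for s, parts in (
            (score[u1, v], ((u1, v),)),
            (score[u2, v], ((u2, v),)),
            (score[u, v1], ((u, v1),)),
            (score[u, v2], ((u, v2),)),
            (score[u1, v1] + score[u2, v2], ((u1, v1), (u2, v2))),
            (score[u1, v2] + score[u2, v1], ((u1, v2), (u2, v1))),
        ):
            if s == best:
                lab: tuple[str, ...] = ()
                for p in parts:
                    lab = tuple(sorted(lab + kept(*p)))
                candidates.append(lab)
        return min(candidates)

    best = score[T.root, S.root]
    return best, frozenset(kept(T.root, S.root))


def mast(T: Tree, S: Tree) -> AgreementResult:
    """Maximum agreement subtree of a uniquely leaf-labelled T and S.

    The kept leaf set is the largest set on which T and S restrict to the
    same rooted tree; equivalently, T restricted to it is MD-consistent
    with S without any duplication at all.
    """
    leaves = T.leaves()
    if len({T.label(v) for v in leaves}) != len(leaves):
        raise TreeDomainError(
            "mast requires a uniquely leaf-labelled tree; use wmast on the induced weighted tree"
        )
    return wmast(WeightedTree.unit(T), S)


def wmast(W: WeightedTree, S: Tree) -> AgreementResult:
    """Weighted maximum agreement subtree (maximize total kept weight)."""
    wbl = {W.tree.label(v): W.weights[v] for v in W.tree.leaves()}
    score, kept = _agree(W.tree, wbl, S)
    sub = W.tree.restrict_to(kept) if kept else None
    return AgreementResult(kept_leaves=kept, subtree=sub, score=score)


# ---------------------------------------------------------------------------
# Caterpillar expansion: WMAST as plain MAST on blown-up trees
# ---------------------------------------------------------------------------


def _expanded_label(g: str, i: int) -> str:
    return f"{g}#{i}"


def _caterpillar(g: str, c: int):
    """Nested spec of the caterpillar (g_c,(...,(g_2,g_1)...))."""
    spec = _expanded_label(g, 1)
    for i in range(2, c + 1):
        spec = (_expanded_label(g, i), spec)
    return spec


def expand(W: WeightedTree, S: Tree) -> tuple[Tree, Tree]:
    """Blow each weight-c leaf up into a caterpillar of c unit leaves.

    The replacement happens in both the weighted tree and the species tree,
    over the expanded genome set {g#1..g#c}; unit-weight leaves are renamed
    to g#1 so both outputs are uniquely leaf-labelled over the same set.
    """
    by_label = {W.tree.label(v): W.weights[v] for v in W.tree.leaves()}

    def rebuild(t: Tree, v: int):
        if t.is_leaf(v):
            g = t.label(v)
            c = by_label.get(g, 1)
            return _caterpillar(g, c)
        a, b = t.children(v)
        return (rebuild(t, a), rebuild(t, b))

    return (
        Tree.from_nested(rebuild(W.tree, W.tree.root)),
        Tree.from_nested(rebuild(S, S.root)),
    )


def compress(result: AgreementResult, W: WeightedTree) -> AgreementResult:
    """Collapse an agreement subtree of the expansion back to weighted leaves.

    A maximum agreement subtree of the expanded trees keeps all or none of
    each caterpillar (keeping part of one could always be extended); this
    is asserted, then each kept caterpillar is recovered as one weighted
    leaf.
    """
    by_label = {W.tree.label(v): W.weights[v] for v in W.tree.leaves()}
    kept_counts: dict[str, int] = {}
    for lbl in result.kept_leaves:
        g = lbl.rsplit("#", 1)[0]
        kept_counts[g] = kept_counts.get(g, 0) + 1
    for g, k in kept_counts.items():
        if k != by_label[g]:
            raise AssertionError(
                f"agreement subtree kept {k} of {by_label[g]} copies of expanded leaf {g}"
            )
    kept = frozenset(kept_counts)
    sub = W.tree.restrict_to(kept) if kept else None
    score = sum(by_label[g] for g in kept)
    return AgreementResult(kept_leaves=kept, subtree=sub, score=score)
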