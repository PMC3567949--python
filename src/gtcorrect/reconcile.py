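"""LCA reconciliation of a gene tree with a species tree.

Every gene-tree vertex is mapped to the lowest common ancestor in the
species tree of the genomes below it.  A vertex whose child mapping
collides with its own mapping is a duplication; duplications split into

* **AD** (apparent duplication): the child genome sets intersect, i.e. the
  two sides carry copies in a common genome.  An AD vertex is a duplication
  under *every* species tree.
* **NAD** (non-apparent duplication): disjoint child genome sets.  A NAD
  vertex witnesses a species triplet on which the gene tree and the species
  tree disagree, and is the signal used for gene-tree correction.

A gene tree is *MD-consistent* with S when it has no NAD vertex with
respect to S, i.e. the duplication cost d(T,S) equals the number of AD
vertices — the smallest it could be under any species tree.

The LCA mapping induces the reconciliation that minimizes duplications,
losses and their sum (the mutation cost); ``build_reconciliation``
materializes it as an extension of T with one grafted "lost" subtree per
loss, and ``loss_cost`` counts the same losses by the per-edge path-length
formula without building the extension.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

from .errors import LabelError, TreeDomainError
from .treeio import Tree

__all__ = [
    "Event",
    "LcaMap",
    "EventTable",
    "Reconciliation",
    "lca_map",
    "classify_events",
    "build_reconciliation",
    "loss_cost",
    "mutation_cost",
    "is_ds_consistent",
    "is_md_consistent",
    "wrong_triplet",
]


class Event(enum.Enum):
    SPECIATION = "speciation"
    AD = "AD"
    NAD = "NAD"


class _SpeciesIndex:
    """Depth/parent index of a species tree for LCA queries."""

    def __init__(self, S: Tree):
        self.S = S
        self.depth: dict[int, int] = {S.root: 0}
        for v in S.preorder():
            for c in S.children(v):
                self.depth[c] = self.depth[v] + 1
        self.leaf_of: dict[str, int] = {}
        for v in S.leaves():
            self.leaf_of[S.label(v)] = v

    def lca(self, a: int, b: int) -> int:
        while a != b:
            if self.depth[a] >= self.depth[b]:
                a = self.S.parent(a)
            else:
                b = self.S.parent(b)
        return a

    def dist(self, anc: int, desc: int) -> int:
        """Edge count between a vertex and one of its descendants."""
        return self.depth[desc] - self.depth[anc]


@dataclass
class LcaMap:
    """LCA mapping M: gene-tree node -> species-tree node."""

    gene_tree: Tree
    species_tree: Tree
    mapping: dict[int, int]
    _index: _SpeciesIndex

    def __getitem__(self, v: int) -> int:
        return self.mapping[v]


@dataclass
class EventTable:
    events: dict[int, Event]
    ad_count: int
    nad_count: int

    @property
    def dup_count(self) -> int:
        """d(T,S): the duplication cost of the LCA reconciliation."""
        return self.ad_count + self.nad_count

    def is_duplication(self, v: int) -> bool:
        return self.events.get(v) in (Event.AD, Event.NAD)


def lca_map(T: Tree, S: Tree) -> LcaMap:
    idx = _SpeciesIndex(S)
    mapping: dict[int, int] = {}
    for v in T.postorder():
        if T.is_leaf(v):
            lbl = T.label(v)
            leaf = idx.leaf_of.get(lbl)
            if leaf is None:
                raise LabelError(f"gene-tree label {lbl!r} absent from the species tree")
            mapping[v] = leaf
        else:
            a, b = T.children(v)
            mapping[v] = idx.lca(mapping[a], mapping[b])
    return LcaMap(T, S, mapping, idx)


def classify_events(T: Tree, S: Tree, m: Optional[LcaMap] = None) -> EventTable:
    """Label every internal vertex SPECIATION, AD or NAD."""
    if m is None:
        m = lca_map(T, S)
    events: dict[int, Event] = {}
    ad = nad = 0
    for v in T.postorder():
        if T.is_leaf(v):
            continue
        a, b = T.children(v)
        if m[a] == m[v] or m[b] == m[v]:
            if T.genome_set(a) & T.genome_set(b):
                events[v] = Event.AD
                ad += 1
            else:
                events[v] = Event.NAD
                nad += 1
        else:
            events[v] = Event.SPECIATION
    return EventTable(events, ad, nad)


# ---------------------------------------------------------------------------
# Losses and the explicit reconciliation
# ---------------------------------------------------------------------------


def loss_cost(T: Tree, S: Tree) -> int:
    """Number of losses of the LCA reconciliation.

    For each gene-tree edge (p, u) the path in S from M(p) to M(u) hides
    dist(M(p), M(u)) - 1 lost lineages, plus one more when p is a
    duplication (the copy on p's other side at M(p) itself).  Nothing is
    charged above the gene-tree root.
    """
    m = lca_map(T, S)
    ev = classify_events(T, S, m)
    total = 0
    for p in T.postorder():
        if T.is_leaf(p):
            continue
        dup = ev.is_duplication(p)
        for u in T.children(p):
            d = m._index.dist(m[p], m[u])
            total += d - 1 + (1 if dup else 0)
    return total


def mutation_cost(T: Tree, S: Tree) -> int:
    """Duplications plus losses of the LCA reconciliation."""
    return classify_events(T, S).dup_count + loss_cost(T, S)


@dataclass
class Reconciliation:
    """The LCA reconciliation R(T,S) as an explicit extension of T."""

    tree: Tree
    insertion_marks: frozenset[int]  # roots of grafted (lost) subtrees
    events: dict[int, Event]  # per original internal vertex of T
    duplication_count: int
    losses: int

    @property
    def mutation_cost(self) -> int:
        return self.duplication_count + self.losses

    def newick(self) -> str:
        """Serialize with a LOSS prefix/suffix on every grafted subtree root."""
        marks = {v: "LOSS:" if self.tree.is_leaf(v) else "LOSS" for v in self.insertion_marks}
        return self.tree.newick(node_labels=marks)


def build_reconciliation(T: Tree, S: Tree) -> Reconciliation:
    m = lca_map(T, S)
    ev = classify_events(T, S, m)
    idx = m._index

    children: dict[int, tuple[int, int]] = {}
    labels: dict[int, str] = {}
    marks: set[int] = set()
    counter = [max(T.nodes()) + 1]

    def fresh() -> int:
        counter[0] += 1
        return counter[0] - 1

    def copy_species(sv: int) -> int:
        """Graft a full copy of the species subtree at sv (a lost lineage)."""
        v = fresh()
        if S.is_leaf(sv):
            labels[v] = S.label(sv)
        else:
            a, b = S.children(sv)
            children[v] = (copy_species(a), copy_species(b))
        return v

    def path_down(top: int, bottom: int) -> list[int]:
        """Species vertices from top down to bottom, inclusive."""
        path = [bottom]
        while path[-1] != top:
            path.append(S.parent(path[-1]))
        path.reverse()
        return path

    def extend_edge(p: int, u: int) -> int:
        """Build the extension of the gene subtree at u for the edge (p,u)."""
        core = build(u)
        if ev.is_duplication(p):
            top = m[p]
        else:
            # first species vertex below M(p) towards M(u)
            top = path_down(m[p], m[u])[1] if m[p] != m[u] else m[u]
        res = core
        for sv in reversed(path_down(top, m[u])[:-1]):
            on_path = path_down(sv, m[u])[1]
            off = next(c for c in S.children(sv) if c != on_path)
            lost = copy_species(off)
            marks.add(lost)
            z = fresh()
            children[z] = (res, lost)
            res = z
        return res

    def build(u: int) -> int:
        if T.is_leaf(u):
            labels[u] = T.label(u)
            return u
        a, b = T.children(u)
        children[u] = (extend_edge(u, a), extend_edge(u, b))
        return u

    root = build(T.root)
    rtree = Tree(children, labels, root)
    return Reconciliation(
        tree=rtree,
        insertion_marks=frozenset(marks),
        events=dict(ev.events),
        duplication_count=ev.dup_count,
        losses=len(marks),
    )


def is_ds_consistent(R: Tree, S: Tree) -> bool:
    """Does R reflect a loss-free duplication/speciation history along S?

    Every vertex t with at least two genomes below it must have a species
    vertex s with the same genome set and satisfy condition (D)
    (equal child genome sets — a duplication) or condition (S) (child
    genome sets equal to s's child genome sets — a speciation).
    """
    by_set = {S.genome_set(v): v for v in S.nodes()}
    for t in R.postorder():
        if R.is_leaf(t):
            continue
        gs = R.genome_set(t)
        if len(gs) < 2:
            continue
        s = by_set.get(gs)
        if s is None:
            return False
        a, b = R.children(t)
        ga, gb = R.genome_set(a), R.genome_set(b)
        if ga == gb:
            continue  # (D)
        sa, sb = (S.genome_set(c) for c in S.children(s))
        if (ga, gb) in ((sa, sb), (sb, sa)):
            continue  # (S)
        return False
    return True


def is_md_consistent(T: Tree, S: Tree) -> bool:
    """True iff T has no NAD vertex with respect to S."""
    if T.size <= 2:
        return True
    return classify_events(T, S).nad_count == 0


def wrong_triplet(
    T: Tree, S: Tree, x: int
) -> tuple[tuple[str, str, str], frozenset[str], frozenset[str]]:
    """A species triplet split differently by the NAD vertex x and by S.

    Returns ``(sorted triplet, pair grouped by x, pair grouped by S)``; the
    lexicographically smallest qualifying triplet is chosen.  x groups
    {a,b | c} when one of its children contains a and b but not c and the
    other contains c but neither a nor b; S's grouping is read off the
    rooted triple of S.
    """
    ev = classify_events(T, S)
    if ev.events.get(x) is not Event.NAD:
        raise TreeDomainError(f"vertex {x} is not a NAD vertex")
    idx = _SpeciesIndex(S)
    a_, b_ = T.children(x)
    ga, gb = T.genome_set(a_), T.genome_set(b_)

    def s_pair(a: str, b: str, c: str) -> frozenset[str]:
        la, lb, lc = idx.leaf_of[a], idx.leaf_of[b], idx.leaf_of[c]
        lab, lac, lbc = idx.lca(la, lb), idx.lca(la, lc), idx.lca(lb, lc)
        top = idx.lca(lab, lc)
        if idx.depth[lab] > idx.depth[top]:
            return frozenset((a, b))
        if idx.depth[lac] > idx.depth[top]:
            return frozenset((a, c))
        return frozenset((b, c))

    for a, b, c in combinations(sorted(ga | gb), 3):
        for pair, single in ((frozenset((a, b)), c), (frozenset((a, c)), b), (frozenset((b, c)), a)):
            p, q = sorted(pair)
            if (p in ga and q in ga and single not in ga and single in gb
                    and p not in gb and q not in gb) or (
                    p in gb and q in gb and single not in gb and single in ga
                    and p not in ga and q not in ga):
                sp = s_pair(a, b, c)
                if sp != pair:
                    return (a, b, c), pair, sp
    raise TreeDomainError(
        f"no wrong triplet found under vertex {x}; not a NAD vertex?"
    )  # unreachable for a genuine NAD
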