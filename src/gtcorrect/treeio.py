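"""Rooted binary leaf-labelled trees and Newick I/O.

The data model is deliberately minimal: a tree is a set of integer node
identifiers, a ``children`` map sending every internal node to its ordered
pair of children, and a ``label`` map on leaves.  Gene trees may repeat
labels (several gene copies in the same genome); species trees are uniquely
leaf-labelled.  Node identifiers are stable under leaf removal and
restriction, so callers can report *which* copy of a repeated label was
touched.

Newick conventions
------------------
* Strictly binary; multifurcations are rejected, not resolved.
* Canonical output orders the two children of every vertex by the smallest
  leaf label found in each subtree (ties broken on the full serialized
  subtree), so ``parse(write(t))`` is an isomorphism and serialized trees
  can be compared as strings.
* A "weighted" dialect stores a positive integer leaf weight in the
  branch-length slot, e.g. ``(1:2,2:1);`` gives leaf ``1`` weight 2.  It is
  used for the weighted agreement-subtree machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Optional, Sequence

import dendropy

from .errors import NewickFormatError, TreeDomainError

__all__ = [
    "Tree",
    "Forest",
    "parse_newick",
    "parse_newick_weighted",
    "parse_forest",
    "write_newick",
]


class Tree:
    """A rooted binary tree with string-labelled leaves.

    Instances are treated as immutable: every editing operation returns a
    new tree.  Node identifiers of surviving nodes are preserved by
    ``remove_leaf``/``restrict_to`` and friends.
    """

    __slots__ = ("root", "_children", "_label", "_parent", "_gs_cache")

    def __init__(
        self,
        children: Mapping[int, tuple[int, int]],
        labels: Mapping[int, str],
        root: int,
    ) -> None:
        self._children = dict(children)
        self._label = dict(labels)
        self.root = root
        self._parent: dict[int, int] = {}
        for v, (a, b) in self._children.items():
            self._parent[a] = v
            self._parent[b] = v
        self._gs_cache: dict[int, frozenset[str]] = {}
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def leaf(cls, label: str) -> "Tree":
        return cls({}, {0: label}, 0)

    @classmethod
    def from_nested(cls, nested) -> "Tree":
        """Build from nested pairs, e.g. ``(("1", "3"), "2")``."""
        children: dict[int, tuple[int, int]] = {}
        labels: dict[int, str] = {}
        counter = [0]

        def build(spec) -> int:
            v = counter[0]
            counter[0] += 1
            if isinstance(spec, str):
                labels[v] = spec
                return v
            if not (isinstance(spec, tuple) and len(spec) == 2):
                raise NewickFormatError(f"nested spec must be a label or a pair: {spec!r}")
            left = build(spec[0])
            right = build(spec[1])
            children[v] = (left, right)
            return v

        root = build(nested)
        return cls(children, labels, root)

    def _validate(self) -> None:
        if not self._label:
            raise TreeDomainError("a tree must have at least one leaf")
        seen = set(self._children) | set(self._label)
        if set(self._children) & set(self._label):
            raise TreeDomainError("a node cannot be both internal and a leaf")
        for v, (a, b) in self._children.items():
            if a not in seen or b not in seen:
                raise TreeDomainError(f"child of node {v} is undefined")
        for lbl in self._label.values():
            if not lbl:
                raise NewickFormatError("empty leaf label")

    # -- basic queries -------------------------------------------------

    @property
    def size(self) -> int:
        """Number of leaves."""
        return len(self._label)

    def is_leaf(self, v: int) -> bool:
        return v in self._label

    def label(self, v: int) -> str:
        return self._label[v]

    def children(self, v: int) -> tuple[int, ...]:
        return self._children.get(v, ())

    def parent(self, v: int) -> Optional[int]:
        return self._parent.get(v)

    def nodes(self) -> list[int]:
        return sorted(set(self._children) | set(self._label))

    def leaves(self, v: Optional[int] = None) -> list[int]:
        """Leaf identifiers below ``v`` (whole tree by default), in preorder."""
        start = self.root if v is None else v
        out = []
        stack = [start]
        while stack:
            u = stack.pop()
            if self.is_leaf(u):
                out.append(u)
            else:
                a, b = self._children[u]
                stack.append(b)
                stack.append(a)
        return out

    def postorder(self, v: Optional[int] = None) -> Iterator[int]:
        start = self.root if v is None else v
        stack = [(start, False)]
        while stack:
            u, done = stack.pop()
            if done or self.is_leaf(u):
                yield u
            else:
                stack.append((u, True))
                a, b = self._children[u]
                stack.append((b, False))
                stack.append((a, False))

    def preorder(self, v: Optional[int] = None) -> Iterator[int]:
        start = self.root if v is None else v
        stack = [start]
        while stack:
            u = stack.pop()
            yield u
            if not self.is_leaf(u):
                a, b = self._children[u]
                stack.append(b)
                stack.append(a)

    def genome_set(self, v: Optional[int] = None) -> frozenset[str]:
        """The *set* (not multiset) of species labels below ``v``."""
        start = self.root if v is None else v
        cached = self._gs_cache.get(start)
        if cached is not None:
            return cached
        for u in self.postorder(start):
            if u in self._gs_cache:
                continue
            if self.is_leaf(u):
                self._gs_cache[u] = frozenset((self._label[u],))
            else:
                a, b = self._children[u]
                self._gs_cache[u] = self._gs_cache[a] | self._gs_cache[b]
        return self._gs_cache[start]

    def labels(self) -> frozenset[str]:
        return self.genome_set(self.root)

    def subtree(self, v: int) -> "Tree":
        """The subtree rooted at ``v``, keeping node identifiers."""
        children = {}
        labels = {}
        for u in self.preorder(v):
            if self.is_leaf(u):
                labels[u] = self._label[u]
            else:
                children[u] = self._children[u]
        return Tree(children, labels, v)

    # -- editing -------------------------------------------------------

    def remove_leaf(self, leaf: int) -> "Tree":
        """Remove ``leaf`` and suppress its parent.

        If the parent was the root, the sibling becomes the new root.
        """
        if not self.is_leaf(leaf):
            raise TreeDomainError(f"node {leaf} is not a leaf")
        if self.size < 2:
            raise TreeDomainError("cannot remove the only leaf of a tree")
        return self.remove_leaves([leaf])

    def remove_leaves(self, drop: Iterable[int]) -> Optional["Tree"]:
        """Remove a set of leaves, suppressing unary vertices; None if empty."""
        drop = set(drop)
        for d in drop:
            if not self.is_leaf(d):
                raise TreeDomainError(f"node {d} is not a leaf")
        keep = set(self._label) - drop

        def rebuild(v: int) -> Optional[int]:
            # returns surviving representative of subtree at v, or None
            if self.is_leaf(v):
                return v if v in keep else None
            a, b = self._children[v]
            ra = rebuild(a)
            rb = rebuild(b)
            if ra is None:
                return rb
            if rb is None:
                return ra
            children[v] = (ra, rb)
            return v

        children: dict[int, tuple[int, int]] = {}
        root = rebuild(self.root)
        if root is None:
            return None
        labels = {v: self._label[v] for v in keep}
        return Tree(children, labels, root)

    def restrict_to(self, keep: Iterable[str]) -> Optional["Tree"]:
        """Restrict to leaves whose label is in ``keep``; None if nothing survives."""
        keep = set(keep)
        drop = [v for v, lbl in self._label.items() if lbl not in keep]
        return self.remove_leaves(drop)

    def graft_leaf(self, at: int, label: str) -> tuple["Tree", int]:
        """Insert a new leaf on the edge above node ``at``.

        Grafting at the root uses the (implicit) root edge, producing a new
        root.  Returns the new tree and the identifier of the new leaf.
        """
        nid = max(set(self._children) | set(self._label)) + 1
        new_leaf = nid
        new_internal = nid + 1
        children = dict(self._children)
        labels = dict(self._label)
        labels[new_leaf] = label
        children[new_internal] = (at, new_leaf)
        if at == self.root:
            root = new_internal
        else:
            p = self._parent[at]
            a, b = children[p]
            children[p] = (new_internal, b) if a == at else (a, new_internal)
            root = self.root
        return Tree(children, labels, root), new_leaf

    def duplicate_leaf(self, leaf: int) -> "Tree":
        """Replace a leaf by a cherry of two copies of its label."""
        if not self.is_leaf(leaf):
            raise TreeDomainError(f"node {leaf} is not a leaf")
        t, _ = self.graft_leaf(leaf, self._label[leaf])
        return t

    # -- serialization and comparison ---------------------------------

    def newick(
        self,
        weights: Optional[Mapping[int, int]] = None,
        node_labels: Optional[Mapping[int, str]] = None,
    ) -> str:
        """Canonical Newick string (children sorted by smallest leaf label).

        ``weights`` maps leaf id -> integer written in the branch-length
        slot; ``node_labels`` maps node id -> extra label (internal labels
        are appended after the closing parenthesis).
        """

        def render(v: int) -> tuple[str, str]:
            # returns (min leaf label, serialized subtree)
            extra = node_labels.get(v, "") if node_labels else ""
            if self.is_leaf(v):
                lbl = self._label[v]
                s = extra + lbl if extra else lbl
                if weights and v in weights:
                    s += f":{weights[v]}"
                return lbl, s
            a, b = self._children[v]
            ka, sa = render(a)
            kb, sb = render(b)
            if (kb, sb) < (ka, sa):
                ka, sa, sb = kb, sb, sa
            return ka, f"({sa},{sb})" + extra

        return render(self.root)[1] + ";"

    def isomorphic(self, other: "Tree") -> bool:
        """Equality as leaf-labelled rooted trees (labels as multisets)."""
        return self.newick() == other.newick()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tree({self.newick()!r})"


@dataclass
class Forest:
    """An ordered list of gene trees analysed together."""

    trees: list[Tree] = field(default_factory=list)

    @property
    def size(self) -> int:
        return sum(t.size for t in self.trees)

    @property
    def genome_set(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for t in self.trees:
            out |= t.labels()
        return out

    def restrict_to(self, keep: Iterable[str]) -> "Forest":
        """Restrict every tree, dropping trees with fewer than two leaves.

        A tree with at most two leaves is MD-consistent with any species
        tree, so it constrains nothing once restricted below that size; a
        1-leaf remnant is dropped entirely.
        """
        keep = set(keep)
        out = []
        for t in self.trees:
            r = t.restrict_to(keep)
            if r is not None and r.size >= 2:
                out.append(r)
        return Forest(out)

    def __iter__(self):
        return iter(self.trees)

    def __len__(self):
        return len(self.trees)


# ---------------------------------------------------------------------------
# Newick parsing (via dendropy)
# ---------------------------------------------------------------------------


def _parse(text: str) -> tuple[Tree, dict[int, int]]:
    try:
        dt = dendropy.Tree.get(
            data=text,
            schema="newick",
            rooting="force-rooted",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickFormatError(f"cannot parse Newick: {exc}") from exc

    children: dict[int, tuple[int, int]] = {}
    labels: dict[int, str] = {}
    weights: dict[int, int] = {}
    ids: dict[int, int] = {}
    counter = [0]

    def visit(nd) -> int:
        v = counter[0]
        counter[0] += 1
        kids = nd.child_nodes()
        if len(kids) == 0:
            lbl = nd.taxon.label if nd.taxon is not None else nd.label
            if not lbl:
                raise NewickFormatError("leaf with empty label")
            labels[v] = str(lbl)
            if nd.edge.length is not None:
                w = nd.edge.length
                if w != int(w) or w < 1:
                    raise NewickFormatError(
                        f"leaf weight must be a positive integer, got {w!r} on leaf {lbl}"
                    )
                weights[v] = int(w)
        elif len(kids) == 2:
            a = visit(kids[0])
            b = visit(kids[1])
            children[v] = (a, b)
        else:
            raise NewickFormatError(
                f"non-binary vertex with {len(kids)} children "
                f"(genome set {sorted(set(l.taxon.label for l in nd.leaf_iter() if l.taxon))})"
            )
        return v

    root = visit(dt.seed_node)
    return Tree(children, labels, root), weights


def parse_newick(text: str) -> Tree:
    """Parse a rooted binary Newick tree; leaf weights, if any, are ignored."""
    tree, _ = _parse(text)
    return tree


def parse_newick_weighted(text: str) -> tuple[Tree, dict[int, int]]:
    """Parse the weighted dialect; returns the tree and leaf-id -> weight.

    Leaves without an explicit weight default to weight 1.
    """
    tree, weights = _parse(text)
    for v in tree.leaves():
        weights.setdefault(v, 1)
    return tree, weights


def parse_forest(text: str) -> Forest:
    """Parse a forest file: one Newick tree per non-empty line."""
    trees = []
    for line in text.splitlines():
        line = line.strip()
        if line:
            trees.append(parse_newick(line))
    return Forest(trees)


def write_newick(t: Tree, **kw) -> str:
    """Canonical Newick serialization (module-level convenience)."""
    return t.newick(**kw)
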