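"""Shared fixtures and independent brute-force oracles."""

from itertools import combinations

import numpy as np
import pytest

from gtcorrect import (
    Forest,
    Tree,
    is_md_consistent,
    parse_newick,
    random_gene_tree,
    random_species_tree,
)


@pytest.fixture
def S3():
    """The three-species tree ((1,2),3) of the worked example."""
    return parse_newick("((1,2),3);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def genomes(n: int) -> list[str]:
    return [str(i + 1) for i in range(n)]


def random_unique_gene_tree(G, seed):
    """Uniform random uniquely leaf-labelled tree on all of G."""
    rng = np.random.default_rng(seed)
    labels = list(G)
    rng.shuffle(labels)
    t = Tree.leaf(labels[0])
    for lbl in labels[1:]:
        nodes = t.nodes()
        t, _ = t.graft_leaf(nodes[rng.integers(len(nodes))], lbl)
    return t


# ---------------------------------------------------------------------------
# Brute-force oracles (deliberately independent of the package's algorithms)
# ---------------------------------------------------------------------------


def mast_oracle(T: Tree, S: Tree) -> int:
    """Exhaustive maximum agreement: try every label subset."""
    labels = sorted(T.labels() & S.labels())
    best = 0
    for k in range(len(labels), 0, -1):
        if k <= best:
            break
        for keep in combinations(labels, k):
            a = T.restrict_to(keep)
            b = S.restrict_to(keep)
            if a is not None and b is not None and a.size == k == b.size \
                    and a.newick() == b.newick():
                best = max(best, k)
                break
    return best


def wmast_oracle(T: Tree, weights_by_label: dict, S: Tree) -> int:
    """Exhaustive weighted maximum agreement over label subsets."""
    labels = sorted(T.labels() & S.labels())
    best = 0
    for k in range(1, len(labels) + 1):
        for keep in combinations(labels, k):
            a = T.restrict_to(keep)
            b = S.restrict_to(keep)
            if a is not None and b is not None and a.size == k == b.size \
                    and a.newick() == b.newick():
                best = max(best, sum(weights_by_label[l] for l in keep))
    return best


def min_removals_oracle(T: Tree, S: Tree) -> int:
    """Exhaustive minimum leaf removal to MD-consistency (ascending k)."""
    if is_md_consistent(T, S):
        return 0
    leaves = T.leaves()
    for k in range(1, T.size - 1):
        for subset in combinations(leaves, k):
            r = T.remove_leaves(subset)
            if r is not None and is_md_consistent(r, S):
                return k
    return T.size - 2


def vertex_cut_oracle(vertices, hyperedges):
    """Smallest vertex subset whose removal disconnects the clique expansion."""
    import networkx as nx

    verts = sorted(vertices)

    def disconnected(removed):
        rem = [v for v in verts if v not in removed]
        if len(rem) < 2:
            return False
        g = nx.Graph()
        g.add_nodes_from(rem)
        for e in hyperedges:
            live = [v for v in sorted(e) if v not in removed]
            for a, b in combinations(live, 2):
                g.add_edge(a, b)
        return not nx.is_connected(g)

    for k in range(0, len(verts) - 1):
        for removed in combinations(verts, k):
            if disconnected(set(removed)):
                return k
    return None
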