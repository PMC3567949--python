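"""Levels, hypergraphs, vertex cuts and species-removal inference."""

import numpy as np
import pytest

from gtcorrect import (
    Forest,
    LevelHypergraph,
    build_level_hypergraph,
    classify_events,
    compute_levels,
    hypergraph_connected,
    infer_md_species_tree,
    is_md_consistent,
    min_vertex_cut,
    minimum_species_removal_inference,
    minsrr_via_minsri,
    parse_newick,
)
from gtcorrect.inference import apparent_duplication_count
from gtcorrect.simulate import random_gene_tree, random_md_tree, random_species_tree

from conftest import genomes, vertex_cut_oracle


def _forest(*nwk):
    return Forest([parse_newick(s) for s in nwk])


def test_levels_examples():
    lv = compute_levels(_forest("(1,2);"))
    assert len(lv) == 1 and len(lv[0]) == 1

    # AD cherry below a non-AD root contributes no further level
    lv2 = compute_levels(_forest("((1,1),2);"))
    assert len(lv2) == 1

    lv3 = compute_levels(_forest("((1,2),3);", "((1,3),2);"))
    assert len(lv3[0]) == 2  # both roots
    assert len(lv3[1]) == 2  # the two internal cherries
    assert len(lv3) == 2


def test_level_skips_ad_roots():
    # root is AD: level 0 descends to its highest non-AD descendants
    f = _forest("((1,2),(1,3));")
    lv = compute_levels(f)
    t = f.trees[0]
    assert all(v != t.root for _, v in lv[0])
    assert len(lv[0]) == 2


def test_build_level_hypergraph():
    f = _forest("(1,2);")
    h = build_level_hypergraph(compute_levels(f)[0], f)
    assert h.vertices == frozenset({"1", "2"})
    assert sorted(sorted(e) for e in h.hyperedges) == [["1"], ["2"]]

    f2 = _forest("((1,2),3);", "((1,3),2);")
    h2 = build_level_hypergraph(compute_levels(f2)[0], f2)
    assert sorted(sorted(e) for e in h2.hyperedges) == [["1", "2"], ["1", "3"], ["2"], ["3"]]


def test_hypergraph_connectivity():
    assert not hypergraph_connected(
        LevelHypergraph(frozenset("12"), [frozenset("1"), frozenset("2")])
    )
    assert hypergraph_connected(
        LevelHypergraph(
            frozenset("123"),
            [frozenset("12"), frozenset("3"), frozenset("13"), frozenset("2")],
        )
    )
    assert hypergraph_connected(LevelHypergraph(frozenset("123"), [frozenset("123")]))


def test_min_vertex_cut_examples():
    # path a-b-c: unique cut vertex b
    h = LevelHypergraph(frozenset("abc"), [frozenset("ab"), frozenset("bc")])
    assert min_vertex_cut(h) == frozenset("b")
    h2 = LevelHypergraph(
        frozenset("123"),
        [frozenset("12"), frozenset("3"), frozenset("13"), frozenset("2")],
    )
    assert min_vertex_cut(h2) == frozenset("1")
    # complete triangle: no separating set
    assert min_vertex_cut(LevelHypergraph(frozenset("abc"), [frozenset("abc")])) is None


def test_min_vertex_cut_matches_brute_force():
    rng = np.random.default_rng(77)
    checked = 0
    while checked < 60:
        nv = int(rng.integers(3, 9))
        verts = [str(i) for i in range(nv)]
        edges = []
        for _ in range(int(rng.integers(2, 7))):
            k = int(rng.integers(1, nv))
            edges.append(frozenset(rng.choice(verts, size=k, replace=False)))
        h = LevelHypergraph(frozenset().union(*edges), edges)
        if not h.vertices or not hypergraph_connected(h):
            continue
        checked += 1
        cut = min_vertex_cut(h)
        opt = vertex_cut_oracle(h.vertices, edges)
        if cut is None:
            assert opt is None
        else:
            assert len(cut) == opt
            # the returned set really disconnects the hypergraph
            g = h.clique_expansion()
            g.remove_nodes_from(cut)
            import networkx as nx

            assert g.number_of_nodes() >= 2 and not nx.is_connected(g)


def test_minsri_examples():
    assert minimum_species_removal_inference(_forest("(1,2);")) == frozenset("12")
    kept = minimum_species_removal_inference(_forest("((1,2),3);", "((1,3),2);"))
    assert len(kept) == 2  # brute force over subsets confirms 2 is optimal
    # an MD forest loses nothing
    f = _forest("((1,2),3);", "(1,(2,2));")
    assert minimum_species_removal_inference(f) == frozenset("123")


def test_minsri_output_certified():
    rng = np.random.default_rng(91)
    for _ in range(40):
        G = genomes(int(rng.integers(3, 7)))
        trees = [
            random_gene_tree(int(rng.integers(3, 9)), G, int(rng.integers(2**31 - 1)))
            for _ in range(int(rng.integers(1, 4)))
        ]
        f = Forest(trees)
        kept = minimum_species_removal_inference(f)
        assert kept <= f.genome_set and len(kept) >= 2
        restricted = f.restrict_to(kept)
        star = infer_md_species_tree(restricted, species=kept)
        assert star is not None
        for t in restricted:
            assert classify_events(t, star).dup_count == apparent_duplication_count(t)


def test_minsrr_examples(S3):
    f = _forest("((1,2),3);")
    assert minsrr_via_minsri(f, S3) == frozenset("123")
    f2 = _forest("((1,3),2);")
    kept = minsrr_via_minsri(f2, S3)
    assert len(kept) == 2
    restricted = f2.restrict_to(kept)
    s_r = S3.restrict_to(kept)
    for t in restricted:
        assert is_md_consistent(t, s_r)


def test_minsrr_random_postcondition():
    rng = np.random.default_rng(55)
    for _ in range(25):
        G = genomes(int(rng.integers(3, 6)))
        S = random_species_tree(G, int(rng.integers(2**31 - 1)))
        f = Forest(
            [random_gene_tree(int(rng.integers(3, 8)), G, int(rng.integers(2**31 - 1)))
             for _ in range(2)]
        )
        kept = minsrr_via_minsri(f, S)
        s_r = S.restrict_to(kept)
        for t in f.restrict_to(kept):
            assert is_md_consistent(t, s_r)


def test_infer_md_species_tree_examples():
    assert infer_md_species_tree(_forest("(1,2);")).newick() == "(1,2);"
    assert infer_md_species_tree(_forest("((1,2),3);", "((1,3),2);")) is None
    # a lone species tree certifies itself (d = 0)
    S = parse_newick("((1,(2,3)),(4,5));")
    star = infer_md_species_tree(Forest([S]))
    assert star is not None
    assert classify_events(S, star).dup_count == 0


def test_infer_md_species_tree_on_generated_md_forests():
    """Forests of trees built by leaf duplication from one species tree are
    MD-forests, and the constructed tree certifies them."""
    rng = np.random.default_rng(61)
    for _ in range(30):
        G = genomes(int(rng.integers(3, 7)))
        S = random_species_tree(G, int(rng.integers(2**31 - 1)))
        f = Forest(
            [random_md_tree(S, len(G) + int(rng.integers(0, 5)), int(rng.integers(2**31 - 1)))
             for _ in range(2)]
        )
        star = infer_md_species_tree(f)
        assert star is not None
        for t in f:
            assert classify_events(t, star).dup_count == apparent_duplication_count(t)
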