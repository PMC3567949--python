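"""Borders, induced weighted trees and the correction algorithm."""

import numpy as np
import pytest

from gtcorrect import (
    ad_border,
    build_TI,
    correct_tree,
    exact_min_removals,
    induced_weighted_tree,
    is_md_consistent,
    mast,
    min_species_removal_correct,
    nad_border,
    parse_newick,
    satisfies_constraint_c,
)
from gtcorrect.errors import TreeDomainError
from gtcorrect.simulate import random_gene_tree, random_species_tree

from conftest import genomes, min_removals_oracle, random_unique_gene_tree


def test_ad_border_examples(S3):
    T = parse_newick("((1,1),2);")
    (x,) = ad_border(T, S3)
    assert T.genome_set(x) == frozenset({"1"})
    # uniquely leaf-labelled: no AD at all
    assert ad_border(parse_newick("((1,3),2);"), S3) == []
    # AD root containing a NAD is not ONLY-AD
    assert ad_border(parse_newick("(((1,3),2),1);"), S3) == []


def test_nad_border_examples(S3):
    T = parse_newick("((1,3),2);")
    assert nad_border(T, S3) == [T.root]
    T2 = parse_newick("(((1,3),2),1);")
    border = nad_border(T2, S3)
    assert len(border) == 2
    sets = {T2.genome_set(v) for v in border}
    assert sets == {frozenset({"1", "2", "3"}), frozenset({"1"})}


def test_induced_weighted_tree(S3):
    W = induced_weighted_tree(parse_newick("(1,(1,2));"), S3)
    assert W.tree.newick() == "(1,2);"
    assert W.weight_of("1") == 2 and W.weight_of("2") == 1
    assert W.value == 3
    # uniquely labelled full tree induces S itself with unit weights
    W2 = induced_weighted_tree(parse_newick("(3,(2,1));"), S3)
    assert W2.tree.newick() == S3.newick()
    assert W2.value == 3


def test_build_TI(S3):
    # no AD: T^I is T itself
    T = parse_newick("((1,3),2);")
    ti = build_TI(T, S3)
    assert ti.tree.newick() == T.newick()
    assert all(w == 1 for w in ti.weights.values())
    # AD cherry collapses to a weighted leaf
    T2 = parse_newick("((1,1),2);")
    ti2 = build_TI(T2, S3)
    assert ti2.tree.newick() == "(1,2);"
    wl = next(v for v in ti2.tree.leaves() if ti2.tree.label(v) == "1")
    assert ti2.weights[wl] == 2
    assert len(ti2.origin[wl]) == 2  # both copies traced back
    assert ti2.value == T2.size


def test_constraint_c(S3):
    assert satisfies_constraint_c(parse_newick("((1,3),2);"), S3)
    assert not satisfies_constraint_c(parse_newick("(((1,3),2),1);"), S3)
    assert satisfies_constraint_c(parse_newick("((1,2),3);"), S3)


@pytest.mark.parametrize(
    "gene,expected",
    [("((1,2),3);", 0), ("((1,3),2);", 1), ("(((1,3),2),1);", 1)],
)
def test_correct_tree_examples(S3, gene, expected):
    rep = correct_tree(parse_newick(gene), S3)
    assert rep.removals == expected
    assert is_md_consistent(rep.corrected, S3)
    assert rep.removals == parse_newick(gene).size - rep.corrected.size
    assert len(rep.removed_leaves) == rep.removals


def test_exact_min_removals_examples(S3):
    assert exact_min_removals(parse_newick("((1,2),3);"), S3)[0] == 0
    assert exact_min_removals(parse_newick("((1,3),2);"), S3)[0] == 1
    n, witness = exact_min_removals(parse_newick("(((1,3),2),1);"), S3)
    assert n == 1 and len(witness) == 1


def test_exact_min_removals_cap(S3):
    from gtcorrect.errors import ResourceError

    with pytest.raises(ResourceError):
        exact_min_removals(parse_newick("(((1,3),2),1);"), S3, cap=1)


def test_correct_tree_output_always_md_consistent():
    rng = np.random.default_rng(31)
    for _ in range(150):
        G = genomes(int(rng.integers(3, 7)))
        S = random_species_tree(G, int(rng.integers(2**31 - 1)))
        T = random_gene_tree(int(rng.integers(3, 14)), G, int(rng.integers(2**31 - 1)))
        rep = correct_tree(T, S)
        assert is_md_consistent(rep.corrected, S)
        assert rep.removals >= min_removals_oracle(T, S) if T.size <= 10 else True


def test_exact_on_uniquely_labelled():
    """On uniquely leaf-labelled trees the algorithm is one MAST call:
    N = |T| - MAST score, and it matches the exhaustive optimum."""
    rng = np.random.default_rng(13)
    for _ in range(60):
        G = genomes(int(rng.integers(4, 9)))
        S = random_species_tree(G, int(rng.integers(2**31 - 1)))
        T = random_unique_gene_tree(G, int(rng.integers(2**31 - 1)))
        rep = correct_tree(T, S)
        assert rep.removals == T.size - mast(T, S).score
        assert rep.removals == min_removals_oracle(T, S)


def test_exact_on_constraint_c():
    rng = np.random.default_rng(29)
    checked = 0
    while checked < 60:
        G = genomes(int(rng.integers(3, 6)))
        S = random_species_tree(G, int(rng.integers(2**31 - 1)))
        T = random_gene_tree(int(rng.integers(4, 11)), G, int(rng.integers(2**31 - 1)))
        if not satisfies_constraint_c(T, S) or is_md_consistent(T, S):
            continue
        checked += 1
        assert correct_tree(T, S).removals == min_removals_oracle(T, S)


def test_all_or_none_copies_on_constraint_c():
    """Under Constraint C the correction removes all copies of a species
    from a collapsed region or none of them."""
    rng = np.random.default_rng(37)
    checked = 0
    while checked < 40:
        G = genomes(int(rng.integers(3, 6)))
        S = random_species_tree(G, int(rng.integers(2**31 - 1)))
        T = random_gene_tree(int(rng.integers(4, 10)), G, int(rng.integers(2**31 - 1)))
        if not satisfies_constraint_c(T, S) or is_md_consistent(T, S):
            continue
        from gtcorrect.reconcile import classify_events, Event

        ev = classify_events(T, S)
        if not any(e is Event.AD for e in ev.events.values()):
            continue  # only informative when a weighted leaf exists
        checked += 1
        rep = correct_tree(T, S)
        removed_by_label: dict[str, int] = {}
        for _, lbl in rep.removed_leaves:
            removed_by_label[lbl] = removed_by_label.get(lbl, 0) + 1
        total_by_label: dict[str, int] = {}
        for v in T.leaves():
            total_by_label[T.label(v)] = total_by_label.get(T.label(v), 0) + 1
        # multi-copy labels live inside one collapsed AD region, so their
        # removal is all-or-none; single copies are trivially all-or-none
        for lbl, k in removed_by_label.items():
            if total_by_label[lbl] > 1:
                assert k == total_by_label[lbl]


def test_min_species_removal(S3):
    removed, corrected = min_species_removal_correct(parse_newick("((1,3),2);"), S3)
    assert len(removed) == 1
    assert is_md_consistent(corrected, S3.restrict_to(corrected.labels()))
    removed2, corrected2 = min_species_removal_correct(parse_newick("((1,2),3);"), S3)
    assert removed2 == frozenset()
    with pytest.raises(TreeDomainError):
        min_species_removal_correct(parse_newick("(((1,3),2),1);"), S3)
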