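"""Dollo parsimony vs enumeration oracle, NJ exactness, monophyly."""

from __future__ import annotations

import random

import dendropy
import numpy as np
import pytest

from mitoribo import phylo
from mitoribo.io_formats import ValidationError, parse_newick

from _tree_utils import oracle_min_losses as _oracle_min_losses
from _tree_utils import patristic as _patristic
from _tree_utils import random_additive_case as _random_additive_case


# ---------------------------------------------------------------------------
# Dollo parsimony
# ---------------------------------------------------------------------------




def test_dollo_fixture_origins(fixture_tree_matrix):
    tree, matrix = fixture_tree_matrix
    results = phylo.dollo_origins(tree, matrix, uncertain_policy="as-absent")
    for protein in ("LRPPRC", "mS31"):
        res = results[protein]
        assert res.origin_label == "Metazoa"
        assert res.n_losses == 0
    assert results["mS39"].origin_label == "Metazoa"


def test_dollo_uncertain_policies(fixture_tree_matrix):
    tree, matrix = fixture_tree_matrix
    absent = phylo.dollo_origins(tree, matrix, uncertain_policy="as-absent")["SLIRP"]
    present = phylo.dollo_origins(tree, matrix, uncertain_policy="as-present")["SLIRP"]
    assert absent.origin_label == "Eumetazoa"  # Ta excluded
    assert present.origin_label == "Parahoxozoa"  # Ta included
    both = phylo.dollo_origins(tree, matrix, uncertain_policy="both")["SLIRP"]
    assert both == (absent, present)


def test_dollo_all_present_is_root(fixture_tree_matrix):
    tree, _ = fixture_tree_matrix
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    res = phylo.dollo_origin(tree, {sp: True for sp in leaves})
    assert set(res.origin_leaves) == set(leaves)
    assert res.n_losses == 0


def test_dollo_disjoint_leaves_verified_by_enumeration(fixture_tree_matrix):
    tree, _ = fixture_tree_matrix
    leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    present = {sp: sp in ("Hs", "Rp") for sp in leaves}
    res = phylo.dollo_origin(tree, present)
    assert set(res.origin_leaves) == set(leaves)  # MRCA of Hs and Rp is the root
    assert res.n_losses == _oracle_min_losses(tree, {"Hs", "Rp"})


def test_dollo_all_absent_errors(fixture_tree_matrix):
    tree, _ = fixture_tree_matrix
    with pytest.raises(ValidationError):
        phylo.dollo_origin(tree, {"Hs": False})


def _random_tree(rng: random.Random, n_leaves: int) -> dendropy.Tree:
    labels = [f"L{i}" for i in range(n_leaves)]
    items = [f"{l}" for l in labels]
    while len(items) > 1:
        i, j = rng.sample(range(len(items)), 2)
        a, b = items[i], items[j]
        items = [x for k, x in enumerate(items) if k not in (i, j)]
        items.append(f"({a},{b})")
    return parse_newick(items[0] + ";")


def test_dollo_minimality_against_oracle_random_trees():
    """Minimal loss count equals exhaustive enumeration on trees <= 8 leaves."""
    rng = random.Random(2024)
    for _ in range(12):
        n = rng.randint(4, 8)
        tree = _random_tree(rng, n)
        leaves = [l.taxon.label for l in tree.leaf_node_iter()]
        for _ in range(8):
            present = {sp: rng.random() < 0.5 for sp in leaves}
            if not any(present.values()):
                present[leaves[0]] = True
            res = phylo.dollo_origin(tree, present)
            want = _oracle_min_losses(tree, {s for s, p in present.items() if p})
            assert res.n_losses == want
            # origin is an ancestor of every present leaf
            assert {s for s, p in present.items() if p} <= set(res.origin_leaves)
            # loss subtrees are disjoint and contain no present leaf
            seen: set[str] = set()
            for ev in res.loss_events:
                assert not (set(ev) & {s for s, p in present.items() if p})
                assert not (set(ev) & seen)
                seen |= set(ev)


def test_dollo_rotation_invariance(fixture_tree_matrix):
    tree, matrix = fixture_tree_matrix
    rotated = tree.clone(depth=1)
    for node in rotated.preorder_node_iter():
        kids = node.child_nodes()
        if len(kids) > 1:
            for k in kids:
                node.remove_child(k)
            for k in reversed(kids):
                node.add_child(k)
    row = matrix.presence.loc["LRPPRC"]
    presence = {sp: bool(row[sp]) for sp in matrix.species}
    a = phylo.dollo_origin(tree, presence)
    b = phylo.dollo_origin(rotated, presence)
    assert a.origin_leaves == b.origin_leaves
    assert a.n_losses == b.n_losses


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------




def test_nj_three_taxon_closed_form():
    d = phylo.DistanceMatrix(
        ["A", "B", "C"], np.array([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float)
    )
    tree = phylo.neighbor_joining(d)
    dist = _patristic(tree)
    assert dist[("A", "B")] == pytest.approx(3.0)
    assert dist[("A", "C")] == pytest.approx(4.0)
    assert dist[("B", "C")] == pytest.approx(5.0)
    lengths = {l.taxon.label: l.edge.length for l in tree.leaf_node_iter()}
    assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
    assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
    assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)


def test_nj_four_taxon_additive_exact():
    """Tree with internal edge 1, pendant edges 1,2,3,4: recovered exactly."""
    labels = ["A", "B", "C", "D"]
    values = np.array(
        [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float
    )
    tree = phylo.neighbor_joining(phylo.DistanceMatrix(labels, values))
    # split AB|CD must exist
    splits = {
        frozenset(l.taxon.label for l in n.leaf_iter())
        for n in tree.preorder_node_iter()
        if not n.is_leaf()
    }
    assert frozenset({"A", "B"}) in splits or frozenset({"C", "D"}) in splits
    dist = _patristic(tree)
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                assert dist[(a, b)] == pytest.approx(values[i, j])


def test_nj_recovers_random_additive_matrices():
    rng = random.Random(7)
    for _ in range(8):
        n = rng.randint(4, 8)
        labels, values = _random_additive_case(rng, n)
        nj_tree = phylo.neighbor_joining(phylo.DistanceMatrix(labels, values))
        dist = _patristic(nj_tree)
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    key = (a, b) if a < b else (b, a)
                    assert dist[key] == pytest.approx(values[i, j], abs=1e-9)


def test_nj_matches_skbio_on_additive_matrix():
    """Independent cross-check: same leaf-to-leaf distances as skbio's NJ."""
    skbio = pytest.importorskip("skbio")
    rng = random.Random(3)
    labels, values = _random_additive_case(rng, 6)
    ours = phylo.neighbor_joining(phylo.DistanceMatrix(labels, values))
    theirs = skbio.tree.nj(skbio.DistanceMatrix(values, ids=labels))
    ours_d = _patristic(ours)
    for (a, b), v in ours_d.items():
        assert theirs.find(a).distance(theirs.find(b)) == pytest.approx(v, abs=1e-9)


def test_nj_rejects_bad_matrices():
    with pytest.raises(ValidationError):
        phylo.DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0]], dtype=float))
    with pytest.raises(ValidationError):
        phylo.neighbor_joining(
            phylo.DistanceMatrix(["A", "B"], np.array([[0, 1], [1, 0]], dtype=float))
        )


# ---------------------------------------------------------------------------
# Monophyly
# ---------------------------------------------------------------------------


def test_monophyly_on_fixture(fixture_tree_matrix):
    tree, _ = fixture_tree_matrix
    assert phylo.is_monophyletic(tree, ["Hs", "Ds"])  # Bilateria
    assert not phylo.is_monophyletic(tree, ["Hs", "Sc"])
    assert phylo.is_monophyletic(tree, ["Hs"])  # singleton
    assert phylo.is_monophyletic(tree, ["Hs", "Ds", "Nv", "Ta", "Aq"])  # Metazoa


def test_monophyly_unknown_taxon_errors(fixture_tree_matrix):
    tree, _ = fixture_tree_matrix
    with pytest.raises(ValidationError):
        phylo.is_monophyletic(tree, ["Hs", "Xx"])


def test_monophyly_with_outgroup_rerooting():
    labels = ["A", "B", "C", "D"]
    values = np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]], dtype=float)
    unrooted = phylo.neighbor_joining(phylo.DistanceMatrix(labels, values))
    assert phylo.is_monophyletic(unrooted, ["A", "B"], outgroup="D")
    assert not phylo.is_monophyletic(unrooted, ["A", "C"], outgroup="D")
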