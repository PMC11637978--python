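"""Shared tree helpers for phylogenetics tests (oracles and generators)."""

from __future__ import annotations

import random

import dendropy
import numpy as np


def patristic(tree: dendropy.Tree) -> dict[tuple[str, str], float]:
    """Leaf-to-leaf path lengths, keyed by sorted label pairs."""
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    for i, a in enumerate(taxa):
        for b in taxa[i + 1 :]:
            out[(a.label, b.label)] = pdm.patristic_distance(a, b)
    return out


def random_additive_case(rng: random.Random, n_taxa: int):
    """A random binary tree with positive branch lengths and its distance matrix."""
    labels = [f"T{i}" for i in range(n_taxa)]
    tree = dendropy.Tree(taxon_namespace=dendropy.TaxonNamespace(labels))
    root = tree.seed_node
    for lab in labels[:3]:
        child = root.new_child()
        child.taxon = tree.taxon_namespace.get_taxon(lab)
        child.edge.length = rng.uniform(0.5, 2.0)
    for lab in labels[3:]:
        edges = [e for e in tree.preorder_edge_iter() if e.head_node.parent_node is not None]
        edge = rng.choice(edges)
        old_len = edge.length
        parent, child = edge.tail_node, edge.head_node
        mid = dendropy.Node()
        parent.remove_child(child)
        parent.add_child(mid)
        f = rng.uniform(0.2, 0.8)
        mid.edge.length = old_len * f
        mid.add_child(child)
        child.edge.length = old_len * (1 - f)
        leaf = mid.new_child()
        leaf.taxon = tree.taxon_namespace.get_taxon(lab)
        leaf.edge.length = rng.uniform(0.5, 2.0)
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    values = np.zeros((n_taxa, n_taxa))
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                values[i, j] = values[j, i] = pdm.patristic_distance(taxa[a], taxa[b])
    return labels, values


def oracle_min_losses(tree: dendropy.Tree, present: set[str]) -> int:
    """Brute force over all single-gain placements and loss-subtree subsets."""
    best = None
    for gain in tree.preorder_node_iter():
        under = {l.taxon.label for l in gain.leaf_iter()}
        if not present <= under:
            continue
        below = [n for n in gain.preorder_iter() if n is not gain]
        leafsets = [{l.taxon.label for l in n.leaf_iter()} for n in below]
        for mask in range(1 << len(below)):
            chosen = [i for i in range(len(below)) if mask >> i & 1]
            if any(leafsets[i] & present for i in chosen):
                continue
            lost = set().union(*(leafsets[i] for i in chosen)) if chosen else set()
            if under - lost == present:
                best = len(chosen) if best is None else min(best, len(chosen))
    assert best is not None
    return best
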