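"""Dollo-parsimony origin inference, neighbor joining and monophyly tests.

Dollo parsimony allows a character (here: possession of an ortholog) to be
gained exactly once and lost any number of times.  On a rooted species tree
the unique loss-minimizing single-gain placement is the most recent common
ancestor (MRCA) of all species possessing the protein; the implied losses are
the maximal subtrees below that origin containing no present species.

Neighbor joining is the classical agglomerative algorithm on a distance
matrix: iteratively join the pair minimizing
``Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k)`` with the standard
rate-corrected branch lengths.  Ties on Q are broken toward the
lexicographically smallest label pair (clusters keyed by their smallest leaf
label) and negative branch lengths are clamped to zero with the deficit
transferred to the sister branch, so the algorithm is fully deterministic
and exact on additive matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_formats import PresenceMatrix, SpeciesTree, ValidationError

__all__ = [
    "DistanceMatrix",
    "DolloResult",
    "dollo_origin",
    "dollo_origins",
    "neighbor_joining",
    "is_monophyletic",
    "read_distance_matrix",
    "write_distance_matrix",
]


# ---------------------------------------------------------------------------
# Dollo parsimony
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DolloResult:
    """Origin and implied losses for one protein under Dollo parsimony."""

    protein: str
    origin_label: str
    origin_leaves: tuple[str, ...]
    loss_events: tuple[tuple[str, ...], ...]  # leaf sets of maximal lost clades
    n_losses: int


def _leaf_labels(node: dendropy.Node) -> tuple[str, ...]:
    return tuple(sorted(l.taxon.label for l in node.leaf_iter()))


def _node_label(node: dendropy.Node) -> str:
    if node.is_leaf():
        return node.taxon.label
    if node.label:
        return node.label
    return "(" + ",".join(_leaf_labels(node)) + ")"


def dollo_origin(
    tree: SpeciesTree, presence: Mapping[str, bool], protein: str = ""
) -> DolloResult:
    """Infer a protein's origin node and loss events from its distribution.

    ``presence`` maps leaf label -> bool; at least one leaf must be present.
    """
    tree_leaves = {l.taxon.label for l in tree.leaf_node_iter()}
    unknown = set(presence) - tree_leaves
    if unknown:
        raise ValidationError(f"presence entries not in tree: {sorted(unknown)}")
    present = {sp for sp, p in presence.items() if p}
    if not present:
        raise ValidationError(f"protein {protein or '?'}: present in no species")

    if len(present) == 1:
        (only,) = present
        origin = next(
            l for l in tree.leaf_node_iter() if l.taxon.label == only
        )
    else:
        origin = tree.mrca(taxon_labels=sorted(present))

    # Maximal subtrees below the origin containing no present leaf.
    losses: list[tuple[str, ...]] = []

    def walk(node: dendropy.Node) -> None:
        for child in node.child_nodes():
            leaves = set(l.taxon.label for l in child.leaf_iter())
            if leaves & present:
                walk(child)
            else:
                losses.append(tuple(sorted(leaves)))

    walk(origin)
    losses.sort()
    return DolloResult(
        protein=protein,
        origin_label=_node_label(origin),
        origin_leaves=_leaf_labels(origin),
        loss_events=tuple(losses),
        n_losses=len(losses),
    )


def dollo_origins(
    tree: SpeciesTree,
    matrix: PresenceMatrix,
    uncertain_policy: str = "as-absent",
) -> dict[str, DolloResult | tuple[DolloResult, DolloResult]]:
    """Dollo origin per protein of a presence matrix.

    Uncertain cells are resolved by policy: ``as-absent`` (default, the
    conservative call for tentative orthologs), ``as-present``, or ``both``
    (returns the pair of results, absent-resolution first).
    """
    if uncertain_policy not in ("as-absent", "as-present", "both"):
        raise ValueError(f"unknown uncertain policy {uncertain_policy!r}")
    out: dict[str, DolloResult | tuple[DolloResult, DolloResult]] = {}
    for protein in matrix.proteins:
        row = matrix.presence.loc[protein]
        unc = matrix.uncertain.loc[protein]
        as_absent = {sp: bool(row[sp]) and not bool(unc[sp]) for sp in matrix.species}
        as_present = {sp: bool(row[sp]) for sp in matrix.species}
        if uncertain_policy == "as-absent":
            out[protein] = dollo_origin(tree, as_absent, protein)
        elif uncertain_policy == "as-present":
            out[protein] = dollo_origin(tree, as_present, protein)
        else:
            out[protein] = (
                dollo_origin(tree, as_absent, protein),
                dollo_origin(tree, as_present, protein),
            )
    return out


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if len(set(self.labels)) != n:
            raise ValidationError("duplicate taxa labels")
        if not np.allclose(self.values, self.values.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        if np.any(self.values < -1e-12):
            raise ValidationError("distances must be non-negative")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(list(df.index.astype(str)), df.to_numpy(dtype=float))


def write_distance_matrix(d: DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(d.values, index=d.labels, columns=d.labels).to_csv(
        path, sep="\t", index_label="taxon"
    )


def neighbor_joining(d: DistanceMatrix) -> dendropy.Tree:
    """Classical NJ; returns an unrooted tree with branch lengths.

    Exact on additive matrices.  See the module docstring for tie-breaking
    and negative-branch handling.
    """
    n0 = len(d.labels)
    if n0 < 3:
        raise ValidationError("neighbor joining needs at least 3 taxa")

    taxa = dendropy.TaxonNamespace(d.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes: dict[str, dendropy.Node] = {}
    for label in d.labels:
        node = dendropy.Node()
        node.taxon = taxa.get_taxon(label)
        nodes[label] = node

    # Active clusters keyed by their smallest member leaf label.
    keys = sorted(d.labels)
    idx = {lab: i for i, lab in enumerate(d.labels)}
    dist: dict[tuple[str, str], float] = {}
    for a in keys:
        for b in keys:
            if a < b:
                dist[(a, b)] = float(d.values[idx[a], idx[b]])

    def get(a: str, b: str) -> float:
        return dist[(a, b)] if a < b else dist[(b, a)]

    active = list(keys)
    while len(active) > 3:
        n = len(active)
        r = {a: sum(get(a, b) for b in active if b != a) for a in active}
        best: tuple[float, str, str] | None = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (n - 2) * get(a, b) - r[a] - r[b]
                cand = (q, a, b)
                if best is None or q < best[0] - 1e-12 or (
                    abs(q - best[0]) <= 1e-12 and (a, b) < (best[1], best[2])
                ):
                    best = cand
        _, a, b = best  # type: ignore[misc]
        dab = get(a, b)
        ba = 0.5 * dab + (r[a] - r[b]) / (2 * (n - 2))
        bb = dab - ba
        if ba < 0:
            bb += ba
            ba = 0.0
        elif bb < 0:
            ba += bb
            bb = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        nodes[a].edge.length = ba
        parent.add_child(nodes[b])
        nodes[b].edge.length = bb
        new_key = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (get(a, c) + get(b, c) - dab)
            lo, hi = sorted((new_key, c))
            dist[(lo, hi)] = duc
        active = [c for c in active if c not in (a, b)]
        active.append(new_key)
        active.sort()
        nodes[new_key] = parent

    a, b, c = active
    dab, dac, dbc = get(a, b), get(a, c), get(b, c)
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    root = tree.seed_node
    for key, ln in ((a, la), (b, lb), (c, lc)):
        root.add_child(nodes[key])
        nodes[key].edge.length = max(ln, 0.0)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Monophyly
# ---------------------------------------------------------------------------


def is_monophyletic(
    tree: dendropy.Tree,
    taxa_subset: Sequence[str],
    outgroup: str | None = None,
) -> bool:
    """True iff the subset is exactly the leaf set of some clade.

    For an unrooted tree an outgroup must be given; the tree is (re)rooted on
    it before the clade test.  Singleton subsets are trivially monophyletic.
    """
    subset = set(taxa_subset)
    if not subset:
        raise ValidationError("empty taxa subset")
    work = tree.clone(depth=1)
    labels = {l.taxon.label for l in work.leaf_node_iter()}
    unknown = subset - labels
    if unknown:
        raise ValidationError(f"unknown taxa: {sorted(unknown)}")
    if outgroup is not None:
        if outgroup not in labels:
            raise ValidationError(f"unknown outgroup {outgroup!r}")
        if outgroup in subset:
            raise ValidationError("outgroup cannot be part of the tested subset")
        og = next(l for l in work.leaf_node_iter() if l.taxon.label == outgroup)
        work.reroot_at_edge(og.edge, update_bipartitions=False)
    elif not work.is_rooted:
        raise ValidationError("unrooted tree: an outgroup is required")
    if len(subset) == 1:
        return True
    mrca = work.mrca(taxon_labels=sorted(subset))
    clade = {l.taxon.label for l in mrca.leaf_iter()}
    return clade == subset
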