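"""Neighbour-joining trees from K2P distances, with bootstrap support.

The agglomeration follows the standard Q-matrix formulation and is fully
deterministic: among tied Q minima the smallest (i, j) index pair is
joined, and negative branch length estimates are clamped to zero. Trees
are dendropy objects, so Newick export, bipartition encoding and
path-length queries come for free.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import dendropy
import numpy as np

from .distances import (
    DistanceMatrix,
    UndefinedDistanceError,
    _pair_counts_encoded,
    encode,
    k2p,
)
from .seqio import BarcodeRecord

__all__ = ["nj", "bootstrap_support", "monophyly_check", "tree_to_newick"]


def _nj_topology(d: np.ndarray, ids: Sequence[str], namespace: dendropy.TaxonNamespace) -> dendropy.Tree:
    n = len(ids)
    nodes: list[dendropy.Node] = []
    for sid in ids:
        node = dendropy.Node()
        node.taxon = namespace.require_taxon(label=sid)
        nodes.append(node)
    D = d.astype(float).copy()

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # argmin scans row-major, so the first minimum is the smallest (i, j)
        flat = int(np.argmin(Q))
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = D[i, j] - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        nodes[i].edge.length = max(li, 0.0)
        parent.add_child(nodes[j])
        nodes[j].edge.length = max(lj, 0.0)
        dnew = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep], dnew[keep]])
        D = np.hstack([D, np.append(dnew[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # resolve the final three nodes around an unrooted central vertex
    root = dendropy.Node()
    (a, b, c) = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    for node, length in ((a, la), (b, lb), (c, lc)):
        root.add_child(node)
        node.edge.length = max(length, 0.0)
    tree = dendropy.Tree(taxon_namespace=namespace, seed_node=root)
    tree.is_rooted = False
    return tree


def nj(m: DistanceMatrix, namespace: Optional[dendropy.TaxonNamespace] = None) -> dendropy.Tree:
    """Neighbour-joining tree from a complete distance matrix.

    Requires at least three taxa and no undefined (NaN) entries; offending
    pairs are listed in the error.
    """
    if len(m) < 3:
        raise ValueError("nj needs at least three taxa")
    undefined = m.undefined_pairs
    if undefined:
        raise UndefinedDistanceError(f"undefined distances for pairs: {undefined}")
    if namespace is None:
        namespace = dendropy.TaxonNamespace()
    return _nj_topology(m.d, m.ids, namespace)


def _nontrivial_bitmasks(tree: dendropy.Tree) -> set[int]:
    """Normalised split bitmasks of the internal (non-leaf) edges."""
    tree.encode_bipartitions()
    n_taxa = len(tree.taxon_namespace)
    out = set()
    for bipartition in tree.bipartition_encoding:
        mask = bipartition.split_bitmask
        size = bin(mask).count("1")
        if 1 < size < n_taxa - 1:
            out.add(mask)
    return out


def _matrix_from_coded(coded: np.ndarray, ids: Sequence[str]) -> DistanceMatrix:
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                dij = k2p(_pair_counts_encoded(coded[i], coded[j]))
            except UndefinedDistanceError:
                dij = np.nan
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(list(ids), d)


def bootstrap_support(
    records: Sequence[BarcodeRecord], B: int = 5000, seed: int = 0
) -> dendropy.Tree:
    """NJ tree with column-resampling bootstrap support on internal edges.

    Alignment columns are resampled with replacement ``B`` times; each
    replicate matrix is re-estimated and its NJ tree rebuilt. The support
    of an internal edge of the full-data tree is the percentage of
    replicates containing the same bipartition, written as the head-node
    label (rounded to one decimal). Reproducible bit-exact given ``seed``.
    Replicates with saturated pairs are built on the defined distances'
    tree only if complete; otherwise the replicate counts against all
    supports (conservative).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    coded = np.array([encode(r.sequence) for r in records])
    ids = [r.specimen_id for r in records]
    namespace = dendropy.TaxonNamespace()
    full = _matrix_from_coded(coded, ids)
    tree = nj(full, namespace)
    target = _nontrivial_bitmasks(tree)
    counts = {mask: 0 for mask in target}
    rng = np.random.default_rng(seed)
    n_sites = coded.shape[1]
    for _ in range(B):
        cols = rng.integers(0, n_sites, n_sites)
        rep_matrix = _matrix_from_coded(coded[:, cols], ids)
        if rep_matrix.undefined_pairs:
            continue
        rep_masks = _nontrivial_bitmasks(_nj_topology(rep_matrix.d, ids, namespace))
        for mask in target & rep_masks:
            counts[mask] += 1
    tree.encode_bipartitions()
    for edge in tree.preorder_edge_iter():
        head = edge.head_node
        if head.is_leaf() or edge.bipartition is None:
            continue
        mask = edge.bipartition.split_bitmask
        if mask in counts:
            head.label = f"{100.0 * counts[mask] / B:.1f}"
    return tree


def monophyly_check(
    tree: dendropy.Tree, species_labels: Mapping[str, str]
) -> dict[str, bool]:
    """Is each species' specimen set isolated by some edge of the tree?

    Works on the unrooted topology: a species is monophyletic when its
    leaf set equals one side of any edge bipartition. Singleton species
    are monophyletic by convention.
    """
    leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    missing = [l for l in leaves if l not in species_labels]
    if missing:
        raise ValueError(f"species labels missing for leaves: {missing}")
    all_leaves = frozenset(leaves)
    sides: set[frozenset[str]] = set()
    for node in tree.preorder_node_iter():
        clade = frozenset(l.taxon.label for l in node.leaf_iter())
        sides.add(clade)
        sides.add(all_leaves - clade)
    by_species: dict[str, set[str]] = {}
    for leaf in leaves:
        by_species.setdefault(species_labels[leaf], set()).add(leaf)
    return {
        sp: len(members) == 1 or frozenset(members) in sides
        for sp, members in by_species.items()
    }


def tree_to_newick(tree: dendropy.Tree) -> str:
    """Newick string with branch lengths to 6 decimals and support labels."""
    return tree.as_string(
        schema="newick",
        real_value_format_specifier=".6f",
        suppress_rooting=True,
    ).strip()
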