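"""Neighbor-joining trees, column-bootstrap support, and species clusters.

NJ follows the classic agglomeration: at each step join the pair (i, j)
minimising Q(i,j) = (n-2) d(i,j) - r_i - r_j with r_i the row sum of the
current matrix, assign the rate-corrected split branch lengths, and reduce
the matrix with the average formula.  Negative branch lengths are clamped
to zero and the deficit moved onto the sister branch so path lengths are
preserved.  Trees are dendropy objects, so Newick round-trips are free.

Species-cluster assessment roots the tree on the outgroup and, for every
nominal species, counts the minimal number of disjoint clades whose leaf
union is exactly that species' specimens (the minimal clade cover); one
clade means the species is monophyletic on the tree.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import dendropy
import numpy as np
import pandas as pd

from .distances import DistanceMatrix, distance_matrix_from_encoded, encode_sequences
from .library_io import ReferenceLibrary


def nj(matrix: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a complete distance matrix.

    Raises on masked (undefined) entries or fewer than 3 leaves.  The
    result is unrooted (dendropy's basal trifurcation).
    """
    n = len(matrix)
    if n < 3:
        raise ValueError("NJ needs at least 3 leaves")
    if np.isnan(matrix.d).any():
        bad = [matrix.voucher_ids[i] for i in sorted(set(np.argwhere(np.isnan(matrix.d))[:, 0]))]
        raise ValueError(f"masked distances block NJ (vouchers involved: {bad[:5]} ...)")

    taxa = dendropy.TaxonNamespace(matrix.voucher_ids)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for label in matrix.voucher_ids:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
    # preallocated working matrix: at most n-3 internal joins are added
    size = 2 * n - 2
    D = np.zeros((size, size), dtype=float)
    D[:n, :n] = matrix.d
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        ix = np.asarray(active)
        sub = D[np.ix_(ix, ix)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = int(np.argmin(q))
        ai, aj = divmod(flat, m)
        i, j = active[ai], active[aj]
        dij = D[i, j]
        vi = 0.5 * dij + (r[ai] - r[aj]) / (2.0 * (m - 2))
        vj = dij - vi
        # clamp negatives, moving the deficit to the sister branch
        if vi < 0:
            vj += vi
            vi = 0.0
        if vj < 0:
            vi += vj
            vj = 0.0
        parent = dendropy.Node()
        nodes[i].edge.length = max(vi, 0.0)
        nodes[j].edge.length = max(vj, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # reduced distances to the new node (average formula)
        u = len(nodes)
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D[u, :] = new_row
        D[:, u] = new_row
        D[u, u] = 0.0
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [u]

    # final three-point join (trifurcating root)
    a, b, c = active
    dab, dac, dbc = D[a, b], D[a, c], D[b, c]
    va = 0.5 * (dab + dac - dbc)
    vb = 0.5 * (dab + dbc - dac)
    vc = 0.5 * (dac + dbc - dab)
    root = dendropy.Node()
    for node, v in ((nodes[a], va), (nodes[b], vb), (nodes[c], vc)):
        node.edge.length = max(v, 0.0)
        root.add_child(node)
    tree.seed_node = root
    tree.is_rooted = False
    tree.update_bipartitions(suppress_unifurcations=False)
    return tree


def _split_set(tree: dendropy.Tree, leaf_labels: frozenset[str]) -> set[frozenset[str]]:
    """Nontrivial unrooted splits as canonical leaf-label sets.

    Each split is represented by the side not containing a fixed reference
    leaf (the lexicographically smallest label), so splits compare equal
    across differently rooted copies of the same topology.
    """
    ref = min(leaf_labels)
    splits = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = frozenset(leaf_labels - below) if ref in below else below
        if 1 < len(side) < len(leaf_labels) - 1:
            splits.add(side)
    return splits


def bootstrap(
    library: ReferenceLibrary,
    n_replicates: int = 1000,
    seed: int | None = None,
    matrix: DistanceMatrix | None = None,
) -> dendropy.Tree:
    """NJ tree with column-bootstrap support on internal edges.

    Alignment columns are resampled uniformly with replacement; each
    replicate's matrix is rebuilt and its NJ tree's splits collected.
    Support on an internal edge of the point tree is the percentage of
    replicates containing the same bipartition, stored as the node label.
    ``n_replicates=0`` returns the unannotated point tree.
    """
    encoded = encode_sequences([r.sequence for r in library])
    if matrix is None:
        matrix = distance_matrix_from_encoded(encoded, library.voucher_ids)
    point_tree = nj(matrix)
    if n_replicates == 0:
        return point_tree
    rng = np.random.default_rng(seed)
    leaf_labels = frozenset(library.voucher_ids)
    counts: dict[frozenset[str], int] = defaultdict(int)
    n_cols = encoded.shape[1]
    for _ in range(n_replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        rep_matrix = distance_matrix_from_encoded(encoded[:, cols], library.voucher_ids)
        if np.isnan(rep_matrix.d).any():
            continue  # saturated replicate; skipped, support denominators unchanged
        for split in _split_set(nj(rep_matrix), leaf_labels):
            counts[split] += 1
    ref = min(leaf_labels)
    split_support: dict[frozenset[str], float] = {}
    for node in point_tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = frozenset(leaf_labels - below) if ref in below else below
        if 1 < len(side) < len(leaf_labels) - 1:
            support = 100.0 * counts.get(side, 0) / n_replicates
            split_support[side] = support
            node.label = f"{support:.0f}"
    # splits are unrooted, node labels are not: keep the split-keyed map on
    # the tree so support survives rerooting
    point_tree.split_support = split_support
    return point_tree


@dataclass
class SpeciesClusters:
    species: str
    n_leaves: int
    n_clusters: int
    forms_single_cluster: bool
    support: float | None          # bootstrap of the species clade when single
    intruding_species: frozenset[str]  # foreign species inside the spanning clade


@dataclass
class ClusterReport:
    per_species: list[SpeciesClusters]

    @property
    def n_single_cluster(self) -> int:
        return sum(1 for s in self.per_species if s.forms_single_cluster)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "species": s.species,
                    "n_leaves": s.n_leaves,
                    "n_clusters": s.n_clusters,
                    "single_cluster": s.forms_single_cluster,
                    "support": s.support if s.support is not None else np.nan,
                    "intruders": "|".join(sorted(s.intruding_species)),
                }
                for s in self.per_species
            ]
        )


def species_clusters(
    tree: dendropy.Tree,
    library: ReferenceLibrary,
    outgroup: str,
) -> ClusterReport:
    """Minimal clade cover of every species on the outgroup-rooted tree."""
    labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if outgroup not in labels:
        raise ValueError(f"outgroup voucher {outgroup!r} not on the tree")
    split_support: dict[frozenset[str], float] = getattr(tree, "split_support", {})
    leaf_labels = frozenset(labels)
    ref = min(leaf_labels)
    tree = tree.clone(depth=1)
    og_node = tree.find_node_with_taxon_label(outgroup)
    tree.to_outgroup_position(og_node, update_bipartitions=False, suppress_unifurcations=True)

    # the outgroup leaf carries a sentinel so no clade containing it is
    # ever monochromatic for an ingroup species
    species_of = {r.voucher_id: r.nominal_species for r in library if not r.is_outgroup}
    _OUT = "\x00outgroup"

    sp_set: dict[int, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            sp = species_of.get(node.taxon.label, _OUT)
            sp_set[id(node)] = frozenset([sp])
        else:
            acc: set[str] = set()
            for ch in node.child_nodes():
                acc |= sp_set[id(ch)]
            sp_set[id(node)] = frozenset(acc)

    def mono_species(node) -> str | None:
        s = sp_set[id(node)]
        if len(s) == 1 and _OUT not in s:
            return next(iter(s))
        return None

    clusters: dict[str, int] = defaultdict(int)
    support: dict[str, float | None] = {}
    for node in tree.preorder_node_iter():
        sp = mono_species(node)
        if sp is None:
            continue
        parent = node.parent_node
        if parent is not None and mono_species(parent) == sp:
            continue  # not maximal
        clusters[sp] += 1
        if not node.is_leaf():
            below = frozenset(lf.taxon.label for lf in node.leaf_iter())
            side = frozenset(leaf_labels - below) if ref in below else below
            if side in split_support:
                support[sp] = split_support[side]
            elif node.label is not None:
                try:
                    support[sp] = float(node.label)
                except ValueError:
                    pass

    members: dict[str, list] = defaultdict(list)
    for lf in tree.leaf_node_iter():
        sp = species_of.get(lf.taxon.label)
        if sp:
            members[sp].append(lf)

    def spanning_clade(leaves) -> dendropy.Node:
        """Smallest clade containing all the given leaves (walk up from one)."""
        want = {id(lf) for lf in leaves}
        node = leaves[0]
        while node.parent_node is not None:
            have = {id(lf) for lf in node.leaf_iter()}
            if want <= have:
                return node
            node = node.parent_node
        return node

    per_species = []
    for sp in sorted(members):
        n_leaves = len(members[sp])
        n_clusters = clusters.get(sp, 0)
        single = n_clusters == 1
        intruders: frozenset[str] = frozenset()
        if not single:
            mrca = spanning_clade(members[sp])
            intruders = frozenset(s for s in sp_set[id(mrca)] - {sp} if s != _OUT)
        sup = support.get(sp) if single and n_leaves > 1 else None
        per_species.append(
            SpeciesClusters(sp, n_leaves, n_clusters, single, sup, intruders)
        )
    return ClusterReport(per_species)


def read_newick(path_or_string: str, is_path: bool = True) -> dendropy.Tree:
    src = {"path": path_or_string} if is_path else {"data": path_or_string}
    return dendropy.Tree.get(schema="newick", **src)


def write_newick(tree: dendropy.Tree, path: str) -> None:
    tree.write(path=path, schema="newick", suppress_rooting=True)
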