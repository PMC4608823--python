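import itertools

import dendropy
import numpy as np
import pytest

from barcode_librarian.distances import distance_matrix
from barcode_librarian.library_io import ReferenceLibrary
from barcode_librarian.njtree import (
    bootstrap,
    nj,
    read_newick,
    species_clusters,
    write_newick,
)

from conftest import make_matrix, make_record


def patristic_matrix(tree, labels):
    """Leaf-to-leaf path lengths from a dendropy tree."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(labels)
    out = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
        out[i, j] = out[j, i] = d
    return out


def splits(tree):
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = min(labels)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        side = frozenset(labels - below) if ref in below else below
        if 1 < len(side) < len(labels) - 1:
            out.add(side)
    return out


def random_additive_matrix(n_leaves, seed):
    """Random binary tree with positive branch lengths -> path-length matrix."""
    rng = np.random.default_rng(seed)
    labels = [f"L{i}" for i in range(n_leaves)]
    taxa = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        node.edge.length = float(rng.uniform(0.01, 0.1))
        nodes.append(node)
    while len(nodes) > 2:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.edge.length = float(rng.uniform(0.01, 0.1))
        parent.add_child(nodes.pop(j))
        parent.add_child(nodes.pop(i))
        nodes.append(parent)
    root = dendropy.Node()
    for node in nodes:
        root.add_child(node)
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = False
    return patristic_matrix(tree, labels), labels, tree


def ls_quartet_oracle(d):
    """Least-squares fit of the 3 quartet topologies to a 4x4 matrix.

    For topology AB|CD the five branch lengths solve the standard
    four-point system; the best topology is the one with the smallest
    residual.  Returns the winning pairing as a frozenset pair.
    """
    best = None
    for (a, b), (c, dd) in [((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2))]:
        # internal branch estimate from the four-point condition
        s1 = d[a, c] + d[b, dd]
        s2 = d[a, dd] + d[b, c]
        s0 = d[a, b] + d[c, dd]
        internal = (s1 + s2) / 2 - s0
        resid = abs(s1 - s2) + max(0.0, -internal)
        if best is None or resid < best[0]:
            best = (resid, frozenset([frozenset([a, b]), frozenset([c, dd])]))
    return best[1]


class TestNJ:
    def test_three_leaves_solve_three_point_equations(self):
        d = np.array([[0, 0.3, 0.5], [0.3, 0, 0.6], [0.5, 0.6, 0]])
        m = make_matrix(["A", "B", "C"], d)
        tree = nj(m)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        # closed form: v_a = (d_ab + d_ac - d_bc)/2 etc.
        assert lengths["A"] == pytest.approx(0.1)
        assert lengths["B"] == pytest.approx(0.2)
        assert lengths["C"] == pytest.approx(0.4)

    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) scaled by 0.01
        src = read_newick("((A:0.01,B:0.02):0.01,(C:0.03,D:0.04):0.0);", is_path=False)
        labels = ["A", "B", "C", "D"]
        d = patristic_matrix(src, labels)
        tree = nj(make_matrix(labels, d))
        # oracle: best least-squares quartet topology
        want = ls_quartet_oracle(d)
        assert want == frozenset([frozenset([0, 1]), frozenset([2, 3])])
        assert splits(tree) == {frozenset({"C", "D"})} or splits(tree) == {
            frozenset({"A", "B"})
        }
        # branch lengths exactly reproduce the path-length matrix
        assert np.allclose(patristic_matrix(tree, labels), d, atol=1e-12)

    @pytest.mark.parametrize("n_leaves,seed", [(4, 0), (5, 1), (6, 2), (8, 3)])
    def test_additive_matrices_reproduced_exactly(self, n_leaves, seed):
        d, labels, src = random_additive_matrix(n_leaves, seed)
        tree = nj(make_matrix(labels, d))
        assert np.allclose(patristic_matrix(tree, labels), d, atol=1e-9)
        assert splits(tree) == splits(src)

    def test_agrees_with_independent_nj_implementation(self):
        # scikit-bio's neighbor joining as the independent cross-check on a
        # noisy (non-additive) matrix
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(12)
        d0, labels, _ = random_additive_matrix(7, 21)
        noise = rng.uniform(0, 0.004, d0.shape)
        noise = (noise + noise.T) / 2
        np.fill_diagonal(noise, 0)
        d = d0 + noise
        ours = nj(make_matrix(labels, d))
        theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids=labels))
        theirs_dp = read_newick(str(theirs).strip(), is_path=False)
        assert splits(ours) == splits(theirs_dp)

    def test_leaf_permutation_invariance(self):
        d, labels, _ = random_additive_matrix(6, 5)
        perm = [3, 0, 5, 1, 4, 2]
        d2 = d[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        assert splits(nj(make_matrix(labels, d))) == splits(
            nj(make_matrix(labels2, d2))
        )

    def test_masked_entries_and_tiny_matrices_rejected(self):
        d = np.array([[0, np.nan, 0.1], [np.nan, 0, 0.1], [0.1, 0.1, 0]])
        with pytest.raises(ValueError):
            nj(make_matrix(["A", "B", "C"], d))
        with pytest.raises(ValueError):
            nj(make_matrix(["A", "B"], np.array([[0, 0.1], [0.1, 0]])))


class TestBootstrap:
    def test_zero_replicates_returns_point_tree(self, small_sim):
        lib, _ = small_sim
        sub = lib.subset(lib.voucher_ids[:10])
        t0 = nj(distance_matrix(sub))
        t1 = bootstrap(sub, n_replicates=0)
        assert splits(t0) == splits(t1)
        assert all(n.label is None for n in t1.preorder_internal_node_iter())

    def test_support_reproducible_given_seed(self, small_sim):
        lib, _ = small_sim
        sub = lib.subset(lib.voucher_ids[:12])
        t1 = bootstrap(sub, n_replicates=20, seed=4)
        t2 = bootstrap(sub, n_replicates=20, seed=4)
        lab1 = sorted(n.label for n in t1.preorder_internal_node_iter() if n.label)
        lab2 = sorted(n.label for n in t2.preorder_internal_node_iter() if n.label)
        assert lab1 == lab2 and lab1

    def test_species_clades_get_high_support_when_separated(self, small_sim):
        lib, truth = small_sim
        vouchers = [v for v in lib.voucher_ids][:30] + ["OUTG0001"]
        sub = lib.subset([v for v in lib.voucher_ids if v in set(vouchers)])
        tree = bootstrap(sub, n_replicates=50, seed=9)
        report = species_clusters(tree, sub, "OUTG0001")
        supports = [
            s.support for s in report.per_species
            if s.n_leaves > 1 and s.support is not None
        ]
        assert supports
        assert min(supports) >= 98.0


def library_from_tree_species(species_of):
    return ReferenceLibrary(
        [
            make_record(
                v,
                sp if sp != "out" else "Out out",
                sp.split()[0] if sp != "out" else "Out",
                "Eristalinae" if sp != "out" else "outgroup",
                "ACGT",
            )
            for v, sp in species_of.items()
        ]
    )


class TestSpeciesClusters:
    def test_contiguous_caterpillar_species_are_single_clusters(self):
        tree = read_newick(
            "((((A1:1,A2:1):1,(B1:1,B2:1):1):1,C1:1):1,out:1);", is_path=False
        )
        lib = library_from_tree_species(
            {"A1": "Sp a", "A2": "Sp a", "B1": "Sp b", "B2": "Sp b",
             "C1": "Sp c", "out": "out"}
        )
        report = species_clusters(tree, lib, "out")
        assert all(s.forms_single_cluster for s in report.per_species)
        assert {s.species: s.n_clusters for s in report.per_species} == {
            "Sp a": 1, "Sp b": 1, "Sp c": 1
        }

    def test_broken_species_counts_two_clusters(self):
        # hand evaluation: A = {A1, A2}; B1 separates them, so the minimal
        # clade cover of A has two clades
        tree = read_newick("((A1:1,(B1:1,A2:1):1):1,out:1);", is_path=False)
        lib = library_from_tree_species(
            {"A1": "Sp a", "A2": "Sp a", "B1": "Sp b", "out": "out"}
        )
        report = species_clusters(tree, lib, "out")
        by_sp = {s.species: s for s in report.per_species}
        assert by_sp["Sp a"].n_clusters == 2
        assert not by_sp["Sp a"].forms_single_cluster
        assert by_sp["Sp a"].intruding_species == {"Sp b"}
        assert by_sp["Sp b"].n_clusters == 1

    def test_singleton_species_trivially_single(self):
        tree = read_newick("((A1:1,(B1:1,A2:1):1):1,out:1);", is_path=False)
        lib = library_from_tree_species(
            {"A1": "Sp a", "A2": "Sp a", "B1": "Sp b", "out": "out"}
        )
        report = species_clusters(tree, lib, "out")
        by_sp = {s.species: s for s in report.per_species}
        assert by_sp["Sp b"].forms_single_cluster

    def test_cluster_sum_bound(self, small_sim):
        lib, _ = small_sim
        tree = nj(distance_matrix(lib))
        report = species_clusters(tree, lib, "OUTG0001")
        n_species = len(report.per_species)
        total = sum(s.n_clusters for s in report.per_species)
        assert total >= n_species
        if all(s.forms_single_cluster for s in report.per_species):
            assert total == n_species

    def test_missing_outgroup_rejected(self, small_sim):
        lib, _ = small_sim
        tree = nj(distance_matrix(lib))
        with pytest.raises(ValueError):
            species_clusters(tree, lib, "NOPE")

    def test_newick_round_trip(self, tmp_path, small_sim):
        lib, _ = small_sim
        sub = lib.subset(lib.voucher_ids[:8])
        tree = nj(distance_matrix(sub))
        path = str(tmp_path / "t.nwk")
        write_newick(tree, path)
        back = read_newick(path)
        assert splits(back) == splits(tree)
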