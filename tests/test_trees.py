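"""Neighbor joining, OLS branch lengths, branch score distance, jack-knife,
and hierarchical simplification.

The oracle for NJ+OLS is additivity: a distance matrix read off a tree's
leaf-to-leaf path lengths must be reproduced exactly by the reconstruction.
Random additive trees are generated here, independently of the code under
test, by sequential random attachment.
"""

import numpy as np
import pandas as pd
import pytest

import dendropy
from dendropy.calculate import treecompare

from redalph.alphabet_io import (
    AlphabetCollection,
    generate_planted_collection,
    generate_random_alphabet,
    loads_collection,
)
from redalph.bigmat import build_consensus
from redalph.trees import (
    _canonical_splits,
    agglomerate_alphabet,
    branch_score_distance,
    consensus_tree,
    fit_ols_branch_lengths,
    jackknife_consensus,
    neighbor_joining,
    newick_to_tree,
    nj_ols_tree,
    path_length_matrix,
    total_branch_length,
    tree_bipartitions,
    tree_to_newick,
)

# ---------------------------------------------------------------------------
# oracle helpers


def random_additive_tree(rng, n_leaves):
    """Random unrooted tree by sequential attachment, uniform edge lengths."""
    labels = [f"t{i:02d}" for i in range(n_leaves)]
    tns = dendropy.TaxonNamespace(labels)
    center = dendropy.Node()
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    for lab in labels[:3]:
        leaf = dendropy.Node(taxon=tns.get_taxon(lab))
        center.add_child(leaf)
        leaf.edge.length = rng.uniform(0.1, 1.0)
    for lab in labels[3:]:
        edges = [e for e in tree.preorder_edge_iter() if e.tail_node is not None]
        target = edges[rng.integers(len(edges))]
        # split the target edge with a new internal node, hang the leaf there
        tail, head = target.tail_node, target.head_node
        mid = dendropy.Node()
        tail.remove_child(head)
        tail.add_child(mid)
        frac = rng.uniform(0.2, 0.8)
        mid.edge.length = target.length * frac
        mid.add_child(head)
        head.edge.length = target.length * (1 - frac)
        leaf = dendropy.Node(taxon=tns.get_taxon(lab))
        mid.add_child(leaf)
        leaf.edge.length = rng.uniform(0.1, 1.0)
    tree.is_rooted = False
    return tree


def tree_distance_frame(tree):
    return path_length_matrix(tree)


# ---------------------------------------------------------------------------
# neighbor joining


class TestNeighborJoining:
    def test_three_leaves_closed_form(self):
        d = pd.DataFrame(
            [[0, 2, 3], [2, 0, 4], [3, 4, 0]],
            index=list("abc"),
            columns=list("abc"),
            dtype=float,
        )
        tree = neighbor_joining(d)
        lengths = {
            lf.taxon.label: lf.edge.length for lf in tree.leaf_node_iter()
        }
        assert lengths == pytest.approx({"a": 0.5, "b": 1.5, "c": 2.5})

    def test_four_leaf_additive_matrix_recovered(self):
        labels = list("abcd")
        d = pd.DataFrame(
            [[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
            index=labels,
            columns=labels,
            dtype=float,
        )
        tree = neighbor_joining(d)
        assert frozenset({"c", "d"}) in tree_bipartitions(tree)  # split ab|cd
        paths = path_length_matrix(tree)
        assert np.allclose(paths.loc[labels, labels].to_numpy(), d.to_numpy())

    def test_all_equal_distances_tie_break_is_deterministic(self):
        labels = list("abcd")
        d = pd.DataFrame(
            np.ones((4, 4)) - np.eye(4), index=labels, columns=labels
        )
        t1, t2 = neighbor_joining(d), neighbor_joining(d)
        assert tree_to_newick(t1) == tree_to_newick(t2)
        pendants = [lf.edge.length for lf in t1.leaf_node_iter()]
        assert pendants == pytest.approx([0.5] * 4)

    def test_rejects_small_or_asymmetric_input(self):
        with pytest.raises(ValueError, match="at least 3"):
            neighbor_joining(
                pd.DataFrame([[0, 1], [1, 0]], index=list("ab"), columns=list("ab"))
            )
        bad = pd.DataFrame(
            [[0, 1, 2], [1.1, 0, 1], [2, 1, 0]],
            index=list("abc"),
            columns=list("abc"),
        )
        with pytest.raises(ValueError, match="asymmetric"):
            neighbor_joining(bad)

    def test_topology_matches_scikit_bio_reference(self):
        from skbio import DistanceMatrix
        from skbio.tree import nj as skbio_nj

        rng = np.random.default_rng(17)
        truth = random_additive_tree(rng, 8)
        frame = tree_distance_frame(truth)
        # jitter breaks exact additivity (and any Q ties) but keeps topology
        jit = rng.uniform(-0.01, 0.01, size=frame.shape)
        jit = (jit + jit.T) / 2
        np.fill_diagonal(jit, 0.0)
        frame = frame + jit
        mine = neighbor_joining(frame)
        ref = skbio_nj(DistanceMatrix(frame.to_numpy(), ids=list(frame.index)))
        ref_tree = newick_to_tree(str(ref))
        assert tree_bipartitions(mine) == tree_bipartitions(ref_tree)


# ---------------------------------------------------------------------------
# OLS branch lengths


class TestOLS:
    @pytest.mark.parametrize("seed", range(50))
    def test_nj_ols_reproduces_random_additive_matrices(self, seed):
        rng = np.random.default_rng(seed)
        truth = random_additive_tree(rng, int(rng.integers(5, 13)))
        frame = tree_distance_frame(truth)
        fitted = nj_ols_tree(frame)
        paths = path_length_matrix(fitted)
        assert np.allclose(
            paths.loc[frame.index, frame.columns].to_numpy(),
            frame.to_numpy(),
            atol=1e-8,
        )

    def test_true_topology_gives_zero_residual_and_true_lengths(self):
        rng = np.random.default_rng(42)
        truth = random_additive_tree(rng, 7)
        frame = tree_distance_frame(truth)
        fitted = fit_ols_branch_lengths(truth, frame)
        s_true = _canonical_splits(truth)
        s_fit = _canonical_splits(fitted)
        assert set(s_true) == set(s_fit)
        for split, length in s_true.items():
            assert s_fit[split] == pytest.approx(length, abs=1e-8)

    def test_small_perturbation_moves_lengths_continuously(self):
        rng = np.random.default_rng(1)
        truth = random_additive_tree(rng, 6)
        frame = tree_distance_frame(truth)
        base = fit_ols_branch_lengths(truth, frame)
        bumped_frame = frame.copy()
        i, j = frame.index[0], frame.index[1]
        eps = 1e-6
        bumped_frame.loc[i, j] += eps
        bumped_frame.loc[j, i] += eps
        bumped = fit_ols_branch_lengths(truth, bumped_frame)
        b0 = path_length_matrix(base).to_numpy()
        b1 = path_length_matrix(bumped).to_numpy()
        assert np.abs(b1 - b0).max() < 100 * eps

    def test_three_leaf_star_equals_nj_closed_form(self):
        d = pd.DataFrame(
            [[0, 2, 3], [2, 0, 4], [3, 4, 0]],
            index=list("abc"),
            columns=list("abc"),
            dtype=float,
        )
        nj = neighbor_joining(d)
        ols = fit_ols_branch_lengths(nj, d)
        for t1, t2 in zip(nj.leaf_node_iter(), ols.leaf_node_iter()):
            assert t2.edge.length == pytest.approx(t1.edge.length, abs=1e-10)


# ---------------------------------------------------------------------------
# Newick round-trip


class TestNewick:
    @pytest.mark.parametrize(
        "text",
        [
            "((a:1,b:2):1,c:3,d:4);",
            "(a:1,b:1,c:1,d:1,e:1);",  # multifurcation
            "(a:-0.5,b:1,c:2);",  # negative branch length
        ],
    )
    def test_round_trip_preserves_splits_and_lengths(self, text):
        t1 = newick_to_tree(text)
        t2 = newick_to_tree(tree_to_newick(t1))
        assert tree_bipartitions(t1) == tree_bipartitions(t2)
        assert branch_score_distance(t1, t2) == pytest.approx(0.0, abs=1e-9)

    def test_malformed_newick_raises(self):
        with pytest.raises(ValueError, match="Newick"):
            newick_to_tree("((a:1,b:2;")


# ---------------------------------------------------------------------------
# branch score distance


class TestBranchScore:
    def test_identity(self):
        t = newick_to_tree("((a:1,b:2):1,c:3,d:4);")
        assert branch_score_distance(t, t) == 0.0

    def test_single_internal_edge_difference(self):
        t1 = newick_to_tree("((a:1,b:2):1.0,c:3,d:4);")
        t2 = newick_to_tree("((a:1,b:2):1.5,c:3,d:4);")
        assert branch_score_distance(t1, t2) == pytest.approx(0.5)
        assert branch_score_distance(t1, t2, squared=True) == pytest.approx(0.25)

    def test_conflicting_splits_add_in_quadrature(self):
        x, y = 0.7, 0.4
        t1 = newick_to_tree(f"((a:1,b:1):{x},c:1,d:1);")  # ab|cd
        t2 = newick_to_tree(f"((a:1,c:1):{y},b:1,d:1);")  # ac|bd
        assert branch_score_distance(t1, t2) == pytest.approx(np.hypot(x, y))

    def test_leaf_set_mismatch(self):
        t1 = newick_to_tree("(a:1,b:1,c:1);")
        t2 = newick_to_tree("(a:1,b:1,x:1);")
        with pytest.raises(ValueError, match="leaf sets"):
            branch_score_distance(t1, t2)

    @pytest.mark.parametrize("seed", range(8))
    def test_metric_axioms_on_random_tree_triples(self, seed):
        rng = np.random.default_rng(seed)
        trees = [random_additive_tree(np.random.default_rng(100 * seed + k), 7)
                 for k in range(3)]
        a, b, c = trees
        dab = branch_score_distance(a, b)
        dba = branch_score_distance(b, a)
        dac = branch_score_distance(a, c)
        dbc = branch_score_distance(b, c)
        assert dab >= 0 and dab == pytest.approx(dba)
        assert branch_score_distance(a, a) == 0.0
        assert dac <= dab + dbc + 1e-12
        del rng

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dendropy_euclidean_distance(self, seed):
        rng = np.random.default_rng(seed)
        t1 = random_additive_tree(rng, 8)
        t2 = random_additive_tree(rng, 8)
        mine = branch_score_distance(t1, t2)
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=tree_to_newick(t1), schema="newick",
                               taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=tree_to_newick(t2), schema="newick",
                               taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        assert mine == pytest.approx(treecompare.euclidean_distance(d1, d2), abs=1e-9)


# ---------------------------------------------------------------------------
# jack-knife


class TestJackknife:
    def test_identical_alphabets_give_zero_distances(self):
        base = generate_random_alphabet(8, 5)
        coll = generate_planted_collection(base, n=6, noise=0.0, seed=1)
        report = jackknife_consensus(coll)
        assert report.convention == "sqrt"
        assert all(d == pytest.approx(0.0, abs=1e-9) for _, d in report.rows)

    def test_planted_collection_is_robust_to_single_drops(self):
        base = generate_random_alphabet(3, 5)
        coll = generate_planted_collection(base, n=20, noise=0.05, seed=3)
        full = consensus_tree(coll)
        report = jackknife_consensus(coll)
        max_d = max(d for _, d in report.rows)
        assert max_d < 0.10 * total_branch_length(full)

    def test_dropping_either_twin_gives_equal_distance(self):
        base = generate_random_alphabet(9, 4)
        noisy = generate_planted_collection(base, n=8, noise=0.3, seed=5)
        twin_a = noisy[0]
        twin_b = type(twin_a)(
            id="twin_b", name="copy", category=twin_a.category, groups=twin_a.groups
        )
        coll = AlphabetCollection(list(noisy) + [twin_b])
        report = dict(jackknife_consensus(coll).rows)
        assert report[twin_a.id] == pytest.approx(report["twin_b"], abs=1e-9)


# ---------------------------------------------------------------------------
# agglomerative simplification


class TestAgglomerate:
    def test_degenerate_ends(self):
        cons = build_consensus(
            generate_planted_collection(generate_random_alphabet(1, 4), 5, 0.2, 2)
        )
        singles = agglomerate_alphabet(cons, 20)
        assert singles.n_groups == 20
        one = agglomerate_alphabet(cons, 1)
        assert one.n_groups == 1

    @pytest.mark.parametrize("seed", range(5))
    def test_noiseless_planted_base_recovered_at_base_k(self, seed):
        base = generate_random_alphabet(seed, 5)
        coll = generate_planted_collection(base, n=10, noise=0.0, seed=seed)
        cons = build_consensus(coll)
        rec = agglomerate_alphabet(cons, base.n_groups)
        assert rec.same_partition(base)

    def test_k_out_of_range(self):
        cons = build_consensus(
            AlphabetCollection([generate_random_alphabet(1, 5)])
        )
        with pytest.raises(ValueError):
            agglomerate_alphabet(cons, 0)

    def test_published_consensus_sweep_yields_valid_partitions(self, published):
        cons = build_consensus(published)
        for k in range(2, 20):
            a = agglomerate_alphabet(cons, k)
            assert a.n_groups == k  # validator ran in the constructor
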