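"""Progressive alignment, distance correction, and neighbor joining."""

import math

import dendropy
import numpy as np
import pytest
from Bio.Align import PairwiseAligner, substitution_matrices

from evescout import phylo
from evescout.phylo import (
    DistanceMatrix,
    TreeNode,
    corrected_distance,
    msa_distance_matrix,
    nearest_neighbor,
    neighbor_joining,
    patristic_distances,
    patristic_matrix,
    progressive_align,
)
from evescout.seqio import ProteinRecord

AA = "ARNDCQEGHILKMFPSTWYV"


def random_binary_tree(n: int, rng) -> TreeNode:
    """A random unrooted binary tree with strictly positive branch lengths,
    built by splitting random edges."""
    nodes = [TreeNode(name=f"t{i}") for i in range(3)]
    root = TreeNode(
        children=[(nodes[i], float(rng.uniform(0.1, 2.0))) for i in range(3)]
    )

    def edges(node):
        out = []
        for i, (child, _) in enumerate(node.children):
            out.append((node, i))
            out.extend(edges(child))
        return out

    for i in range(3, n):
        es = edges(root)
        parent, ci = es[rng.integers(len(es))]
        child, length = parent.children[ci]
        mid = TreeNode(
            children=[
                (child, length * 0.5),
                (TreeNode(name=f"t{i}"), float(rng.uniform(0.1, 2.0))),
            ]
        )
        parent.children[ci] = (mid, length * 0.5)
    return root


def dendropy_rf(nwk1: str, nwk2: str) -> int:
    tns = dendropy.TaxonNamespace()
    t1 = dendropy.Tree.get(data=nwk1, schema="newick", taxon_namespace=tns)
    t2 = dendropy.Tree.get(data=nwk2, schema="newick", taxon_namespace=tns)
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(t1, t2)


class TestProgressiveAlign:
    def test_identical_pair_gap_free(self):
        msa = progressive_align(
            [ProteinRecord("a", "MKWVLL"), ProteinRecord("b", "MKWVLL")]
        )
        assert msa.rows == ["MKWVLL", "MKWVLL"]

    def test_single_gap_opposite_deletion(self):
        msa = progressive_align(
            [ProteinRecord("a", "ACDEFG"), ProteinRecord("b", "ACEFG")]
        )
        assert msa.row("a") == "ACDEFG"
        assert msa.row("b") == "AC-EFG"

    def test_pairwise_score_matches_independent_global_aligner(self):
        """The two-sequence case is plain global affine alignment; scores
        must match an independent implementation."""
        ref = PairwiseAligner()
        ref.mode = "global"
        ref.substitution_matrix = substitution_matrices.load("BLOSUM62")
        ref.open_gap_score = -11
        ref.extend_gap_score = -1
        m = phylo.load_blosum62()
        rng = np.random.default_rng(0)
        for _ in range(40):
            a = "".join(rng.choice(list(AA), size=rng.integers(5, 25)))
            b = "".join(rng.choice(list(AA), size=rng.integers(5, 25)))
            msa = progressive_align([ProteinRecord("a", a), ProteinRecord("b", b)])
            score = _alignment_score(msa.row("a"), msa.row("b"), m)
            assert score == pytest.approx(ref.score(a, b)), (a, b)

    def test_input_order_invariance(self):
        seqs = [
            ProteinRecord("x", "MKVLAWEFQRNDS"),
            ProteinRecord("y", "MKVLWEFQRNDS"),
            ProteinRecord("z", "MRVLAWGFQKNDS"),
        ]
        ref = progressive_align(seqs)
        for perm in ([2, 0, 1], [1, 2, 0], [2, 1, 0]):
            out = progressive_align([seqs[i] for i in perm])
            assert all(out.row(s.id) == ref.row(s.id) for s in seqs)

    def test_single_sequence_rejected(self):
        with pytest.raises(ValueError):
            progressive_align([ProteinRecord("a", "MKWV")])


def _alignment_score(r1: str, r2: str, matrix) -> float:
    score = 0.0
    in_gap = None
    for a, b in zip(r1, r2):
        if a == "-" or b == "-":
            which = "a" if a == "-" else "b"
            score -= 1.0 if in_gap == which else 11.0
            in_gap = which
        else:
            score += matrix.score(a, b)
            in_gap = None
    return score


class TestCorrectedDistance:
    def test_identical_rows(self):
        assert corrected_distance("MKWV", "MKWV") == 0.0

    def test_half_different(self):
        assert corrected_distance("AAAA", "AAGG") == pytest.approx(math.log(2))

    def test_jensen_bound(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = "".join(rng.choice(list(AA), size=30))
            b = "".join(rng.choice(list(AA), size=30))
            shared = sum(1 for x, y in zip(a, b) if x != "-" and y != "-")
            p = sum(1 for x, y in zip(a, b) if x != y) / shared
            assert corrected_distance(a, b) >= p - 1e-12

    def test_saturated_rows_capped(self):
        assert corrected_distance("AAAA", "GGGG") == 10.0

    def test_no_shared_columns_rejected(self):
        with pytest.raises(ValueError):
            corrected_distance("A---", "---G")


class TestNeighborJoining:
    def test_additive_four_taxon_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)) -> additive matrix
        vals = np.array(
            [
                [0, 3, 5, 6],
                [3, 0, 6, 7],
                [5, 6, 0, 7],
                [6, 7, 0, 0],
            ],
            dtype=float,
        )
        vals[2, 3] = vals[3, 2] = 7.0
        dm = DistanceMatrix(["A", "B", "C", "D"], vals)
        tree = neighbor_joining(dm)
        pm = patristic_matrix(tree)
        assert pm.labels == ["A", "B", "C", "D"]
        assert np.allclose(pm.values, vals, atol=1e-12)
        assert dendropy_rf(tree.newick(), "((A:1,B:2):1,(C:3,D:4):0);") == 0

    def test_star_matrix_zero_internal_branches(self):
        vals = np.full((4, 4), 2.0)
        np.fill_diagonal(vals, 0.0)
        tree = neighbor_joining(DistanceMatrix(list("ABCD"), vals))
        internal = _internal_branch_lengths(tree)
        assert all(b == pytest.approx(0.0, abs=1e-12) for b in internal)

    def test_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix(["A", "B"], np.zeros((2, 2))))

    def test_random_tree_recovery(self):
        """NJ recovers random binary trees from their additive matrices
        (patristic equality and zero Robinson-Foulds distance)."""
        rng = np.random.default_rng(2)
        for _ in range(30):
            n = int(rng.integers(4, 13))
            truth = random_binary_tree(n, rng)
            dm = patristic_matrix(truth)
            recovered = neighbor_joining(dm)
            pm = patristic_matrix(recovered)
            assert np.allclose(pm.values, dm.values, atol=1e-9)
            assert dendropy_rf(truth.newick(), recovered.newick()) == 0

    def test_deterministic_under_ties(self):
        vals = np.full((5, 5), 4.0)
        np.fill_diagonal(vals, 0.0)
        dm = DistanceMatrix(list("ABCDE"), vals)
        assert neighbor_joining(dm).newick() == neighbor_joining(dm).newick()


def _internal_branch_lengths(tree: TreeNode):
    out = []

    def walk(node):
        for child, length in node.children:
            if not child.is_leaf:
                out.append(length)
            walk(child)

    walk(tree)
    return out


class TestTreeQueries:
    def test_newick_round_trip_through_dendropy(self):
        rng = np.random.default_rng(3)
        tree = random_binary_tree(9, rng)
        dt = dendropy.Tree.get(data=tree.newick(), schema="newick")
        pdm = dt.phylogenetic_distance_matrix()
        mine = patristic_distances(tree)
        for t1 in dt.taxon_namespace:
            for t2 in dt.taxon_namespace:
                if t1.label < t2.label:
                    assert pdm.distance(t1, t2) == pytest.approx(
                        mine[(t1.label, t2.label)], abs=1e-9
                    )

    def test_three_leaf_nearest_neighbors(self):
        tree = TreeNode(
            children=[
                (TreeNode(name="a"), 1.0),
                (TreeNode(name="b"), 1.0),
                (TreeNode(name="c"), 5.0),
            ]
        )
        assert nearest_neighbor(tree, "a") == "b"
        assert nearest_neighbor(tree, "b") == "a"

    def test_unknown_taxon_rejected(self):
        tree = random_binary_tree(5, np.random.default_rng(4))
        with pytest.raises(ValueError):
            nearest_neighbor(tree, "nope")

    def test_nearest_neighbor_matches_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            tree = random_binary_tree(10, rng)
            dist = patristic_distances(tree)
            for taxon in tree.leaves():
                brute = min(
                    (l for l in tree.leaves() if l != taxon),
                    key=lambda l: (dist[(taxon, l)], l),
                )
                assert nearest_neighbor(tree, taxon) == brute


class TestEndToEnd:
    def test_diverged_family_groups_by_similarity(self):
        """Sequences mutated from two ancestors cluster by ancestor, and
        nearest neighbors stay within families."""
        rng = np.random.default_rng(6)
        anc1 = "".join(rng.choice(list(AA), size=120))
        anc2 = "".join(rng.choice(list(AA), size=120))

        def mutant(base, rate):
            return "".join(
                c if rng.random() > rate else rng.choice(list(AA)) for c in base
            )

        seqs = [
            ProteinRecord("f1_a", mutant(anc1, 0.05)),
            ProteinRecord("f1_b", mutant(anc1, 0.10)),
            ProteinRecord("f1_c", mutant(anc1, 0.30)),
            ProteinRecord("f2_a", mutant(anc2, 0.05)),
            ProteinRecord("f2_b", mutant(anc2, 0.10)),
        ]
        msa, tree = phylo.build_tree(seqs)
        assert msa.length >= 120
        for taxon in ("f1_a", "f1_b"):
            assert nearest_neighbor(tree, taxon).startswith("f1")
        for taxon in ("f2_a", "f2_b"):
            assert nearest_neighbor(tree, taxon).startswith("f2")
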