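"""Tree reading, pruning, and covariance construction."""

import dendropy
import numpy as np
import pytest

from phylodispersal import PhyloTree, lambda_transform, read_trees
from phylodispersal.phylo import TreeValidationError
from phylodispersal.simulate import simulate_yule_tree


class TestReadTrees:
    def test_single_newick_line(self, tmp_path):
        path = tmp_path / "t.nwk"
        path.write_text("((A:1,B:1):1,C:2);\n")
        trees = read_trees(path)
        assert len(trees) == 1
        assert set(trees[0].tip_labels) == {"A", "B", "C"}
        assert trees[0].root_to_tip_distances() == {"A": 2, "B": 2, "C": 2}

    def test_multi_tree_file_preserves_order_and_count(self, tmp_path):
        path = tmp_path / "many.nwk"
        lines = [f"((A:1,B:1):{i},C:{i + 1});" for i in range(1, 101)]
        path.write_text("\n".join(lines) + "\n")
        trees = read_trees(path)
        assert len(trees) == 100
        assert trees[9].root_to_tip_distances()["C"] == 11

    def test_duplicate_tip_labels_rejected(self, tmp_path):
        path = tmp_path / "dup.nwk"
        path.write_text("((A:1,A:1):1,C:2);\n")
        with pytest.raises(TreeValidationError, match="duplicate"):
            read_trees(path)

    def test_malformed_newick_names_line(self, tmp_path):
        path = tmp_path / "bad.nwk"
        path.write_text("((A:1,B:1):1,C:2);\n((A:1,B:1:1,C;\n")
        with pytest.raises(ValueError, match="line 2"):
            read_trees(path)

    def test_nexus_trees_block(self, tmp_path):
        path = tmp_path / "t.nex"
        tl = dendropy.TreeList.get(
            data="((A:1,B:1):1,C:2);\n(A:2,(B:1,C:1):1);\n",
            schema="newick", preserve_underscores=True,
        )
        tl.write(path=str(path), schema="nexus")
        trees = read_trees(path)
        assert len(trees) == 2

    def test_labels_normalized_spaces_to_underscores(self):
        t = PhyloTree.from_newick("(('Parus major':1,B:1):1,C:2);")
        assert "Parus_major" in t.tip_labels


class TestPrune:
    def test_identity_prune_keeps_distances(self, yule_tree_20):
        before = yule_tree_20.root_to_tip_distances()
        after = yule_tree_20.prune(set(yule_tree_20.tip_labels))
        for sp, d in after.root_to_tip_distances().items():
            assert d == pytest.approx(before[sp], abs=1e-10)

    def test_prune_collapses_and_conserves_path_lengths(self, three_tip_tree):
        pruned = three_tip_tree.prune({"A", "C"})
        assert set(pruned.tip_labels) == {"A", "C"}
        d = pruned.root_to_tip_distances()
        assert d["A"] == pytest.approx(2.0)
        assert d["C"] == pytest.approx(2.0)

    def test_random_subset_preserves_retained_tip_depths(self, rng):
        tree = simulate_yule_tree(30, 1.0, seed=5)
        before = tree.root_to_tip_distances()
        keep = list(rng.choice(tree.tip_labels, size=12, replace=False))
        after = tree.prune(keep).root_to_tip_distances()
        for sp in keep:
            assert after[sp] == pytest.approx(before[sp], abs=1e-10)

    def test_missing_species_error_names_them(self, three_tip_tree):
        with pytest.raises(KeyError, match="Z"):
            three_tip_tree.prune({"A", "Z"})


class TestVCV:
    def test_three_tip_matrix(self, three_tip_tree):
        V = three_tip_tree.vcv(order=["A", "B", "C"])
        np.testing.assert_allclose(
            V.matrix, [[2, 1, 0], [1, 2, 0], [0, 0, 2]]
        )

    def test_star_tree_is_diagonal(self, star_tree):
        V = star_tree.vcv()
        np.testing.assert_allclose(V.matrix, np.eye(8))

    def test_matches_pairwise_mrca_oracle(self, yule_tree_20):
        """Brute-force oracle: V_ij = (d_i + d_j - patristic_ij) / 2."""
        order = list(yule_tree_20.tip_labels)
        V = yule_tree_20.vcv(order=order).matrix
        depths = yule_tree_20.root_to_tip_distances()
        pdm = yule_tree_20.dendropy_tree.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in yule_tree_20.dendropy_tree.taxon_namespace}
        for i, a in enumerate(order):
            for j, b in enumerate(order):
                if i == j:
                    expected = depths[a]
                else:
                    patristic = pdm.patristic_distance(taxa[a], taxa[b])
                    expected = (depths[a] + depths[b] - patristic) / 2
                assert V[i, j] == pytest.approx(expected, abs=1e-9)

    def test_symmetric_psd(self, yule_tree_20):
        V = yule_tree_20.vcv().matrix
        np.testing.assert_allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() > -1e-9

    def test_non_ultrametric_warns(self):
        t = PhyloTree.from_newick("((A:1,B:3):1,C:2);")
        with pytest.warns(UserWarning, match="ultrametric"):
            t.vcv()

    def test_zero_length_internal_branch_collapsed(self):
        t = PhyloTree.from_newick("(((A:1,B:1):0,C:1):1,D:2);")
        V = t.vcv(order=["A", "B", "C", "D"])
        # A, B and C all coalesce at depth 1 after the collapse
        assert V.matrix[0, 2] == pytest.approx(1.0)
        assert np.linalg.matrix_rank(V.matrix) == 4


class TestLambdaTransform:
    def test_lambda_one_is_identity(self, three_tip_tree):
        V = three_tip_tree.vcv()
        np.testing.assert_array_equal(
            lambda_transform(V, 1.0).matrix, V.matrix
        )

    def test_lambda_zero_is_diagonal(self, three_tip_tree):
        V = three_tip_tree.vcv()
        np.testing.assert_allclose(
            lambda_transform(V, 0.0).matrix, np.diag(np.diag(V.matrix))
        )

    def test_half_lambda_scales_offdiagonal(self, three_tip_tree):
        V = three_tip_tree.vcv(order=["A", "B", "C"])
        np.testing.assert_allclose(
            lambda_transform(V, 0.5).matrix,
            [[2, 0.5, 0], [0.5, 2, 0], [0, 0, 2]],
        )

    def test_linear_in_lambda(self, yule_tree_20, rng):
        V = yule_tree_20.vcv()
        a, b = 0.3, 0.8
        mid = lambda_transform(V, (a + b) / 2).matrix
        avg = (lambda_transform(V, a).matrix + lambda_transform(V, b).matrix) / 2
        np.testing.assert_allclose(mid, avg, atol=1e-12)

    @pytest.mark.parametrize("lam", [-0.1, 1.5])
    def test_out_of_range_rejected(self, three_tip_tree, lam):
        with pytest.raises(ValueError):
            lambda_transform(three_tip_tree.vcv(), lam)
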