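"""Euclidean distances in index space, UPGMA clustering, Newick export.

The UPGMA implementation is cross-checked against scipy's average-linkage
agglomeration (an independent route to the same algorithm) and against a
hand-worked three-leaf case; ultrametricity and label-permutation
invariance are asserted as properties.
"""

import dendropy
import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet, linkage
from scipy.spatial.distance import squareform

from dnawalk.phylo import (
    DistanceMatrix,
    euclidean_distances,
    standardize_features,
    to_newick,
    upgma,
)


class Vec:
    def __init__(self, id, v1, v2, v3):
        self.id, self.v1, self.v2, self.v3 = id, v1, v2, v3


def random_distance_matrix(rng: np.random.Generator, n: int) -> DistanceMatrix:
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    labels = [f"L{i}" for i in range(n)]
    return DistanceMatrix(labels=labels, values=d)


class TestEuclideanDistances:
    def test_identical_points_have_zero_distance(self):
        dm = euclidean_distances([Vec("a", 1, 2, 3), Vec("b", 1, 2, 3)])
        assert dm.values[0, 1] == 0.0

    def test_closed_form_345(self):
        dm = euclidean_distances([Vec("a", 0, 0, 0), Vec("b", 1, 2, 2)])
        assert dm.values[0, 1] == pytest.approx(3.0)

    def test_symmetric_zero_diagonal(self):
        rng = np.random.default_rng(0)
        vecs = [Vec(f"v{i}", *rng.normal(size=3)) for i in range(6)]
        dm = euclidean_distances(vecs)
        assert np.allclose(dm.values, dm.values.T)
        assert np.allclose(np.diag(dm.values), 0)

    def test_duplicate_ids_error(self):
        with pytest.raises(ValueError, match="duplicate"):
            euclidean_distances([Vec("a", 0, 0, 0), Vec("a", 1, 1, 1)])

    def test_non_finite_component_names_the_id(self):
        with pytest.raises(ValueError, match="bad"):
            euclidean_distances([Vec("ok", 0, 0, 0), Vec("bad", np.nan, 1, 1)])

    def test_standardize_gives_unit_variance(self):
        rng = np.random.default_rng(1)
        vecs = [Vec(f"v{i}", *rng.normal(size=3)) for i in range(8)]
        pts = standardize_features(vecs)
        assert np.allclose(pts.mean(axis=0), 0, atol=1e-12)
        assert np.allclose(pts.std(axis=0), 1, atol=1e-12)


class TestUPGMA:
    def test_two_leaves_merge_at_half_distance(self):
        dm = DistanceMatrix(labels=("A", "B"), values=np.array([[0.0, 2.0], [2.0, 0.0]]))
        tree = upgma(dm)
        assert len(tree.merges) == 1
        assert tree.merges[0].height == 1.0
        assert to_newick(tree) == "(A:1,B:1);"

    def test_three_leaf_hand_agglomeration(self):
        d = np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], dtype=float)
        tree = upgma(DistanceMatrix(labels=("A", "B", "C"), values=d))
        assert [m.height for m in tree.merges] == [1.0, 2.0]
        assert to_newick(tree) == "((A:1,B:1):1,C:2);"

    def test_single_leaf_rejected(self):
        with pytest.raises(ValueError):
            upgma(DistanceMatrix(labels=("A",), values=np.zeros((1, 1))))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_scipy_average_linkage(self, seed):
        """Merge heights equal scipy's group-average agglomeration / 2."""
        dm = random_distance_matrix(np.random.default_rng(seed), 6)
        tree = upgma(dm)
        Z = linkage(squareform(dm.values), method="average")
        assert np.allclose(sorted(tree.heights()), sorted(Z[:, 2] / 2.0), atol=1e-12)
        ours = tree.cophenetic_matrix().values
        theirs = squareform(cophenet(Z))
        assert np.allclose(ours, theirs, atol=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_cophenetic_matrix_is_ultrametric(self, seed):
        dm = random_distance_matrix(np.random.default_rng(seed + 100), 7)
        coph = upgma(dm).cophenetic_matrix().values
        n = coph.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert coph[i, j] <= max(coph[i, k], coph[j, k]) + 1e-9

    def test_heights_non_decreasing(self):
        dm = random_distance_matrix(np.random.default_rng(5), 10)
        h = upgma(dm).heights()
        assert (np.diff(h) >= -1e-12).all()

    def test_merge_sizes_sum_to_leaf_count(self):
        dm = random_distance_matrix(np.random.default_rng(6), 8)
        tree = upgma(dm)
        assert tree.merges[-1].size == 8

    def test_label_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(7)
        dm = random_distance_matrix(rng, 6)
        perm = rng.permutation(6)
        dm_p = DistanceMatrix(
            labels=[dm.labels[i] for i in perm], values=dm.values[np.ix_(perm, perm)]
        )
        a = upgma(dm).cophenetic_matrix()
        b = upgma(dm_p).cophenetic_matrix()
        order = [b.labels.index(lab) for lab in a.labels]
        assert np.allclose(a.values, b.values[np.ix_(order, order)], atol=1e-12)


class TestNewick:
    def _parse(self, newick: str) -> dendropy.Tree:
        return dendropy.Tree.get(data=newick, schema="newick")

    def test_round_trip_recovers_cophenetic_distances(self):
        dm = random_distance_matrix(np.random.default_rng(8), 6)
        tree = upgma(dm)
        parsed = self._parse(to_newick(tree, precision=12))
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        coph = tree.cophenetic_matrix()
        for i, a in enumerate(coph.labels):
            for j, b in enumerate(coph.labels):
                if i < j:
                    assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                        coph.values[i, j], abs=1e-9
                    )

    def test_root_to_leaf_paths_are_equal(self):
        dm = random_distance_matrix(np.random.default_rng(9), 5)
        parsed = self._parse(to_newick(upgma(dm), precision=12))
        depths = [leaf.distance_from_root() for leaf in parsed.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9

    def test_labels_with_spaces_are_quoted(self):
        dm = DistanceMatrix(
            labels=("Homo sapiens", "Pan paniscus"),
            values=np.array([[0.0, 1.0], [1.0, 0.0]]),
        )
        newick = to_newick(upgma(dm))
        assert "'Homo sapiens'" in newick
        parsed = self._parse(newick)
        assert {t.label for t in parsed.taxon_namespace} == {"Homo sapiens", "Pan paniscus"}
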