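"""PCoA, neighbor joining, Ward clustering and Newick serialization,
cross-checked against classical-scaling algebra, brute-force tree
fitting, exhaustive agglomeration, and independent libraries."""

import dendropy
import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix as SkbioDM
from skbio.stats.ordination import pcoa as skbio_pcoa
from sklearn.metrics import adjusted_rand_score

from bulkadmix import synthetic
from bulkadmix.diversity import mrd_matrix
from bulkadmix.structure import (
    cluster_labels,
    leaf_names,
    linkage_table,
    neighbor_joining,
    newick,
    pcoa,
    tree_distance_matrix,
    ward_linkage,
    write_newick,
)
from oracles import best_quartet_tree, random_additive_matrix, ward_brute_force


def dm(arr, labels=None):
    arr = np.asarray(arr, dtype=float)
    labels = labels or [f"P{i}" for i in range(arr.shape[0])]
    return pd.DataFrame(arr, index=labels, columns=labels)


def mrd_of_random_panel(seed, n=10, L=80):
    rng = np.random.default_rng(seed)
    freqs = pd.DataFrame(rng.random((n, L)),
                         index=[f"P{i}" for i in range(n)],
                         columns=[f"L{j}" for j in range(L)])
    return mrd_matrix(freqs)


class TestPCoA:
    def test_degenerate_zero_matrix(self):
        res = pcoa(dm(np.zeros((4, 4))))
        assert res.eigenvalues.size == 0
        assert res.coordinates.shape == (4, 0)
        assert np.allclose(res.all_eigenvalues, 0, atol=1e-12)

    def test_collinear_points_single_axis(self):
        # points at 0, 3, 4 on a line
        d = dm([[0, 3, 4], [3, 0, 1], [4, 1, 0]])
        res = pcoa(d)
        assert res.eigenvalues.size == 1
        coords = res.coordinates.to_numpy()
        rebuilt = squareform(pdist(coords))
        assert np.allclose(rebuilt, d.to_numpy(), atol=1e-9)

    def test_equilateral_triangle_splits_variance_evenly(self):
        d = dm(np.ones((3, 3)) - np.eye(3))
        res = pcoa(d)
        assert res.eigenvalues.size == 2
        assert res.eigenvalues[0] == pytest.approx(res.eigenvalues[1], rel=1e-9)
        assert np.allclose(res.pct_variance, [50, 50], atol=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_mrd_is_euclidean_and_distances_reproduced(self, seed):
        d = mrd_of_random_panel(seed)
        res = pcoa(d)
        lam_max = np.abs(res.all_eigenvalues).max()
        assert res.all_eigenvalues.min() >= -1e-9 * lam_max
        rebuilt = squareform(pdist(res.coordinates.to_numpy()))
        assert np.allclose(rebuilt, d.to_numpy(), atol=1e-9)
        # column norms carry the eigenvalues
        norms_sq = (res.coordinates.to_numpy() ** 2).sum(axis=0)
        assert np.allclose(norms_sq, res.eigenvalues, rtol=1e-9)

    def test_matches_independent_implementation(self):
        d = mrd_of_random_panel(3)
        res = pcoa(d)
        ref = skbio_pcoa(SkbioDM(d.to_numpy(), ids=list(d.index)), number_of_dimensions=5)
        assert np.allclose(res.eigenvalues[:5], ref.eigvals.to_numpy()[:5], atol=1e-9)
        assert np.allclose(np.abs(res.coordinates.to_numpy()[:, :5]),
                           np.abs(ref.samples.to_numpy()[:, :5]), atol=1e-6)

    def test_asymmetric_input_rejected(self):
        bad = dm([[0, 1, 2], [1, 0, 3], [2, 2.5, 0]])
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(bad)

    def test_sign_convention_reproducible(self):
        d = mrd_of_random_panel(4)
        a, b = pcoa(d), pcoa(d)
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)
        for col in a.coordinates:
            scores = a.coordinates[col].to_numpy()
            assert scores[np.argmax(np.abs(scores))] > 0


class TestNeighborJoining:
    def test_two_leaf_closed_form(self):
        t = neighbor_joining(dm([[0, 0.4], [0.4, 0]], ["A", "B"]))
        assert newick(t) == "(A:0.2,B:0.2);"

    def test_quartet_recovery_matches_brute_force(self, rng):
        d_arr, labels = random_additive_matrix(4, rng)
        (pair1, pair2), lengths = best_quartet_tree(d_arr)
        t = neighbor_joining(dm(d_arr, labels))
        td = tree_distance_matrix(t, labels)
        assert np.allclose(td.to_numpy(), d_arr, atol=1e-9)
        # the NJ split must be the least-squares optimal split
        nwk = newick(t)
        sibs = {frozenset([labels[a] for a in pair1]), frozenset([labels[a] for a in pair2])}

        def splits(node):
            found = set()
            for c in node.children:
                ln = leaf_names(c)
                if len(ln) == 2:
                    found.add(frozenset(ln))
                found |= splits(c)
            return found

        assert sibs & splits(t), f"NJ tree {nwk} lacks the optimal quartet split {sibs}"

    @pytest.mark.parametrize("n_leaves", [4, 5, 6, 8])
    def test_additive_matrices_reproduced_exactly(self, n_leaves):
        rng = np.random.default_rng(100 + n_leaves)
        d_arr, labels = random_additive_matrix(n_leaves, rng)
        t = neighbor_joining(dm(d_arr, labels))
        td = tree_distance_matrix(t, labels)
        assert np.allclose(td.to_numpy(), d_arr, atol=1e-9)

    def test_leaf_order_invariance(self, rng):
        d_arr, labels = random_additive_matrix(6, rng)
        d = dm(d_arr, labels)
        perm = list(np.random.default_rng(5).permutation(labels))
        t1 = neighbor_joining(d)
        t2 = neighbor_joining(d.loc[perm, perm])
        pd.testing.assert_frame_equal(tree_distance_matrix(t1, sorted(labels)),
                                      tree_distance_matrix(t2, sorted(labels)))

    def test_branch_lengths_never_negative(self):
        # a non-additive matrix that provokes negative NJ estimates
        d = mrd_of_random_panel(9, n=7, L=5)

        def walk(node):
            assert node.length >= 0
            for c in node.children:
                walk(c)

        walk(neighbor_joining(d))

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            neighbor_joining(dm([[0.0]], ["A"]))


class TestNewick:
    def test_round_trip_preserves_path_lengths(self, rng, tmp_path):
        d_arr, labels = random_additive_matrix(6, rng)
        t = neighbor_joining(dm(d_arr, labels))
        path = tmp_path / "tree.nwk"
        write_newick(t, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        pdm = parsed.phylogenetic_distance_matrix()
        taxa = {x.label: x for x in parsed.taxon_namespace}
        mine = tree_distance_matrix(t, labels)
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                assert pdm.distance(taxa[a], taxa[b]) == pytest.approx(
                    mine.loc[a, b], abs=1e-12
                )

    def test_labels_with_metacharacters_are_quoted(self):
        t = neighbor_joining(dm([[0, 0.4], [0.4, 0]], ["pop one", "B:2"]))
        s = newick(t)
        assert "'pop one'" in s and "'B:2'" in s
        parsed = dendropy.Tree.get(data=s, schema="newick")
        assert sorted(x.label for x in parsed.taxon_namespace) == ["B:2", "pop one"]

    def test_duplicate_leaf_labels_rejected(self):
        t = neighbor_joining(dm([[0, 0.4], [0.4, 0]], ["A", "B"]))
        for node in t.children:
            node.name = "A"
        with pytest.raises(ValueError, match="duplicate"):
            newick(t)


class TestWard:
    def test_two_tight_clusters_merge_last(self):
        d_arr = np.full((6, 6), 0.9)
        d_arr[:3, :3] = 0.01
        d_arr[3:, 3:] = 0.01
        np.fill_diagonal(d_arr, 0)
        z = ward_linkage(dm(d_arr))
        # the final merge joins the two size-3 clusters
        assert z[-1, 3] == 6
        child_sizes = [z[int(c) - 6, 3] for c in z[-1, :2]]
        assert child_sizes == [3, 3]

    def test_first_merge_is_closest_pair(self):
        d = dm([[0, 0.1, 0.8], [0.1, 0, 0.7], [0.8, 0.7, 0]])
        z = ward_linkage(d)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 1}

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_agglomeration(self, seed):
        n = 5 if seed % 2 else 6
        d = mrd_of_random_panel(seed, n=n, L=40)
        z = ward_linkage(d)
        merges = ward_brute_force(d.to_numpy())
        assert len(merges) == z.shape[0]
        # compare partition sequence and heights step by step
        id_to_set = {i: frozenset([i]) for i in range(n)}
        for step, (a, b, height) in enumerate(merges):
            za, zb = int(z[step, 0]), int(z[step, 1])
            sa, sb = id_to_set[za], id_to_set[zb]
            assert {sa, sb} == {a, b}
            assert z[step, 2] == pytest.approx(height, abs=1e-9)
            id_to_set[n + step] = sa | sb

    def test_heights_non_decreasing(self):
        z = ward_linkage(mrd_of_random_panel(7, n=12))
        assert (np.diff(z[:, 2]) >= -1e-12).all()

    def test_linkage_table_schema(self):
        d = mrd_of_random_panel(2, n=4)
        table = linkage_table(ward_linkage(d), labels=list(d.index))
        assert list(table.columns) == ["child1", "child2", "height", "size"]
        assert table["size"].iloc[-1] == 4

    def test_single_population_rejected(self):
        with pytest.raises(ValueError):
            ward_linkage(dm([[0.0]], ["A"]))

    def test_recovers_synthetic_groups(self):
        """Ward at k=3 on strongly drifted three-group panels matches the
        true group labels almost perfectly."""
        scores = []
        for seed in range(10):
            _, freqs, labels = synthetic.simulate_reference_panel(
                K=3, L=200, n_populations_per_group=5, drift=30, seed=seed
            )
            z = ward_linkage(mrd_matrix(freqs))
            found = cluster_labels(z, 3)
            scores.append(adjusted_rand_score(labels.to_numpy(), found))
        assert np.mean(scores) > 0.9
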