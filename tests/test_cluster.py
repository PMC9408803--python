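"""Phylogroup clustering: agglomeration, cutting, Newick, bootstrap."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from allerisc.arisc import arisc_matrix
from allerisc.cluster import (
    ClusterTree,
    DistanceMatrix,
    bootstrap_support,
    build_tree,
    cut_clusters,
    from_newick,
    to_newick,
)
from allerisc.simulate import FamilySpec, generate_study


def _dm(ids, condensed):
    n = len(ids)
    v = np.zeros((n, n))
    it = iter(condensed)
    for i in range(n):
        for j in range(i + 1, n):
            v[i, j] = v[j, i] = next(it)
    return DistanceMatrix(ids=ids, values=v)


def _planted_study(seed, n_families=4, sizes=(5, 5, 5, 5), length=150):
    specs = [
        FamilySpec(n_members=sz, length=length, target_identity=0.9, label=f"F{i + 1}")
        for i, sz in enumerate(sizes[:n_families])
    ]
    return generate_study(specs=specs, seed=seed)


def _family_distance(records, truth):
    m = arisc_matrix(records)
    return DistanceMatrix.from_arisc(m), truth.labels_for(m.ids)


class TestBuildTree:
    def test_closest_pair_merges_first(self):
        d = _dm(["a", "b", "c"], [0.1, 0.9, 0.9])
        tree = build_tree(d)
        first = min(tree.internal_nodes(), key=lambda n: n.merge_order)
        assert sorted(first.leaf_names()) == ["a", "b"]

    def test_leaf_set_equals_input_ids(self):
        rng = np.random.default_rng(0)
        ids = [f"s{i}" for i in range(8)]
        v = rng.random((8, 8))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        tree = build_tree(DistanceMatrix(ids=ids, values=v))
        assert sorted(tree.leaf_ids) == sorted(ids)

    def test_heights_non_decreasing_towards_root(self):
        rng = np.random.default_rng(1)
        v = rng.random((10, 10))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        tree = build_tree(DistanceMatrix(ids=[f"s{i}" for i in range(10)], values=v))
        for node in tree.internal_nodes():
            assert all(node.height >= c.height for c in node.children)

    def test_rejects_bad_matrices(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(ids=["a", "b"], values=np.array([[0, 0.1], [0.3, 0]]))
        with pytest.raises(ValueError, match="negative"):
            DistanceMatrix(ids=["a", "b"], values=np.array([[0, -0.1], [-0.1, 0]]))
        with pytest.raises(ValueError, match="at least 3"):
            build_tree(_dm(["a", "b"], [0.5]))

    def test_matches_scipy_average_linkage_partition(self):
        """On a tie-free random matrix our UPGMA cut agrees with scipy's."""
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(5)
        v = rng.random((9, 9))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0)
        ids = [f"s{i}" for i in range(9)]
        ours = cut_clusters(build_tree(DistanceMatrix(ids=ids, values=v)), 3)
        theirs = fcluster(linkage(squareform(v), method="average"), 3, criterion="maxclust")
        assert adjusted_rand_score([ours[i] for i in ids], theirs) == pytest.approx(1.0)

    @pytest.mark.parametrize("linkage", ["upgma", "complete", "nj"])
    def test_all_linkages_recover_planted_families(self, linkage):
        records, truth = _planted_study(seed=2)
        d, labels = _family_distance(records, truth)
        assignment = cut_clusters(build_tree(d, linkage), 4)
        got = [assignment[i] for i in d.ids]
        assert adjusted_rand_score(labels, got) == pytest.approx(1.0)


class TestCutClusters:
    def test_extreme_cuts(self):
        d = _dm(["a", "b", "c", "d"], [0.1, 0.8, 0.9, 0.7, 0.85, 0.2])
        tree = build_tree(d)
        assert set(cut_clusters(tree, 1).values()) == {1}
        singles = cut_clusters(tree, 4)
        assert sorted(singles.values()) == [1, 2, 3, 4]
        with pytest.raises(ValueError):
            cut_clusters(tree, 0)
        with pytest.raises(ValueError):
            cut_clusters(tree, 5)

    def test_partition_invariant_to_input_order(self):
        records, truth = _planted_study(seed=9, sizes=(4, 4, 4, 4))
        d1, _ = _family_distance(records, truth)
        rng = np.random.default_rng(1)
        perm = list(rng.permutation(len(records)))
        records2 = [records[i] for i in perm]
        d2, _ = _family_distance(records2, truth)
        a1 = cut_clusters(build_tree(d1), 4)
        a2 = cut_clusters(build_tree(d2), 4)
        ids = d1.ids
        assert adjusted_rand_score(
            [a1[i] for i in ids], [a2[i] for i in ids]
        ) == pytest.approx(1.0)


class TestNewick:
    def test_write_read_write_is_byte_stable(self):
        records, truth = _planted_study(seed=4, sizes=(4, 5, 6, 7))
        d, _ = _family_distance(records, truth)
        tree = build_tree(d)
        n1 = to_newick(tree)
        n2 = to_newick(from_newick(n1))
        assert n1 == n2

    def test_round_trip_preserves_topology_and_supports(self):
        d = _dm(["a", "b", "c", "d"], [0.1, 0.8, 0.9, 0.7, 0.85, 0.2])
        tree = build_tree(d)
        for node in tree.internal_nodes():
            node.support = 0.5
        back = from_newick(to_newick(tree))
        assert sorted(back.leaf_ids) == ["a", "b", "c", "d"]
        assert {frozenset(c) for c in back.clades()} == {
            frozenset(c) for c in tree.clades()
        }
        assert all(n.support == 0.5 for n in back.internal_nodes())

    def test_dendropy_can_parse_our_newick(self):
        import dendropy

        d = _dm(["a", "b", "c", "d"], [0.1, 0.8, 0.9, 0.7, 0.85, 0.2])
        nwk = to_newick(build_tree(d))
        t = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(l.taxon.label for l in t.leaf_node_iter()) == ["a", "b", "c", "d"]


class TestBootstrap:
    def test_single_replicate_gives_binary_supports(self):
        records, _ = _planted_study(seed=6, n_families=2, sizes=(3, 3), length=100)
        tree = bootstrap_support(records, n_reps=1, seed=0)
        assert all(n.support in (0.0, 1.0) for n in tree.internal_nodes())

    def test_fixed_seed_reproduces_supports(self):
        records, _ = _planted_study(seed=6, n_families=2, sizes=(3, 4), length=100)
        t1 = bootstrap_support(records, n_reps=25, seed=123)
        t2 = bootstrap_support(records, n_reps=25, seed=123)
        assert to_newick(t1) == to_newick(t2)

    def test_well_separated_families_have_strong_support(self):
        records, truth = _planted_study(seed=3, n_families=3, sizes=(4, 4, 4), length=150)
        tree = bootstrap_support(records, n_reps=100, seed=7)
        supports = {frozenset(n.leaf_names()): n.support for n in tree.internal_nodes()}
        for fam in ("F1", "F2", "F3"):
            clade = frozenset(r.id for r in records if truth.family_of[r.id] == fam)
            assert supports[clade] >= 0.9
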