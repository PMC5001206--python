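import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import brute_pearson
from portrait.errors import ValidationError
from portrait.io import LabeledMatrix
from portrait.protein import (
    cut_clusters,
    hierarchical_cluster,
    protein_similarity,
    to_newick,
)


def matrix(values, features, samples):
    return LabeledMatrix(pd.DataFrame(values, index=features, columns=samples))


class TestProteinSimilarity:
    def test_identical_columns(self):
        prots = [f"p{i}" for i in range(5)]
        v = np.arange(5.0).reshape(-1, 1)
        t = protein_similarity(matrix(v, prots, ["C1"]), matrix(v, prots, ["T1"]))
        assert t.df.at["C1", "T1"] == pytest.approx(1.0)

    def test_hand_case_matches_brute_force(self):
        prots = [f"p{i}" for i in range(5)]
        a = [1.0, 4.0, 2.0, 6.0, 3.0]
        b = [2.0, 3.0, 1.0, 7.0, 5.0]
        t = protein_similarity(
            matrix(np.array(a).reshape(-1, 1), prots, ["C1"]),
            matrix(np.array(b).reshape(-1, 1), prots, ["T1"]),
        )
        assert t.df.at["C1", "T1"] == pytest.approx(brute_pearson(a, b))

    def test_disjoint_subtypes_leave_all_missing(self, rng):
        prots = [f"p{i}" for i in range(5)]
        t = protein_similarity(
            matrix(rng.normal(size=(5, 2)), prots, ["C1", "C2"]),
            matrix(rng.normal(size=(5, 2)), prots, ["T1", "T2"]),
            subtype_map={"C1": "LuminalA", "C2": "LuminalA",
                         "T1": "BasalLike", "T2": "BasalLike"},
        )
        assert t.df.isna().all().all()

    def test_subtype_map_keeps_matching_pairs_only(self, rng):
        prots = [f"p{i}" for i in range(5)]
        t = protein_similarity(
            matrix(rng.normal(size=(5, 1)), prots, ["C1"]),
            matrix(rng.normal(size=(5, 2)), prots, ["T1", "T2"]),
            subtype_map={"C1": "LuminalA", "T1": "LuminalA", "T2": "BasalLike"},
        )
        assert np.isfinite(t.df.at["C1", "T1"])
        assert np.isnan(t.df.at["C1", "T2"])


def brute_average_linkage(dist: dict, items: list[str]):
    """Naive agglomeration oracle returning the merge order (member sets)."""
    clusters = {frozenset([i]) for i in items}
    cluster_dist = {}

    def d(a, b):
        return float(np.mean([dist[tuple(sorted((x, y)))] for x in a for y in b]))

    merges = []
    while len(clusters) > 1:
        pair = min(
            itertools.combinations(sorted(clusters, key=sorted), 2),
            key=lambda p: d(*p),
        )
        merges.append((set(pair[0] | pair[1]), d(*pair)))
        clusters -= set(pair)
        clusters.add(pair[0] | pair[1])
    return merges


class TestHierarchicalClustering:
    def planted(self, rng, centers, n_per, noise=0.05):
        cols, labels = {}, {}
        for k, c in enumerate(centers):
            for j in range(n_per):
                name = f"S{k}_{j}"
                cols[name] = np.asarray(c, dtype=float) + rng.normal(0, noise, len(c))
                labels[name] = k
        df = pd.DataFrame(cols, index=[f"f{i}" for i in range(len(centers[0]))])
        return LabeledMatrix(df), labels

    def test_identical_samples_merge_first_at_zero_height(self):
        m = matrix(np.array([[1.0, 1.0, 5.0], [2.0, 2.0, 1.0], [3.0, 3.0, 9.0]]),
                   ["f0", "f1", "f2"], ["A", "B", "C"])
        tree = hierarchical_cluster(m, distance="euclidean")
        first = tree.linkage[0]
        assert {tree.leaves[int(first[0])], tree.leaves[int(first[1])]} == {"A", "B"}
        assert first[2] == pytest.approx(0.0)

    def test_average_linkage_merge_order_matches_brute_force(self, rng):
        samples = list("ABCD")
        m = matrix(rng.normal(size=(6, 4)), [f"f{i}" for i in range(6)], samples)
        tree = hierarchical_cluster(m, linkage="average", distance="euclidean")
        from scipy.spatial.distance import pdist, squareform

        dm = squareform(pdist(m.data.to_numpy().T))
        dist = {
            tuple(sorted((samples[i], samples[j]))): dm[i, j]
            for i in range(4) for j in range(i + 1, 4)
        }
        expected = brute_average_linkage(dist, samples)
        # rebuild member sets from the scipy linkage
        members = {i: {s} for i, s in enumerate(samples)}
        got = []
        for k, row in enumerate(tree.linkage):
            merged = members[int(row[0])] | members[int(row[1])]
            members[len(samples) + k] = merged
            got.append((merged, row[2]))
        for (set_a, h_a), (set_b, h_b) in zip(expected, got):
            assert set_a == set_b
            assert h_a == pytest.approx(h_b)

    def test_heights_monotone_for_average_linkage(self, rng):
        m = matrix(rng.normal(size=(8, 10)), [f"f{i}" for i in range(8)],
                   [f"S{i}" for i in range(10)])
        tree = hierarchical_cluster(m, linkage="average", distance="euclidean")
        h = tree.merge_heights()
        assert (np.diff(h) >= -1e-12).all()

    def test_feature_reordering_invariance(self, rng):
        feats = [f"f{i}" for i in range(6)]
        vals = rng.normal(size=(6, 5))
        m1 = matrix(vals, feats, [f"S{i}" for i in range(5)])
        perm = rng.permutation(6)
        m2 = matrix(vals[perm], [feats[i] for i in perm], [f"S{i}" for i in range(5)])
        t1 = hierarchical_cluster(m1)
        t2 = hierarchical_cluster(m2)
        np.testing.assert_allclose(t1.linkage, t2.linkage, atol=1e-12)

    def test_constant_sample_rejected_under_correlation_distance(self):
        m = matrix(np.array([[1.0, 1.0], [2.0, 1.0], [3.0, 1.0]]),
                   ["f0", "f1", "f2"], ["ok", "flat"])
        with pytest.raises(ValidationError, match="flat"):
            hierarchical_cluster(m, distance="one_minus_pearson")

    def test_cut_recovers_planted_groups(self, rng):
        centers = np.eye(4) * 10
        m, labels = self.planted(rng, centers, n_per=5)
        tree = hierarchical_cluster(m, distance="euclidean")
        partition = pd.Series(cut_clusters(tree, 4))
        truth = pd.Series(labels)
        # partitions agree up to relabeling
        table = pd.crosstab(partition, truth)
        assert (table.gt(0).sum(axis=1) == 1).all()
        assert partition.nunique() == 4

    def test_cut_extremes(self, rng):
        m = matrix(rng.normal(size=(4, 6)), [f"f{i}" for i in range(4)],
                   [f"S{i}" for i in range(6)])
        tree = hierarchical_cluster(m, distance="euclidean")
        assert set(cut_clusters(tree, 1).values()) == {1}
        assert len(set(cut_clusters(tree, 6).values())) == 6
        with pytest.raises(ValueError):
            cut_clusters(tree, 7)

    def test_newick_export_contains_all_leaves(self, rng):
        m = matrix(rng.normal(size=(4, 5)), [f"f{i}" for i in range(4)],
                   ["alpha", "beta", "gamma", "delta", "eps"])
        tree = hierarchical_cluster(m, distance="euclidean")
        nwk = to_newick(tree)
        assert nwk.endswith(";")
        for leaf in m.sample_ids:
            assert leaf in nwk
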