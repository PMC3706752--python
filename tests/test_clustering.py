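"""Hierarchical clustering, purity, silhouette and consensus clustering."""

import io

import numpy as np
import pandas as pd
import pytest

from isosig.clustering import (
    ConsensusMatrix,
    DistanceMatrix,
    cluster_purity,
    consensus_cdf,
    consensus_cluster,
    cut_to_k,
    euclidean_distances,
    hierarchical_cluster,
    silhouette,
)
from isosig.errors import DataError, ValidationError
from isosig.matrix import ExpressionMatrix

from conftest import log2_matrix


def one_d_matrix(points, ids=None):
    ids = ids or [f"s{i}" for i in range(len(points))]
    return log2_matrix(np.array([points], dtype=float), features=["f0"], samples=ids)


class TestDistances:
    def test_three_four_five(self):
        m = log2_matrix([[0.0, 3.0], [0.0, 4.0]], samples=["a", "b"])
        d = euclidean_distances(m)
        assert d.values[0, 1] == pytest.approx(5.0)
        assert d.values[1, 0] == pytest.approx(5.0)
        assert d.values[0, 0] == 0.0

    def test_identical_samples_distance_zero(self):
        m = log2_matrix([[1.0, 1.0], [2.0, 2.0]], samples=["a", "b"])
        assert euclidean_distances(m).values[0, 1] == 0.0

    def test_nan_rejected(self):
        df = pd.DataFrame({"a": [1.0], "b": [np.nan]}, index=["f0"])
        m = ExpressionMatrix.__new__(ExpressionMatrix)
        m.data, m.level, m.scale = df, "isoform", "log2"
        with pytest.raises(DataError):
            euclidean_distances(m)


class TestHierarchy:
    @pytest.mark.parametrize("linkage", ["complete", "average", "ward"])
    def test_close_pair_merges_first(self, linkage):
        dend = hierarchical_cluster(
            euclidean_distances(one_d_matrix([0.0, 1.0, 10.0])), linkage
        )
        first = dend.linkage_matrix[0]
        assert {int(first[0]), int(first[1])} == {0, 1}

    def test_duplicates_merge_at_height_zero(self):
        dend = hierarchical_cluster(euclidean_distances(one_d_matrix([2.0, 2.0, 9.0])))
        assert dend.linkage_matrix[0, 2] == 0.0

    def test_leaves_conserved_in_newick(self):
        dend = hierarchical_cluster(
            euclidean_distances(one_d_matrix([0.0, 1.0, 10.0, 11.0]))
        )
        newick = dend.to_newick()
        from Bio import Phylo  # independent parser as structural check

        tree = Phylo.read(io.StringIO(newick), "newick")
        assert sorted(t.name for t in tree.get_terminals()) == ["s0", "s1", "s2", "s3"]

    def test_cut_extremes_and_pair(self):
        m = one_d_matrix([0.0, 1.0, 10.0])
        dend = hierarchical_cluster(euclidean_distances(m))
        singletons = cut_to_k(dend, 3)
        assert singletons.nunique() == 3
        assert cut_to_k(dend, 1).nunique() == 1
        two = cut_to_k(dend, 2)
        assert two["s0"] == two["s1"] != two["s2"]

    def test_cut_bad_k_rejected(self):
        dend = hierarchical_cluster(euclidean_distances(one_d_matrix([0.0, 1.0])))
        with pytest.raises(ValidationError):
            cut_to_k(dend, 0)


class TestPurity:
    @pytest.mark.parametrize("misplaced,expected", [(4, 0.975), (12, 0.925)])
    def test_two_cluster_arithmetic(self, misplaced, expected):
        # 160 samples in 2 clusters; `misplaced` sit in the cluster whose
        # majority belongs to the other class
        labels = pd.Series(["T"] * 73 + ["N"] * 87, index=[f"c{i}" for i in range(160)])
        assign = pd.Series(1, index=labels.index)
        assign[labels == "N"] = 2
        flip = list(labels.index[:misplaced // 2]) + list(labels.index[-misplaced // 2:])
        assign[flip] = 3 - assign[flip]
        assert cluster_purity(assign, labels) == pytest.approx(expected)

    def test_hand_majority_count(self):
        labels = pd.Series(list("TTNNN"), index=list("abcde"))
        assign = pd.Series([1, 1, 1, 2, 2], index=list("abcde"))
        assert cluster_purity(assign, labels) == pytest.approx(0.8)

    def test_pure_clusters_give_one(self):
        labels = pd.Series(list("TTNN"), index=list("abcd"))
        assign = pd.Series([1, 1, 2, 2], index=list("abcd"))
        assert cluster_purity(assign, labels) == 1.0

    def test_two_class_purity_at_least_half(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(4, 30))
            labels = pd.Series(rng.choice(["x", "y"], n), index=range(n))
            assign = pd.Series(rng.choice([1, 2], n), index=range(n))
            assert cluster_purity(assign, labels) >= 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            cluster_purity(pd.Series(dtype=int), pd.Series(dtype=str))


def brute_silhouette(D, labels):
    """O(n^2) literal-definition silhouette reference."""
    n = len(labels)
    out = np.zeros(n)
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = sum(D[i, j] for j in own) / len(own)
        b = min(
            np.mean([D[i, j] for j in range(n) if labels[j] == c])
            for c in set(labels)
            if c != labels[i]
        )
        out[i] = (b - a) / max(a, b)
    return out


class TestSilhouette:
    def test_separated_duplicate_clusters_width_one(self):
        m = one_d_matrix([0.0, 0.0, 9.0, 9.0])
        d = euclidean_distances(m)
        assign = pd.Series([1, 1, 2, 2], index=d.sample_ids)
        res = silhouette(d, assign)
        np.testing.assert_allclose(res.widths, 1.0)

    def test_hand_formula(self):
        m = one_d_matrix([0.0, 1.0, 5.0, 6.0])
        d = euclidean_distances(m)
        assign = pd.Series([1, 1, 2, 2], index=d.sample_ids)
        res = silhouette(d, assign)
        assert res.widths["s0"] == pytest.approx(1 - 1 / 5.5)
        assert res.overall_mean == pytest.approx(res.widths.mean())

    def test_matches_brute_force_reference(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            n = int(rng.integers(5, 31))
            X = rng.normal(size=(n, 3))
            labels = rng.integers(0, 3, size=n)
            if len(set(labels)) < 2:
                continue
            from scipy.spatial.distance import pdist, squareform

            D = squareform(pdist(X))
            d = DistanceMatrix([f"s{i}" for i in range(n)], D)
            assign = pd.Series(labels, index=d.sample_ids)
            res = silhouette(d, assign)
            np.testing.assert_allclose(res.widths.to_numpy(), brute_silhouette(D, labels), atol=1e-12)

    def test_single_cluster_rejected(self):
        d = euclidean_distances(one_d_matrix([0.0, 1.0]))
        with pytest.raises(ValidationError):
            silhouette(d, pd.Series([1, 1], index=d.sample_ids))


def blobs_matrix(seed=0, n_per=6, shift=50.0):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal(0, 1, size=(n_per, 8)), rng.normal(shift, 1, size=(n_per, 8))]
    )
    return log2_matrix(X.T)


class TestConsensus:
    def test_no_resampling_variation_matches_full_membership(self):
        m = blobs_matrix(seed=1)
        cons = consensus_cluster(m, k=2, n_resamples=5, sample_frac=1.0, seed=0)
        idx = cons.index
        full = cut_to_k(hierarchical_cluster(euclidean_distances(m)), 2)
        same = np.equal.outer(full.to_numpy(), full.to_numpy())
        off = ~np.eye(len(full), dtype=bool)
        assert set(np.unique(idx[off])) <= {0.0, 1.0}
        np.testing.assert_array_equal(idx[off] == 1.0, same[off])

    def test_separated_blobs_give_binary_consensus(self):
        m = blobs_matrix(seed=2)
        cons = consensus_cluster(m, k=2, n_resamples=50, sample_frac=0.8, seed=3)
        idx = cons.index
        n_per = 6
        within = idx[:n_per, :n_per][~np.eye(n_per, dtype=bool)]
        across = idx[:n_per, n_per:]
        assert np.nanmin(within) == 1.0
        assert np.nanmax(across) == 0.0

    def test_coselection_bounded_and_deterministic(self):
        m = blobs_matrix(seed=4)
        c1 = consensus_cluster(m, k=2, n_resamples=25, seed=9)
        c2 = consensus_cluster(m, k=2, n_resamples=25, seed=9)
        assert c1.coselect.max() <= 25
        np.testing.assert_array_equal(c1.cocluster, c2.cocluster)
        np.testing.assert_array_equal(c1.coselect, c2.coselect)

    def test_invalid_parameters_rejected(self):
        m = blobs_matrix(seed=5)
        with pytest.raises(ValidationError):
            consensus_cluster(m, k=2, n_resamples=0)
        with pytest.raises(ValidationError):
            consensus_cluster(m, k=1, n_resamples=5)


class TestConsensusCdf:
    def _from_index(self, idx):
        n = idx.shape[0]
        sel = np.full((n, n), 10.0)
        co = idx * 10.0
        co[np.isnan(idx)] = 0.0
        sel[np.isnan(idx)] = 0.0
        return ConsensusMatrix([f"s{i}" for i in range(n)], co, sel)

    def test_all_ones_single_jump(self):
        idx = np.ones((3, 3))
        cdf = consensus_cdf(self._from_index(idx))
        assert cdf["index_value"].tolist() == [1.0]
        assert cdf["cumulative_fraction"].tolist() == [1.0]

    def test_half_zero_half_one(self):
        idx = np.ones((4, 4))
        idx[0, 1] = idx[1, 0] = 0.0
        idx[0, 2] = idx[2, 0] = 0.0
        idx[0, 3] = idx[3, 0] = 1.0
        idx[1, 2] = idx[2, 1] = 1.0
        idx[1, 3] = idx[3, 1] = np.nan
        idx[2, 3] = idx[3, 2] = np.nan
        cdf = consensus_cdf(self._from_index(idx))
        assert cdf.set_index("index_value")["cumulative_fraction"][0.0] == 0.5
        assert cdf.set_index("index_value")["cumulative_fraction"][1.0] == 1.0

    def test_nondecreasing_and_ends_at_one(self):
        m = blobs_matrix(seed=6)
        cons = consensus_cluster(m, k=2, n_resamples=30, seed=2)
        cdf = consensus_cdf(cons)
        assert (np.diff(cdf["cumulative_fraction"]) >= 0).all()
        assert cdf["cumulative_fraction"].iloc[-1] == 1.0

    def test_no_defined_pairs_rejected(self):
        cons = ConsensusMatrix(["a", "b"], np.zeros((2, 2)), np.zeros((2, 2)))
        with pytest.raises(DataError):
            consensus_cdf(cons)
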