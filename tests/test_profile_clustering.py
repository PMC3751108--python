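import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from acetylscan.coverage import ReadSet
from acetylscan.genome_model import GeneAnnotation
from acetylscan.profile_clustering import (
    contribution_crosstab,
    kmeans_profiles,
    profile_matrix,
)
from oracles import exhaustive_min_inertia, naive_tss_profile


class TestProfileMatrix:
    def test_no_reads_zero_matrix(self, toy_gene):
        mat = profile_matrix(ReadSet([], [], []), [toy_gene], window=500, bin_bp=10)
        assert mat.shape == (1, 100)
        assert (mat.to_numpy() == 0).all()

    def test_row_equals_bruteforce_profile(self):
        g = GeneAnnotation("g", "chr1", "+", 10000, 15000)
        rs = ReadSet(["chr1", "chr1"], [9195, 10100], [9245, 10160])
        mat = profile_matrix(rs, [g], window=2000, bin_bp=10, scale="raw")
        want = naive_tss_profile(
            [("chr1", 9195, 9245), ("chr1", 10100, 10160)],
            [("g", "chr1", "+", 10000, 15000)],
            window=2000,
            bin_bp=10,
        )
        np.testing.assert_allclose(mat.loc["g"].to_numpy(), want, atol=1e-12)

    def test_unit_sum_scaling(self):
        g = GeneAnnotation("g", "chr1", "+", 10000, 15000)
        rs = ReadSet(["chr1"], [9195], [9245])
        mat = profile_matrix(rs, [g], window=2000, bin_bp=10, scale="unit_sum")
        assert mat.loc["g"].sum() == pytest.approx(1.0)


class TestKmeans:
    def test_k1_centroid_is_column_mean(self):
        mat = pd.DataFrame(np.arange(12.0).reshape(4, 3), index=list("abcd"))
        out = kmeans_profiles(mat, k=1, seed=0)
        np.testing.assert_allclose(out.centroids.iloc[0], mat.mean(axis=0))
        assert set(out.labels) == {1}

    def test_separated_1d_points_split_correctly(self):
        mat = pd.DataFrame({"x": [0.0, 0.1, 10.0, 10.1]}, index=list("abcd"))
        out = kmeans_profiles(mat, k=2, seed=0)
        assert out.labels["a"] == out.labels["b"]
        assert out.labels["c"] == out.labels["d"]
        assert out.labels["a"] != out.labels["c"]
        cents = sorted(out.centroids["x"])
        assert cents == pytest.approx([0.05, 10.05])

    def test_identical_rows_zero_inertia(self):
        mat = pd.DataFrame(np.ones((6, 4)), index=[f"g{i}" for i in range(6)])
        out = kmeans_profiles(mat, k=3, seed=0)
        assert out.inertia == pytest.approx(0.0, abs=1e-12)

    def test_k_exceeding_rows_rejected(self):
        mat = pd.DataFrame(np.ones((2, 3)))
        with pytest.raises(ValueError):
            kmeans_profiles(mat, k=5, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        mat = pd.DataFrame(rng.normal(size=(30, 6)), index=[f"g{i}" for i in range(30)])
        a = kmeans_profiles(mat, k=3, seed=42)
        b = kmeans_profiles(mat, k=3, seed=42)
        pd.testing.assert_series_equal(a.labels, b.labels)
        assert a.inertia == b.inertia

    def test_matches_exhaustive_partition_minimum(self):
        rng = np.random.default_rng(21)
        for _ in range(12):
            n = int(rng.integers(3, 9))
            k = int(rng.integers(1, min(3, n) + 1))
            pts = rng.normal(size=(n, 2))
            mat = pd.DataFrame(pts, index=[f"g{i}" for i in range(n)])
            got = kmeans_profiles(mat, k=k, seed=0, restarts=20).inertia
            want = exhaustive_min_inertia(pts, k)
            assert got == pytest.approx(want, abs=1e-9)

    def test_relabeling_orders_clusters_by_peak_offset(self):
        # three archetypes: body-peaked, flat-ish, promoter-peaked
        cols = np.arange(-200, 200, 10)
        def bump(center, width=30):
            return np.exp(-0.5 * ((cols - center) / width) ** 2)
        rows, names = [], []
        for i in range(5):
            rows.append(bump(150) + 1e-3 * i)
            names.append(f"body{i}")
        for i in range(5):
            rows.append(bump(-150) + 1e-3 * i)
            names.append(f"prom{i}")
        mat = pd.DataFrame(rows, index=names, columns=cols)
        out = kmeans_profiles(mat, k=2, seed=0)
        # label 1 = most downstream centroid peak
        assert all(out.labels[f"body{i}"] == 1 for i in range(5))
        assert all(out.labels[f"prom{i}"] == 2 for i in range(5))


class TestContributionCrosstab:
    def test_hand_tabulation(self):
        labels = pd.Series({"A": 1, "B": 1, "C": 2, "D": 2})
        cents = pd.DataFrame(np.zeros((2, 3)), index=[1, 2])
        from acetylscan.profile_clustering import ClusterAssignment

        assign = ClusterAssignment(labels=labels, centroids=cents, inertia=0.0)
        strata = pd.Series({"A": "low", "B": "high", "C": "low", "D": "high"})
        tab = contribution_crosstab(assign, strata)
        assert tab.loc["low"].tolist() == [0.5, 0.5]
        assert tab.loc["high"].tolist() == [0.5, 0.5]

    def test_single_cluster_rows_are_one_hot(self):
        labels = pd.Series({"A": 1, "B": 1, "C": 1})
        cents = pd.DataFrame(np.zeros((2, 3)), index=[1, 2])
        from acetylscan.profile_clustering import ClusterAssignment

        assign = ClusterAssignment(labels=labels, centroids=cents, inertia=0.0)
        tab = contribution_crosstab(assign, pd.Series({"A": "x", "B": "x", "C": "y"}))
        assert tab.loc["x"].tolist() == [1.0, 0.0]

    def test_rows_sum_to_one_and_order_invariant(self):
        rng = np.random.default_rng(3)
        ids = [f"g{i}" for i in range(40)]
        labels = pd.Series(rng.integers(1, 4, 40), index=ids)
        cents = pd.DataFrame(np.zeros((3, 2)), index=[1, 2, 3])
        from acetylscan.profile_clustering import ClusterAssignment

        assign = ClusterAssignment(labels=labels, centroids=cents, inertia=0.0)
        strata = pd.Series(rng.choice(["a", "b", "c"], 40), index=ids)
        tab = contribution_crosstab(assign, strata)
        np.testing.assert_allclose(tab.sum(axis=1), 1.0, atol=1e-9)
        perm = rng.permutation(ids)
        assign2 = ClusterAssignment(labels=labels.loc[perm], centroids=cents, inertia=0.0)
        tab2 = contribution_crosstab(assign2, strata.loc[perm])
        pd.testing.assert_frame_equal(tab, tab2)


class TestPlantedShapeRecovery:
    def test_three_planted_shape_classes_recovered(self):
        """Genes with promoter-peaked, body-peaked or flat profiles should be
        recovered by k=3 shape clustering at high Rand agreement."""
        rng = np.random.default_rng(7)
        genes, reads_c, reads_s, reads_e, truth = [], [], [], [], []
        pos = 10000
        for i in range(90):
            gid = f"g{i:03d}"
            genes.append(GeneAnnotation(gid, "chr1", "+", pos, pos + 5000))
            kind = i % 3
            truth.append(kind)
            n = 120
            if kind == 0:  # promoter-peaked
                centers = pos + rng.normal(-800, 200, n)
            elif kind == 1:  # body-peaked
                centers = pos + rng.normal(1000, 200, n)
            else:  # flat: sparse uniform background only
                n = 12
                centers = pos + rng.uniform(-2000, 2000, n)
            for c in centers:
                s = int(c) - 25
                reads_c.append("chr1")
                reads_s.append(max(0, s))
                reads_e.append(max(0, s) + 50)
            pos += 20000
        rs = ReadSet(reads_c, reads_s, reads_e)
        mat = profile_matrix(rs, genes, window=2000, bin_bp=10)
        out = kmeans_profiles(mat, k=3, seed=0)
        score = adjusted_rand_score(truth, [out.labels[g.gene_id] for g in genes])
        assert score >= 0.9
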