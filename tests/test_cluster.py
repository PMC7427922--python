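"""Distances, agglomeration, cuts, density clustering, purity, k selection.

The agglomerative implementation is checked against an exhaustive
reference that recomputes inter-cluster distances from the raw points at
every step (Ward's merge cost from cluster centroids, min/max/mean for
the other linkages), and cross-checked against scipy's linkage.
"""

import numpy as np
import pandas as pd
import pytest

from phenomap import cluster
from phenomap.preprocess import EncodedMatrix
from tests.conftest import make_matrix


# ---------------------------------------------------------------------------
# reference implementations (independent of the package internals)


def reference_agglomerate(points, linkage="ward"):
    """O(n^3) agglomeration recomputing distances from raw points."""
    n = len(points)
    members = {i: [i] for i in range(n)}
    merges = []
    for step in range(n - 1):
        best = None
        for i in sorted(members):
            for j in sorted(members):
                if j <= i:
                    continue
                A = points[members[i]]
                B = points[members[j]]
                if linkage == "ward":
                    ca, cb = A.mean(axis=0), B.mean(axis=0)
                    d = (
                        2.0
                        * len(A)
                        * len(B)
                        / (len(A) + len(B))
                        * np.sum((ca - cb) ** 2)
                    )
                else:
                    pair = np.array(
                        [np.sum((a - b) ** 2) for a in A for b in B]
                    )
                    d = {
                        "single": pair.min(),
                        "complete": pair.max(),
                        "average": pair.mean(),
                    }[linkage]
                if best is None or d < best[2]:
                    best = (i, j, d)
        i, j, d = best
        new = n + step
        members[new] = members.pop(i) + members.pop(j)
        merges.append((i, j, d))
    return merges


def reference_dbscan(X, eps, min_pts):
    """Direct reachability-expansion density clustering (squared distances)."""
    n = len(X)
    D = ((X[:, None, :] - X[None, :, :]) ** 2).sum(-1)
    neighbors = [set(np.where(D[i] <= eps)[0]) for i in range(n)]
    core = [len(nb) >= min_pts for nb in neighbors]
    labels = np.full(n, -1)
    cid = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        queue = [i]
        labels[i] = cid
        while queue:
            q = queue.pop()
            if not core[q]:
                continue
            for nb in neighbors[q]:
                if labels[nb] == -1:
                    labels[nb] = cid
                    queue.append(nb)
        cid += 1
    return labels


# ---------------------------------------------------------------------------


class TestDistance:
    def test_three_four_five(self):
        m = make_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        D = cluster.distance_matrix(m)
        assert D.d[0, 1] == pytest.approx(25.0)
        assert D.d[0, 0] == 0.0

    def test_identical_rows_distance_zero(self):
        m = make_matrix(np.ones((3, 5)))
        assert cluster.distance_matrix(m).d.max() == 0.0

    def test_matches_double_loop(self, rng):
        X = rng.normal(size=(20, 10))
        D = cluster.distance_matrix(make_matrix(X))
        naive = np.zeros((20, 20))
        for i in range(20):
            for j in range(20):
                naive[i, j] = np.sum((X[i] - X[j]) ** 2)
        np.testing.assert_allclose(D.d, naive, atol=1e-9)

    def test_incomplete_matrix_rejected(self):
        m = make_matrix(np.ones((3, 2)))
        m.values[0, 0] = np.nan
        m.mask[0, 0] = False
        with pytest.raises(ValueError, match="complete"):
            cluster.distance_matrix(m)


class TestHierarchical:
    def test_two_tight_pairs_merge_first(self):
        X = np.array([[0.0], [0.1], [10.0], [10.1]])
        dend = cluster.hierarchical_cluster(
            cluster.distance_matrix(make_matrix(X))
        )
        first_two = {
            frozenset(dend.merges[0][:2].astype(int)),
            frozenset(dend.merges[1][:2].astype(int)),
        }
        assert first_two == {frozenset({0, 1}), frozenset({2, 3})}

    @pytest.mark.parametrize("linkage", cluster.LINKAGES)
    def test_merge_sequence_matches_exhaustive_reference(self, linkage, rng):
        for trial in range(5):
            X = rng.normal(size=(8, 3))
            dend = cluster.hierarchical_cluster(
                cluster.distance_matrix(make_matrix(X)), linkage=linkage
            )
            ref = reference_agglomerate(X, linkage)
            for got, (ri, rj, rd) in zip(dend.merges, ref):
                assert {int(got[0]), int(got[1])} == {ri, rj}
                assert got[2] == pytest.approx(rd, rel=1e-8)

    def test_partitions_match_scipy_ward(self, rng):
        from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
        from sklearn.metrics import adjusted_rand_score

        X = rng.normal(size=(40, 6))
        dend = cluster.hierarchical_cluster(cluster.distance_matrix(make_matrix(X)))
        Z = scipy_linkage(X, method="ward")
        for k in (2, 3, 5):
            mine = cluster.cut_tree(dend, k).labels.to_numpy()
            ref = fcluster(Z, k, criterion="maxclust")
            assert adjusted_rand_score(mine, ref) == pytest.approx(1.0)

    def test_monotone_heights_for_ward(self, rng):
        X = rng.normal(size=(25, 4))
        dend = cluster.hierarchical_cluster(cluster.distance_matrix(make_matrix(X)))
        heights = dend.merges[:, 2]
        assert (np.diff(heights) >= -1e-10).all()

    def test_planted_clusters_recovered(self, rng):
        from sklearn.metrics import adjusted_rand_score

        centers = np.array([[0.0] * 4, [10.0] * 4, [-10.0] * 4])
        labels = np.repeat([0, 1, 2], 30)
        X = centers[labels] + rng.normal(size=(90, 4))
        dend = cluster.hierarchical_cluster(cluster.distance_matrix(make_matrix(X)))
        got = cluster.cut_tree(dend, 3).labels.to_numpy()
        assert adjusted_rand_score(labels, got) >= 0.9

    def test_single_patient_rejected(self):
        D = cluster.DistanceMatrix(np.zeros((1, 1)), ["P0"])
        with pytest.raises(ValueError, match="at least 2"):
            cluster.hierarchical_cluster(D)


class TestCutTree:
    def test_extreme_cuts(self, rng):
        X = rng.normal(size=(12, 3))
        dend = cluster.hierarchical_cluster(cluster.distance_matrix(make_matrix(X)))
        assert cluster.cut_tree(dend, 1).labels.nunique() == 1
        assert cluster.cut_tree(dend, 12).labels.nunique() == 12
        with pytest.raises(ValueError):
            cluster.cut_tree(dend, 0)
        with pytest.raises(ValueError):
            cluster.cut_tree(dend, 13)

    def test_nested_refinement(self, rng):
        X = rng.normal(size=(30, 4))
        dend = cluster.hierarchical_cluster(cluster.distance_matrix(make_matrix(X)))
        cuts = {k: cluster.cut_tree(dend, k).labels for k in range(2, 8)}
        for k in range(3, 8):
            fine, coarse = cuts[k], cuts[k - 1]
            # each fine cluster maps into exactly one coarse cluster
            mapping = pd.DataFrame({"f": fine, "c": coarse}).groupby("f")["c"].nunique()
            assert (mapping == 1).all()

    def test_labels_ordered_by_outcome_frequency(self, rng):
        X = np.vstack(
            [rng.normal(0, 1, (20, 2)), rng.normal(8, 1, (20, 2))]
        )
        ids = [f"P{i:03d}" for i in range(40)]
        y = pd.Series([0] * 20 + [1] * 20, index=ids)
        dend = cluster.hierarchical_cluster(cluster.distance_matrix(make_matrix(X)))
        assign = cluster.cut_tree(dend, 2, outcomes=y)
        freqs = [
            y[assign.labels == c].mean() for c in sorted(assign.labels.unique())
        ]
        assert freqs == sorted(freqs, reverse=True)
        assert freqs[0] == 1.0  # cluster A = highest HFpEF frequency


class TestDensity:
    def test_two_blobs(self, rng):
        X = np.vstack([rng.normal(0, 0.3, (25, 2)), rng.normal(10, 0.3, (25, 2))])
        assign = cluster.density_cluster(make_matrix(X), eps=4.0, min_pts=4)
        assert assign.k == 2
        assert (assign.labels >= 0).all()

    def test_tiny_eps_all_noise(self, rng):
        X = rng.uniform(0, 100, size=(30, 2))
        assign = cluster.density_cluster(make_matrix(X), eps=1e-6, min_pts=3)
        assert assign.k == 0
        assert (assign.labels == -1).all()

    def test_matches_reference_expansion(self, rng):
        from sklearn.metrics import adjusted_rand_score

        for trial in range(5):
            X = rng.normal(size=(50, 3)) * (1 + trial)
            mine = cluster.density_cluster(make_matrix(X), eps=2.5, min_pts=4)
            ref = reference_dbscan(X, eps=2.5, min_pts=4)
            a, b = mine.labels.to_numpy(), ref
            # identical noise sets and identical partition of the rest
            assert np.array_equal(a == -1, b == -1)
            if (a >= 0).sum() > 1:
                assert adjusted_rand_score(a[a >= 0], b[b >= 0]) == pytest.approx(1.0)

    def test_bad_params_rejected(self):
        m = make_matrix(np.ones((5, 2)))
        with pytest.raises(ValueError):
            cluster.density_cluster(m, eps=0, min_pts=3)
        with pytest.raises(ValueError):
            cluster.density_cluster(m, eps=1.0, min_pts=0)


def assignment_from_counts(counts):
    labels, outcomes = {}, {}
    pid = 0
    for c, (hf, nohf) in enumerate(counts):
        for _ in range(hf):
            labels[f"P{pid}"] = c
            outcomes[f"P{pid}"] = 1
            pid += 1
        for _ in range(nohf):
            labels[f"P{pid}"] = c
            outcomes[f"P{pid}"] = 0
            pid += 1
    return (
        cluster.ClusterAssignment(pd.Series(labels), k=len(counts)),
        pd.Series(outcomes),
    )


class TestPurity:
    def test_published_three_cluster_value(self):
        assign, y = assignment_from_counts([(5, 2), (35, 24), (40, 55)])
        assert cluster.purity(assign, y) == pytest.approx(95 / 161)
        assert round(100 * cluster.purity(assign, y)) == 59

    def test_uniform_cluster_is_pure(self):
        assign, y = assignment_from_counts([(10, 0)])
        assert cluster.purity(assign, y) == 1.0

    def test_even_split_is_half(self):
        assign, y = assignment_from_counts([(5, 5), (8, 8)])
        assert cluster.purity(assign, y) == 0.5

    def test_matches_brute_force_majority_count(self, rng):
        from collections import Counter

        for _ in range(20):
            n = int(rng.integers(10, 60))
            k = int(rng.integers(2, 6))
            lab = pd.Series(
                rng.integers(0, k, n), index=[f"P{i}" for i in range(n)]
            )
            while lab.nunique() != k:
                lab = pd.Series(
                    rng.integers(0, k, n), index=[f"P{i}" for i in range(n)]
                )
            y = pd.Series(rng.integers(0, 2, n), index=lab.index)
            assign = cluster.ClusterAssignment(lab, k=k)
            brute = (
                sum(
                    Counter(y[lab == c]).most_common(1)[0][1]
                    for c in range(k)
                )
                / n
            )
            assert cluster.purity(assign, y) == pytest.approx(brute)
            # lower bound: majority class overall
            overall = max(y.mean(), 1 - y.mean())
            assert cluster.purity(assign, y) >= overall - 1e-12

    def test_purity_nondecreasing_in_k(self, rng):
        X = rng.normal(size=(40, 5))
        ids = [f"P{i:03d}" for i in range(40)]
        y = pd.Series(rng.integers(0, 2, 40), index=ids)
        dend = cluster.hierarchical_cluster(cluster.distance_matrix(make_matrix(X)))
        purities = [
            cluster.purity(cluster.cut_tree(dend, k), y) for k in range(1, 12)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(purities, purities[1:]))


class TestHomogeneity:
    def test_published_chi2(self):
        assign, y = assignment_from_counts([(5, 2), (35, 24), (40, 55)])
        chi2, p = cluster.outcome_homogeneity_test(assign, y)
        assert chi2 == pytest.approx(5.69, abs=0.01)
        assert p == pytest.approx(0.058, abs=0.0005)

    def test_identical_frequencies_give_p_one(self):
        assign, y = assignment_from_counts([(10, 10), (20, 20), (5, 5)])
        chi2, p = cluster.outcome_homogeneity_test(assign, y)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_consistent_with_stats_module_2x2(self):
        from phenomap import stats

        assign, y = assignment_from_counts([(12, 5), (6, 14)])
        chi2, p = cluster.outcome_homogeneity_test(assign, y)
        ref = stats.chi_square_test([[12, 5], [6, 14]], correction="off")
        assert chi2 == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.p_value)


class TestSelectK:
    def test_tied_p_values_pick_smallest_k(self):
        # four tight pairs, each pair one HFpEF + one asymptomatic:
        # every 2-4 cluster cut is a union of pairs, all with 50% outcome,
        # so p = 1 everywhere and the tie-break must choose k = 2
        X = np.array([[0.0], [0.01], [10.0], [10.01], [20.0], [20.01], [30.0], [30.01]])
        ids = [f"P{i:03d}" for i in range(8)]
        y = pd.Series([1, 0] * 4, index=ids)
        dend = cluster.hierarchical_cluster(cluster.distance_matrix(make_matrix(X)))
        assign, evals = cluster.select_k(dend, y, range(2, 5))
        assert all(e.p_value == pytest.approx(1.0) for e in evals)
        assert assign.k == 2

    def test_strong_three_group_structure_selected(self, rng):
        centers = np.array([0.0, -6.0, 3.0])
        sizes, freqs = (53, 53, 54), (0.7, 0.6, 0.4)
        X, y = [], []
        for c in range(3):
            X.append(rng.normal(centers[c], 1.0, size=(sizes[c], 5)))
            y.append(rng.uniform(size=sizes[c]) < freqs[c])
        X, y = np.vstack(X), np.concatenate(y).astype(int)
        ids = [f"P{i:03d}" for i in range(len(y))]
        dend = cluster.hierarchical_cluster(cluster.distance_matrix(make_matrix(X)))
        assign, evals = cluster.select_k(dend, pd.Series(y, index=ids))
        assert {e.k for e in evals} == {2, 3, 4, 5}
        best = min(evals, key=lambda e: (e.p_value, e.k))
        assert assign.k == best.k
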