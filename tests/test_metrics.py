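"""Transfer entropy, silhouette width, k-NN, and TE-row clustering."""
import numpy as np
import pytest

from neurotwin.metrics import (assign_by_silhouette, cluster_te_rows,
                               knn_assign, mean_silhouette_positive,
                               silhouette_width, te_matrix,
                               transfer_entropy, TransferEntropyTable)


# --------------------------------------------------------------------------
# transfer entropy
# --------------------------------------------------------------------------
def _enumerated_te_noisy_copy(p_flip: float) -> float:
    """Exact TE (nats) for Y_{t+1} = X_t with flip probability p.

    Brute-force enumeration of the stationary joint distribution of
    (Y_{t+1}, Y_t, X_t) with X iid Bernoulli(1/2); independent of the
    estimator under test.
    """
    te = 0.0
    # p(y1, y0, x0) = p(x0) p(y0) p(y1 | x0); y0 is an independent earlier flip
    joint = np.zeros((2, 2, 2))
    for x0 in (0, 1):
        for y0 in (0, 1):
            for y1 in (0, 1):
                p_y1 = (1 - p_flip) if y1 == x0 else p_flip
                joint[y1, y0, x0] = 0.5 * 0.5 * p_y1
    p_y1y0 = joint.sum(axis=2)
    p_y0x0 = joint.sum(axis=0)
    p_y0 = joint.sum(axis=(0, 2))
    for y1 in (0, 1):
        for y0 in (0, 1):
            for x0 in (0, 1):
                pj = joint[y1, y0, x0]
                if pj > 0:
                    te += pj * np.log(pj * p_y0[y0]
                                      / (p_y1y0[y1, y0] * p_y0x0[y0, x0]))
    return te


class TestTransferEntropy:
    def test_independent_series_close_to_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=4000)
        y = rng.normal(size=4000)
        res = transfer_entropy(x, y, full=True, seed=1)
        assert abs(res.value) < 3 * res.null_sd + 1e-3

    @pytest.mark.parametrize("p_flip", [0.1, 0.3])
    def test_noisy_copy_chain_matches_enumeration(self, p_flip):
        """Plug-in estimate on a binary Markov chain vs the exact value."""
        rng = np.random.default_rng(2)
        n = 30000
        x = rng.integers(0, 2, n)
        flips = rng.random(n) < p_flip
        y = np.empty(n, dtype=int)
        y[0] = x[0]
        y[1:] = np.where(flips[1:], 1 - x[:-1], x[:-1])
        expect = _enumerated_te_noisy_copy(p_flip)
        est = transfer_entropy(x, y, n_bins=2, seed=3)
        assert est == pytest.approx(expect, abs=0.02)

    def test_unidirectional_coupling_has_no_reverse_flow(self):
        rng = np.random.default_rng(4)
        n = 20000
        x = rng.integers(0, 2, n)
        y = np.empty(n, dtype=int)
        y[0] = 0
        y[1:] = x[:-1]
        forward = transfer_entropy(x, y, n_bins=2, seed=5, full=True)
        reverse = transfer_entropy(y, x, n_bins=2, seed=6, full=True)
        assert forward.value > 0.5          # ~log 2 for a perfect copy
        assert abs(reverse.value) < 3 * reverse.null_sd + 1e-3

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            transfer_entropy([1.0, 2.0], [0.5, 0.1])


class TestTeMatrix:
    def _traces(self, rng, n_folds=2, L2=2, R=3, T=400):
        traces = {}
        for f in range(n_folds):
            for cond in ("anesthetized", "awake"):
                z2 = rng.normal(size=(T, L2))
                d1 = rng.normal(size=(T, R, 4))
                traces[(f, cond)] = (z2, d1)
        return traces

    def test_shape_matches_fold_and_region_layout(self):
        """4 folds x 3 units by 10 regions x 2 conditions -> 12 x 20."""
        rng = np.random.default_rng(7)
        traces = {}
        for f in range(4):
            for cond in ("anesthetized", "awake"):
                traces[(f, cond)] = (rng.normal(size=(60, 3)),
                                     rng.normal(size=(60, 10, 2)))
        regions = [f"R{i}" for i in range(10)]
        table = te_matrix(traces, regions, n_permutations=0)
        assert table.matrix.shape == (12, 20)

    def test_duplicate_regions_give_identical_columns(self):
        rng = np.random.default_rng(8)
        z2 = rng.normal(size=(500, 1))
        d1 = rng.normal(size=(500, 1, 2))
        d1_dup = np.concatenate([d1, d1], axis=1)
        traces = {(0, "awake"): (z2, d1_dup), (0, "anesthetized"): (z2, d1_dup)}
        table = te_matrix(traces, ["A", "B"], n_permutations=0)
        m = table.data
        assert np.allclose(m[("A", "awake")], m[("B", "awake")])

    def test_planted_driver_dominates_its_row(self):
        """A z2 unit that drives region 0 shows the largest TE there."""
        rng = np.random.default_rng(9)
        T = 3000
        z2 = rng.normal(size=(T, 2))
        d1 = rng.normal(size=(T, 3)) * 0.3
        d1[1:, 0] += 1.5 * np.sign(z2[:-1, 0])        # unit 0 -> region 0
        traces = {(0, "awake"): (z2, d1), (0, "anesthetized"): (z2, d1)}
        table = te_matrix(traces, ["A", "B", "C"], n_permutations=20, seed=1)
        row0 = table.data.loc[(0, 0)]
        assert row0[("A", "awake")] == row0.max()

    def test_zscore_is_global(self):
        rng = np.random.default_rng(10)
        table = te_matrix(self._traces(rng), ["A", "B", "C"],
                          n_permutations=0)
        z = table.zscored().to_numpy()
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0)


# --------------------------------------------------------------------------
# silhouette
# --------------------------------------------------------------------------
def _brute_force_silhouette(points, labels):
    n = len(points)
    s = np.zeros(n)
    for i in range(n):
        d_i = [np.linalg.norm(points[i] - points[j]) for j in range(n)]
        own = [d_i[j] for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            continue
        a = sum(own) / len(own)
        b = min(
            np.mean([d_i[j] for j in range(n) if labels[j] == lab])
            for lab in set(labels) if lab != labels[i])
        s[i] = (b - a) / max(a, b)
    return s


class TestSilhouette:
    def test_two_tight_pairs_hand_value(self):
        pts = np.array([[0, 0], [0, 1], [10, 0], [10, 1]], dtype=float)
        labels = np.array(["A", "A", "B", "B"])
        res = silhouette_width(pts, labels)
        b = (10.0 + np.sqrt(101.0)) / 2.0
        assert np.allclose(res.s, (b - 1.0) / b)
        assert res.mean == pytest.approx((b - 1.0) / b)

    def test_equidistant_point_scores_zero(self):
        # point 0: a = 2 (its cluster mate), b = 2 (the other cluster)
        pts = np.array([[0.0], [2.0], [-2.0]])
        labels = np.array(["A", "A", "B"])
        res = silhouette_width(pts, labels)
        assert res.s[0] == pytest.approx(0.0)

    def test_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(11)
        pts = rng.normal(size=(50, 3))
        labels = rng.choice(list("ABC"), size=50)
        res = silhouette_width(pts, labels)
        assert np.allclose(res.s, _brute_force_silhouette(pts, labels))

    def test_matches_sklearn(self):
        from sklearn.metrics import silhouette_samples
        rng = np.random.default_rng(12)
        pts = rng.normal(size=(40, 2))
        labels = rng.choice(["x", "y", "z"], size=40)
        res = silhouette_width(pts, labels)
        assert np.allclose(res.s, silhouette_samples(pts, labels))

    def test_single_cluster_raises(self):
        with pytest.raises(ValueError):
            silhouette_width(np.zeros((3, 2)), np.array(["A", "A", "A"]))

    def test_random_labels_on_symmetric_data_average_near_zero(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(200, 2))
        labels = rng.choice(["A", "B"], size=200)
        res = silhouette_width(pts, labels)
        assert abs(res.mean) < 0.05

    def test_positive_mean_test_helper(self):
        s = np.full(50, 0.3) + np.random.default_rng(14).normal(0, 0.05, 50)
        t, p = mean_silhouette_positive(s)
        assert p < 1e-10


class TestAssignBySilhouette:
    def test_centroid_goes_to_own_cluster(self):
        clusters = {"A": np.array([[0, 0], [0, 1]]),
                    "B": np.array([[5, 5], [5, 6]])}
        assert assign_by_silhouette([0.0, 0.5], clusters) == "A"

    def test_midpoint_tie_breaks_to_first_sorted_label(self):
        clusters = {"B": np.array([[1.0]]), "A": np.array([[-1.0]])}
        assert assign_by_silhouette([0.0], clusters) == "A"

    def test_agrees_with_brute_force_configurations(self):
        rng = np.random.default_rng(15)
        for _ in range(100):
            a = rng.normal(0, 1, (4, 2))
            b = rng.normal(3, 1, (4, 2))
            q = rng.normal(1.5, 2, 2)
            # brute force: compare mean distances via silhouette definition
            da = np.mean([np.linalg.norm(q - p) for p in a])
            db = np.mean([np.linalg.norm(q - p) for p in b])
            s_in_a = (db - da) / max(da, db)
            s_in_b = (da - db) / max(da, db)
            expect = "A" if s_in_a >= s_in_b else "B"
            assert assign_by_silhouette(q, {"A": a, "B": b}) == expect

    def test_empty_cluster_raises(self):
        with pytest.raises(ValueError):
            assign_by_silhouette([0.0], {"A": np.empty((0, 1)),
                                         "B": np.array([[1.0]])})


# --------------------------------------------------------------------------
# k-NN
# --------------------------------------------------------------------------
class TestKnnAssign:
    def test_exact_reference_point_with_k1(self):
        ref = np.array([[0.0, 0.0], [5.0, 5.0], [1.0, 2.0], [6.0, 4.0]])
        lab = np.array(["A", "B", "A", "B"])
        res = knn_assign(ref[[1]], ref, lab, k_candidates=[1])
        assert res.labels[0] == "B"

    def test_separated_gaussians_classified_perfectly(self):
        rng = np.random.default_rng(16)
        a = rng.normal(0, 0.1, (50, 2))
        b = rng.normal(3, 0.1, (50, 2))
        ref = np.vstack([a, b])
        lab = np.array(["A"] * 50 + ["B"] * 50)
        res = knn_assign(np.array([[0, 0], [3, 3]]), ref, lab)
        assert list(res.labels) == ["A", "B"]
        assert res.loocv_accuracy == 1.0

    def test_k1_reproduces_reference_labels(self):
        rng = np.random.default_rng(17)
        ref = rng.normal(size=(30, 2))
        lab = rng.choice(["A", "B"], 30)
        res = knn_assign(ref, ref, lab, k_candidates=[1])
        assert np.array_equal(res.labels, lab)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            knn_assign(np.zeros((1, 1)), np.zeros((4, 1)),
                       np.array(list("ABAB")), k_candidates=[2])

    def test_too_few_reference_points_raises(self):
        with pytest.raises(ValueError):
            knn_assign(np.zeros((1, 1)), np.zeros((2, 1)),
                       np.array(["A", "B"]), k_candidates=[3])


# --------------------------------------------------------------------------
# hierarchical clustering of TE rows
# --------------------------------------------------------------------------
def _table_from(matrix, n_regions=2):
    import pandas as pd
    n_rows, n_cols = matrix.shape
    regions = [f"R{i}" for i in range(n_cols // 2)]
    cols = pd.MultiIndex.from_tuples(
        [(r, c) for r in regions for c in ("anesthetized", "awake")])
    idx = pd.MultiIndex.from_tuples(
        [(i // 3, i % 3) for i in range(n_rows)], names=["fold", "unit"])
    return TransferEntropyTable(pd.DataFrame(matrix, index=idx, columns=cols))


class TestClusterTeRows:
    def test_identical_rows_merge_at_zero_distance(self):
        m = np.tile([1.0, 2.0, 3.0, 4.0], (3, 1))
        m = m + np.array([[0.0], [0.0], [5.0]])
        res = cluster_te_rows(_table_from(m), n_groups=2)
        assert res.groups[0] == res.groups[1] != res.groups[2]
        assert res.linkage[0, 2] == pytest.approx(0.0)

    def test_planted_blocks_recovered(self):
        rng = np.random.default_rng(18)
        blocks = []
        for center in (0.0, 5.0, -5.0):
            blocks.append(center + rng.normal(0, 0.1, (3, 6)))
        m = np.vstack(blocks)
        res = cluster_te_rows(_table_from(m), n_groups=3)
        g = res.groups
        assert len(set(g[:3])) == 1
        assert len(set(g[3:6])) == 1
        assert len(set(g[6:])) == 1
        assert len(set(g)) == 3

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(19)
        m = np.vstack([rng.normal(0, 0.1, (3, 4)),
                       rng.normal(4, 0.1, (3, 4))])
        perm = rng.permutation(6)
        res1 = cluster_te_rows(_table_from(m), n_groups=2)
        res2 = cluster_te_rows(_table_from(m[perm]), n_groups=2)
        # same partition after undoing the permutation
        part1 = [frozenset(np.where(res1.groups == g)[0])
                 for g in sorted(set(res1.groups))]
        part2 = [frozenset(perm[np.where(res2.groups == g)[0]])
                 for g in sorted(set(res2.groups))]
        assert set(part1) == set(part2)

    def test_newick_export_contains_all_rows(self):
        m = np.random.default_rng(20).normal(size=(4, 4))
        res = cluster_te_rows(_table_from(m), n_groups=2)
        assert res.newick.endswith(";")
        for lab in res.row_labels:
            assert lab in res.newick
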