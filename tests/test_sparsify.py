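import numpy as np
import pytest

from spcn.data_io import SignalMatrix
from spcn.pcm import SignificanceMatrices, SymmetricAssociationMatrix
from spcn.sparsify import (
    CvErrorCurve,
    build_mask,
    build_spcn,
    complete_special_node,
    cv_prediction_error,
    fold_split,
    select_threshold,
    threshold_grid,
)
from spcn.synthetic import random_sparse_precision, sample_ggm


class TestFoldSplit:
    def test_leave_one_out_degenerate(self):
        labels = fold_split(10, 10, seed=0)
        assert sorted(np.bincount(labels)) == [1] * 10

    def test_partition_sizes(self):
        labels = fold_split(103, 10, seed=1)
        sizes = np.bincount(labels, minlength=10)
        assert set(sizes) <= {10, 11}
        assert sizes.sum() == 103

    def test_seed_reproducibility(self):
        a = fold_split(100, 10, seed=5)
        b = fold_split(100, 10, seed=5)
        c = fold_split(100, 10, seed=6)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_bad_args(self):
        with pytest.raises(ValueError):
            fold_split(5, 1, seed=0)
        with pytest.raises(ValueError):
            fold_split(3, 5, seed=0)


def sparse_P(p, pairs):
    S = np.eye(p)
    for i, j in pairs:
        S[i, j] = S[j, i] = 0.5
    return S


class TestCvPredictionError:
    def test_intercept_only_error(self):
        train = np.array([[1.0], [2.0], [3.0]])
        test = np.array([[5.0]])
        err = cv_prediction_error(train, test, np.eye(1))
        assert err == pytest.approx((5.0 - 2.0) ** 2)

    def test_perfect_linear_fit(self):
        rng = np.random.default_rng(0)
        x = rng.random(50)
        train = np.column_stack([x, 2 * x])
        xt = rng.random(10)
        test = np.column_stack([xt, 2 * xt])
        err_y = cv_prediction_error(train, test, sparse_P(2, [(0, 1)]))
        assert err_y == pytest.approx(0.0, abs=1e-18)

    def test_hand_computed_ols(self):
        # train x=[1,2,3], y=[2,4,6]; OLS gives y=2x; test (4, 9) -> (9-8)^2 = 1
        train = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        test = np.array([[4.0, 9.0]])
        err = cv_prediction_error(train, test, sparse_P(2, [(0, 1)]))
        # variable x is perfectly predicted from y as well; mean over the two
        assert err == pytest.approx((1.0 + 0.25) / 2)

    def test_singular_design_warns_not_fatal(self):
        rng = np.random.default_rng(1)
        x = rng.random(20)
        train = np.column_stack([x, x, rng.random(20)])
        test = np.column_stack([x[:5], x[:5], rng.random(5)])
        with pytest.warns(UserWarning, match="redundant"):
            err = cv_prediction_error(
                train, test, sparse_P(3, [(0, 2), (1, 2)])
            )
        assert np.isfinite(err)


class TestSelectThreshold:
    def test_ten_percent_rule_worked_example(self):
        curve = CvErrorCurve(
            thresholds=[1e-1, 1e-2, 1e-3, 1e-4],
            errors=[0.40, 0.42, 0.45, 0.90],
        )
        assert select_threshold(curve, 0.10) == pytest.approx(1e-3)

    def test_flat_curve_lowest_threshold(self):
        curve = CvErrorCurve(thresholds=[0.1, 0.01, 0.001], errors=[0.5, 0.5, 0.5])
        assert select_threshold(curve) == pytest.approx(0.001)

    def test_zero_tolerance_argmin(self):
        curve = CvErrorCurve(
            thresholds=[0.1, 0.01, 0.001], errors=[0.40, 0.40, 0.90]
        )
        assert select_threshold(curve, 0.0) == pytest.approx(0.01)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            CvErrorCurve(thresholds=[0.01, 0.1], errors=[0.1, 0.2])
        with pytest.raises(ValueError):
            CvErrorCurve(thresholds=[0.1], errors=[np.nan])


class TestThresholdGrid:
    def test_covers_all_unique_values(self):
        q = np.array([0.5, 0.01, 0.2, 0.01])
        grid = threshold_grid(q)
        assert set([0.5, 0.2, 0.01]) <= set(grid)
        assert np.all(np.diff(grid) < 0)

    def test_sentinel_gives_empty_model(self):
        q = np.array([0.5, 0.2])
        grid = threshold_grid(q)
        assert grid[-1] < 0.2

    def test_cap_respected(self):
        rng = np.random.default_rng(2)
        q = rng.random(1000)
        grid = threshold_grid(q, cap=50)
        assert grid.size <= 53  # cap + endpoints + sentinel


class TestBuildMask:
    def keeps(self, count, n_folds=10, p=3):
        mats = []
        for f in range(n_folds):
            m = np.zeros((p, p), dtype=bool)
            if f < count:
                m[0, 1] = m[1, 0] = True
            mats.append(m)
        return mats

    def test_seven_of_ten_kept(self):
        mask = build_mask(self.keeps(7), min_support=7)
        assert mask.keep[0, 1]
        assert mask.support[0, 1] == 7
        assert mask.provenance[0, 1] == "masked"

    def test_six_of_ten_dropped(self):
        mask = build_mask(self.keeps(6), min_support=7)
        assert not mask.keep[0, 1]
        assert mask.support[0, 1] == 6

    def test_unanimity_and_absence(self):
        assert build_mask(self.keeps(10), 7).keep[0, 1]
        assert not build_mask(self.keeps(0), 7).keep[0, 1]

    def test_symmetry_and_diagonal(self):
        mask = build_mask(self.keeps(8))
        np.testing.assert_array_equal(mask.keep, mask.keep.T)
        assert not mask.keep.diagonal().any()


class TestCompleteSpecialNode:
    def setup_mask(self, kept_pairs, p=5):
        mats = [np.zeros((p, p), dtype=bool) for _ in range(10)]
        for m in mats:
            for i, j in kept_pairs:
                m[i, j] = m[j, i] = True
        return build_mask(mats, 7)

    def sig(self, qrow, p=5):
        q = np.ones((p, p))
        q[0, 1:] = q[1:, 0] = qrow
        np.fill_diagonal(q, 0)
        return SignificanceMatrices(np.zeros((p, p)), q, p * (p - 1) // 2)

    def test_already_at_target_unchanged(self):
        names = ["mRNA", "A", "B", "C", "D"]
        mask = self.setup_mask([(0, 1), (0, 2), (0, 3), (0, 4)])
        out = complete_special_node(mask, self.sig([0.1] * 4), names, "mRNA", 4)
        np.testing.assert_array_equal(out.keep, mask.keep)

    def test_smallest_q_selected(self):
        # degree 2, deficit 2; candidates B:0.3, C:0.1, D:0.2 -> add C and D
        names = ["mRNA", "A", "B", "C", "D", "E"]
        mask = self.setup_mask([(0, 1), (0, 5)], p=6)
        q = self.sig([0.9, 0.3, 0.1, 0.2, 0.8], p=6)
        out = complete_special_node(mask, q, names, "mRNA", 4)
        assert out.keep[0, 3] and out.keep[0, 4]
        assert not out.keep[0, 2]
        assert out.provenance[0, 3] == "mrna_completed"
        assert out.provenance[0, 1] == "masked"

    def test_saturation_warns(self):
        names = ["mRNA", "A", "B", "C"]
        mats = [np.zeros((4, 4), dtype=bool) for _ in range(10)]
        mask = build_mask(mats, 7)
        q = SignificanceMatrices(np.zeros((4, 4)), np.ones((4, 4)), 6)
        with pytest.warns(UserWarning, match="completing as far as possible"):
            out = complete_special_node(mask, q, names, "mRNA", 4)
        assert out.keep[0].sum() == 3

    def test_unknown_node_fatal(self):
        mask = self.setup_mask([])
        with pytest.raises(ValueError, match="special node"):
            complete_special_node(mask, self.sig([0.1] * 4), list("abcde"), "mRNA")


class TestBuildSpcn:
    def test_independence_model_empty_network(self):
        truth = random_sparse_precision(6, 0, seed=0)
        X = sample_ggm(truth, 5000, seed=1)
        net = build_spcn(X, seed=2)
        assert net.edge_indices() == []

    def test_chain_recovery(self, chain_sample):
        X, truth = chain_sample
        net = build_spcn(X, seed=3)
        assert set(net.edge_indices()) == {(0, 1), (1, 2)}
        # signs follow the true partial correlations
        assert np.sign(net.weights[0, 1]) == np.sign(truth.partial_corr_true[0, 1])

    def test_deterministic_given_seed(self, chain_sample):
        X, _ = chain_sample
        a = build_spcn(X, seed=4)
        b = build_spcn(X, seed=4)
        np.testing.assert_array_equal(a.weights, b.weights)
        np.testing.assert_array_equal(a.mask.support, b.mask.support)
        assert a.fold_thresholds == b.fold_thresholds

    def test_monotone_sparsification_per_fold(self):
        # lowering the q-threshold never adds edges
        rng = np.random.default_rng(5)
        truth = random_sparse_precision(5, 4, seed=6)
        X = sample_ggm(truth, 500, seed=7)
        from spcn.pcm import correlation_matrix, fisher_z_significance, \
            partial_correlation_matrix, rank_transform

        sig = fisher_z_significance(
            partial_correlation_matrix(correlation_matrix(rank_transform(X)))
        )
        grid = threshold_grid(sig.qvalues[np.triu_indices(5, 1)])
        prev = None
        for t in grid:
            keep = sig.qvalues <= t
            np.fill_diagonal(keep, False)
            if prev is not None:
                assert np.all(prev | ~keep)  # keep subset of prev
            prev = keep

    def test_mask_edges_significant_in_min_support_folds(self, chain_sample):
        X, _ = chain_sample
        net = build_spcn(X, seed=8)
        for i, j in net.edge_indices():
            assert net.mask.support[i, j] >= net.mask.min_support

    def test_special_node_completion_in_pipeline(self):
        truth = random_sparse_precision(6, 0, seed=9)
        X = sample_ggm(truth, 3000, seed=10)
        X.variable_names[0] = "mRNA"
        net = build_spcn(X, seed=11, special_node="mRNA", special_degree=4)
        i = net.variable_names.index("mRNA")
        assert net.mask.keep[i].sum() == 4
        provs = {net.mask.provenance[i, j] for j in np.flatnonzero(net.mask.keep[i])}
        assert provs == {"mrna_completed"}
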