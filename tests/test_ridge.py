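import numpy as np
import pytest

from neurodistill import (
    ValidationError,
    connectivity,
    connectivity_matrix,
    fit_ridge,
    predict_target,
    score_r2,
    select_lambda,
)


class TestFitRidge:
    def test_near_interpolation_when_seed_equals_target(self):
        rng = np.random.default_rng(0)
        seed = rng.standard_normal((25, 5))
        rm = fit_ridge(seed, seed, 1e-8)
        np.testing.assert_allclose(predict_target(rm, seed), seed, atol=1e-6)

    def test_matches_independent_lstsq_oracle(self):
        # the oracle solves each voxel by QR on the λ-augmented design,
        # independent of the joint normal-equations path under test
        rng = np.random.default_rng(1)
        for _ in range(10):
            n, p, q = 20, 5, 3
            lam = 2.5
            seed = rng.standard_normal((n, p))
            target = rng.standard_normal((n, q))
            rm = fit_ridge(seed, target, lam)
            S = seed - seed.mean(axis=0)
            T = target - target.mean(axis=0)
            aug = np.vstack([S, np.sqrt(lam) * np.eye(p)])
            oracle = np.linalg.lstsq(
                aug, np.vstack([T, np.zeros((p, q))]), rcond=None
            )[0]
            np.testing.assert_allclose(rm.weights, oracle, atol=1e-8)

    def test_matches_sklearn_ridge(self):
        sklearn_linear = pytest.importorskip("sklearn.linear_model")
        rng = np.random.default_rng(5)
        seed = rng.standard_normal((40, 6))
        target = rng.standard_normal((40, 2))
        rm = fit_ridge(seed, target, 3.0)
        sk = sklearn_linear.Ridge(alpha=3.0).fit(seed, target)
        np.testing.assert_allclose(rm.weights, sk.coef_.T, atol=1e-8)
        np.testing.assert_allclose(rm.intercepts, sk.intercept_, atol=1e-8)

    def test_noiseless_map_recovered_in_small_lambda_limit(self):
        rng = np.random.default_rng(2)
        seed = rng.standard_normal((50, 4))
        A = rng.standard_normal((4, 3))
        c = rng.standard_normal(3)
        target = seed @ A + c
        rm = fit_ridge(seed, target, 1e-10)
        np.testing.assert_allclose(rm.weights, A, atol=1e-4)
        np.testing.assert_allclose(rm.intercepts, c, atol=1e-4)

    def test_intercept_absorbs_constant_seed_shift(self):
        rng = np.random.default_rng(3)
        seed = rng.standard_normal((30, 4))
        target = rng.standard_normal((30, 2))
        rm = fit_ridge(seed, target, 1.0)
        rm_shift = fit_ridge(seed + 5.0, target, 1.0)
        np.testing.assert_allclose(
            predict_target(rm, seed), predict_target(rm_shift, seed + 5.0),
            atol=1e-8,
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValidationError):
            fit_ridge(np.ones((1, 2)), np.ones((1, 2)), 1.0)
        with pytest.raises(ValidationError):
            fit_ridge(np.ones((5, 2)), np.ones((5, 2)), 0.0)
        bad = np.ones((5, 2))
        bad[0, 0] = np.inf
        with pytest.raises(ValidationError):
            fit_ridge(bad, np.ones((5, 2)), 1.0)


class TestScoreR2:
    def test_anchor_values(self):
        actual = np.array([[1.0], [2.0], [3.0], [4.0]])
        assert score_r2(actual, actual)[0] == pytest.approx(1.0)
        means = np.full_like(actual, actual.mean())
        assert score_r2(means, actual)[0] == pytest.approx(0.0)
        predicted = np.array([[1.0], [2.0], [3.0], [5.0]])
        assert score_r2(predicted, actual)[0] == pytest.approx(0.8)

    def test_zero_variance_voxels_excluded(self):
        actual = np.column_stack([np.arange(4.0), np.full(4, 2.0)])
        predicted = actual.copy()
        mean, per_voxel = score_r2(predicted, actual)
        assert mean == pytest.approx(1.0)
        assert np.isnan(per_voxel[1])

    def test_training_r2_nonincreasing_in_lambda(self):
        rng = np.random.default_rng(4)
        seed = rng.standard_normal((40, 8))
        target = rng.standard_normal((40, 3))
        r2s = []
        for lam in [1e-2, 1.0, 1e2, 1e4]:
            rm = fit_ridge(seed, target, lam)
            r2s.append(score_r2(predict_target(rm, seed), target)[0])
        assert all(a >= b - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_strictly_decreasing_as_noise_added(self):
        rng = np.random.default_rng(6)
        actual = rng.standard_normal((100, 4))
        worse = 0
        for _ in range(20):
            clean = actual + 0.1 * rng.standard_normal(actual.shape)
            noisy = clean + 0.5 * rng.standard_normal(actual.shape)
            if score_r2(noisy, actual)[0] < score_r2(clean, actual)[0]:
                worse += 1
        assert worse == 20


class TestSelectLambda:
    def test_single_element_grid(self):
        rng = np.random.default_rng(0)
        s, t = rng.standard_normal((20, 3)), rng.standard_normal((20, 2))
        best, scores = select_lambda(s[:10], t[:10], s[10:], t[10:], [7.5])
        assert best == 7.5 and set(scores) == {7.5}

    def test_noiseless_data_prefers_smallest_lambda(self):
        rng = np.random.default_rng(1)
        seed = rng.standard_normal((60, 4))
        target = seed @ rng.standard_normal((4, 3))
        best, scores = select_lambda(
            seed[:30], target[:30], seed[30:], target[30:],
            [1e-6, 1e0, 1e4],
        )
        assert best == pytest.approx(1e-6)
        assert scores[1e-6] >= scores[1e4]

    def test_pure_noise_target_prefers_heavy_shrinkage(self):
        rng = np.random.default_rng(2)
        wins = 0
        for _ in range(10):
            seed = rng.standard_normal((60, 10))
            target = rng.standard_normal((60, 4))
            grid = [1e-2, 1e2, 1e6]
            best, scores = select_lambda(
                seed[:30], target[:30], seed[30:], target[30:], grid
            )
            if scores[1e6] >= scores[1e-2]:
                wins += 1
            rm_small = fit_ridge(seed[:30], target[:30], 1e-2)
            train_r2 = score_r2(predict_target(rm_small, seed[:30]), target[:30])[0]
            assert scores[best] <= train_r2
        assert wins >= 9

    def test_empty_grid_rejected(self):
        with pytest.raises(ValidationError):
            select_lambda(np.ones((4, 2)), np.ones((4, 2)),
                          np.ones((4, 2)), np.ones((4, 2)), [])


class TestConnectivity:
    def test_self_connectivity_is_one(self, small_sim):
        dataset, _, _ = small_sim
        roi = dataset.roi_names[0]
        assert connectivity(dataset, roi, roi, "train") == pytest.approx(1.0)

    def test_independent_noise_regions_near_zero(self):
        from neurodistill import TrialDataset

        rng = np.random.default_rng(17)
        n = 2000
        ds = TrialDataset(
            subject_id="noise",
            activity=rng.standard_normal((n, 20)),
            trial_category=np.zeros(n, dtype=int),
            trial_split=["train"] * n,
            trial_run=np.zeros(n, dtype=int),
            voxel_roi=["R1"] * 10 + ["R2"] * 10,
        )
        r = connectivity(ds, "R1", "R2", "train")
        assert abs(r) < 0.07  # 3·SE bound at n = 2000

    def test_hierarchy_falloff_matches_default_config(self, default_sim):
        dataset, _, _ = default_sim
        cm = connectivity_matrix(dataset, dataset.roi_names, "train")
        row = cm[0]  # V1 against the hierarchy
        assert row[1] > row[3] > row[6]
        # adjacent pairs couple more strongly than the most distant pair
        adjacent = [cm[i, i + 1] for i in range(6)]
        assert min(adjacent) > cm[0, 6]

    def test_matrix_symmetric_unit_diagonal_elementwise(self, small_sim):
        dataset, _, _ = small_sim
        rois = dataset.roi_names
        cm = connectivity_matrix(dataset, rois, "validation")
        np.testing.assert_allclose(cm, cm.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(cm), 1.0)
        assert cm[0, 1] == pytest.approx(
            connectivity(dataset, rois[0], rois[1], "validation")
        )

    def test_constant_series_rejected(self):
        from neurodistill import TrialDataset

        ds = TrialDataset(
            subject_id="x",
            activity=np.column_stack([np.ones(5), np.arange(5.0)]),
            trial_category=[0, 1, 2, 3, 4],
            trial_split=["train"] * 5,
            trial_run=[0] * 5,
            voxel_roi=["A", "B"],
        )
        with pytest.raises(ValidationError):
            connectivity(ds, "A", "B", "train")
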