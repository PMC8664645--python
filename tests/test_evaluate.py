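import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from neurodistill import (
    EffectMatrix,
    ValidationError,
    build_effect_matrix,
    corner_means,
    fisher_z,
    paired_effect_test,
    unit_scores,
)


class TestUnitScores:
    def test_perfect_and_inverted_predictions(self):
        truth = np.arange(12.0).reshape(4, 3)
        perfect = unit_scores(truth, truth, ["a", "b", "c"])
        assert all(s.r == pytest.approx(1.0) for s in perfect)
        assert all(s.mae == 0.0 and s.mse == 0.0 for s in perfect)
        inverted = unit_scores(-truth, truth, ["a", "b", "c"])
        assert all(s.r == pytest.approx(-1.0) for s in inverted)

    def test_hand_computed_metrics(self):
        truth = np.array([[0.0], [1.0], [2.0]])
        predicted = np.array([[0.0], [2.0], [4.0]])
        (s,) = unit_scores(predicted, truth, ["u"])
        assert s.r == pytest.approx(1.0, abs=1e-10)
        assert s.mae == pytest.approx(1.0, abs=1e-10)
        assert s.mse == pytest.approx(5.0 / 3.0, abs=1e-10)

    def test_degenerate_unit_has_nan_r_but_finite_errors(self):
        truth = np.array([[1.0], [2.0], [3.0]])
        constant = np.full((3, 1), 2.0)
        (s,) = unit_scores(constant, truth, ["u"])
        assert np.isnan(s.r) and np.isfinite(s.mae)

    def test_too_few_categories_rejected(self):
        with pytest.raises(ValidationError):
            unit_scores(np.ones((2, 1)), np.ones((2, 1)), ["u"])


class TestFisherZ:
    def test_anchor_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.floats(-0.999, 0.999))
    def test_odd_symmetry(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_out_of_range_clipped_with_warning(self):
        with pytest.warns(RuntimeWarning):
            z = fisher_z(1.0)
        assert np.isfinite(z)


class TestPairedEffectTest:
    def test_identical_conditions_give_null_result(self):
        r = np.array([0.1, 0.4, -0.2, 0.3])
        res = paired_effect_test(r, r)
        assert res.t == 0.0 and res.p == 1.0 and res.df == 3

    def test_hand_computed_case(self):
        before = np.zeros(3)
        after = np.tanh([0.1, 0.2, 0.3])  # Δz = 0.1, 0.2, 0.3 exactly
        res = paired_effect_test(before, after)
        assert res.mean_dz == pytest.approx(0.2, abs=1e-10)
        assert res.t == pytest.approx(0.2 / (0.1 / np.sqrt(3)), abs=1e-9)
        assert res.df == 2

    def test_pooled_sample_of_500_gives_df_499(self):
        rng = np.random.default_rng(0)
        before = rng.uniform(-0.5, 0.5, 500)  # 100 units × 5 subjects
        after = rng.uniform(-0.5, 0.5, 500)
        assert paired_effect_test(before, after).df == 499

    def test_matches_scipy_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            before = rng.uniform(-0.9, 0.9, n)
            after = rng.uniform(-0.9, 0.9, n)
            res = paired_effect_test(before, after)
            oracle = stats.ttest_1samp(np.arctanh(after) - np.arctanh(before), 0.0)
            assert res.t == pytest.approx(oracle.statistic, abs=1e-10)
            assert res.p == pytest.approx(oracle.pvalue, abs=1e-10)

    def test_sign_antisymmetry(self):
        rng = np.random.default_rng(2)
        before = rng.uniform(-0.8, 0.8, 20)
        after = rng.uniform(-0.8, 0.8, 20)
        fwd = paired_effect_test(before, after)
        rev = paired_effect_test(after, before)
        assert fwd.t == pytest.approx(-rev.t, abs=1e-12)

    def test_missing_pairs_dropped(self):
        before = np.array([0.1, np.nan, 0.3, 0.2, -0.1])
        after = np.array([0.2, 0.1, np.nan, 0.4, 0.0])
        assert paired_effect_test(before, after).n == 3  # only complete pairs

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            paired_effect_test([0.1, np.nan, 0.2], [0.2, 0.3, np.nan])


def synthetic_scores(roi_order, n_units=10, shift=0.0, seed=0):
    """Long-form paired unit scores for every ordered ROI pair."""
    rng = np.random.default_rng(seed)
    rows = []
    for target in roi_order:
        for s in roi_order:
            if s == target:
                continue
            r_b = rng.uniform(-0.3, 0.6, n_units)
            rows += [
                {
                    "target": target, "seed": s, "subject_id": "s1",
                    "unit_id": u, "r_before": r_b[u],
                    "r_after": np.tanh(np.arctanh(r_b[u]) + shift
                                       + rng.normal(0, 0.05)),
                }
                for u in range(n_units)
            ]
    return pd.DataFrame(rows)


class TestEffectMatrix:
    ROIS = ["V1", "V2", "V3", "V4", "LOC", "FFA", "PPA"]

    def test_seven_region_matrix_has_42_populated_cells(self):
        em = build_effect_matrix(
            synthetic_scores(self.ROIS), "layer1", "perception", self.ROIS
        )
        assert np.isfinite(em.t_values).sum() == 42
        assert np.isnan(np.diag(em.t_values)).all()
        assert em.bonferroni_m == 42
        frame = em.to_frame()
        assert len(frame) == 42

    def test_identical_scores_give_zero_t_nothing_significant(self):
        scores = synthetic_scores(self.ROIS[:3])
        scores["r_after"] = scores["r_before"]
        em = build_effect_matrix(scores, "f", "perception", self.ROIS[:3])
        off = ~np.eye(3, dtype=bool)
        assert (em.t_values[off] == 0.0).all()
        assert not em.significant.any()

    def test_missing_pair_is_an_error_listing_pairs(self):
        scores = synthetic_scores(self.ROIS[:3])
        scores = scores[~((scores.target == "V1") & (scores.seed == "V3"))]
        with pytest.raises(ValidationError, match="V1"):
            build_effect_matrix(scores, "f", "perception", self.ROIS[:3])

    def test_bonferroni_monotone_in_family_size(self):
        scores = synthetic_scores(self.ROIS, shift=0.08, seed=3)
        em_big = build_effect_matrix(scores, "f", "perception", self.ROIS,
                                     correction_m=42)
        em_small = build_effect_matrix(scores, "f", "perception", self.ROIS,
                                       correction_m=6)
        assert em_big.significant.sum() <= em_small.significant.sum()
        assert not (em_big.significant & ~em_small.significant).any()

    def test_uniform_positive_shift_detected_everywhere(self):
        scores = synthetic_scores(self.ROIS, shift=0.3, seed=4)
        em = build_effect_matrix(scores, "f", "perception", self.ROIS)
        off = ~np.eye(7, dtype=bool)
        assert (em.t_values[off] > 0).all()
        assert em.significant[off].all()


class TestCornerMeans:
    def make_matrix(self, mean_dz):
        R = mean_dz.shape[0]
        dz_pools = {}
        rng = np.random.default_rng(0)
        for i in range(R):
            for j in range(R):
                if i != j:
                    dz_pools[(i, j)] = mean_dz[i, j] + rng.normal(0, 1e-6, 30)
        return EffectMatrix(
            feature_name="f", task="perception",
            roi_order=[f"R{k}" for k in range(R)],
            t_values=np.zeros((R, R)), p_values=np.ones((R, R)),
            mean_dz=mean_dz, n_pairs=30, bonferroni_m=R * (R - 1),
            significant=np.zeros((R, R), bool), dz_pools=dz_pools,
        )

    def test_all_ones_matrix(self):
        mean_dz = np.ones((7, 7))
        cs = corner_means(self.make_matrix(mean_dz))
        assert cs.top_down_mean == pytest.approx(1.0)
        assert cs.bottom_up_mean == pytest.approx(1.0)
        assert cs.top_down_test.p < 1e-6

    def test_upper_right_block_only(self):
        mean_dz = np.zeros((7, 7))
        mean_dz[:3, 4:] = 1.0  # low targets × high seeds
        cs = corner_means(self.make_matrix(mean_dz))
        assert cs.top_down_mean == pytest.approx(1.0, abs=1e-5)
        assert cs.bottom_up_mean == pytest.approx(0.0, abs=1e-5)

    def test_small_matrix_rejected(self):
        mean_dz = np.zeros((4, 4))
        with pytest.raises(ValidationError):
            corner_means(self.make_matrix(mean_dz))
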