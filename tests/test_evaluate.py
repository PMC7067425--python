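"""Evaluation protocol: SSIM, grid mask, Dice, adjustment, paired statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from skimage.metrics import structural_similarity

from winstitch import (
    ArtefactProfile,
    adjusted_scores,
    dice_scores,
    exact_sign_test,
    make_grid_mask,
    paired_t_test,
    run_benchmark,
    ssim_classwise,
)

from _oracles import dice_oracle, grid_mask_oracle


class TestSSIM:
    def test_identical_images_score_one(self, rng):
        x = rng.random((64, 64, 3))
        assert ssim_classwise(x, x) == pytest.approx(1.0)

    def test_inverted_checkerboard_is_anticorrelated(self):
        board = ((np.arange(64)[:, None] // 8 + np.arange(64)[None, :] // 8) % 2).astype(float)
        assert ssim_classwise(board, 1.0 - board) < 0

    def test_mean_over_class_channels(self, rng):
        pred = rng.random((64, 64, 3))
        truth = rng.random((64, 64, 3))
        per_channel = [
            structural_similarity(pred[..., c], truth[..., c], win_size=7, data_range=1.0)
            for c in range(3)
        ]
        assert ssim_classwise(pred, truth) == pytest.approx(np.mean(per_channel))

    def test_constant_channels_are_stable(self):
        x = np.full((32, 32, 2), 0.5)
        assert math.isfinite(ssim_classwise(x, x))

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mismatch"):
            ssim_classwise(rng.random((32, 32)), rng.random((16, 16)))


class TestGridMask:
    @pytest.mark.parametrize("patch", [32, 64, 128])
    @pytest.mark.parametrize("half_width", [1, 5])
    def test_matches_per_pixel_oracle(self, patch, half_width):
        mask = make_grid_mask(256, 256, patch, half_width)
        oracle = grid_mask_oracle(256, 256, patch, half_width)
        np.testing.assert_array_equal(mask, oracle)

    def test_zero_half_width_marks_nothing(self):
        assert not make_grid_mask(256, 256, 64, 0).any()

    def test_single_tile_has_no_interior_lines(self):
        assert not make_grid_mask(128, 128, 128, 5).any()

    def test_band_size(self):
        # 3 interior lines per axis on 256/64, bands of 2*h pixels, overlaps counted once
        h = 4
        mask = make_grid_mask(256, 256, 64, h)
        per_axis = 3 * 2 * h
        expected = per_axis * 256 * 2 - per_axis * per_axis
        assert int(mask.sum()) == expected

    def test_partitions_the_image(self):
        mask = make_grid_mask(256, 256, 64, 5)
        assert mask.sum() + (~mask).sum() == 256 * 256

    def test_excessive_half_width_rejected(self):
        with pytest.raises(ValueError, match="half_width"):
            make_grid_mask(256, 256, 64, 32)


class TestDice:
    def test_perfect_prediction(self, rng):
        labels = rng.integers(0, 3, (32, 32))
        table = dice_scores(labels, labels)
        assert table.loc["all", "micro"] == 1.0
        assert table.loc["all", "macro"] == 1.0

    def test_disjoint_masks_score_zero(self):
        pred = np.array([[1, 1], [1, 1]])
        truth = np.array([[0, 0], [0, 0]])
        table = dice_scores(pred, truth, n_classes=2)
        assert table.loc["all", "micro"] == 0.0
        assert table.loc["all", "macro"] == 0.0

    def test_hand_tallied_two_class_example(self):
        # truth [0,0,1,1] vs pred [0,1,0,1]: per class TP=1, FP=1, FN=1
        # micro = 2*2/(2*2+2+2) = 0.5; macro = mean(0.5, 0.5) = 0.5
        table = dice_scores(np.array([0, 1, 0, 1]), np.array([0, 0, 1, 1]))
        assert table.loc["all", "micro"] == pytest.approx(0.5)
        assert table.loc["all", "macro"] == pytest.approx(0.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_matches_confusion_matrix_oracle(self, seed):
        r = np.random.default_rng(seed)
        pred = r.integers(0, 3, (16, 16))
        truth = r.integers(0, 3, (16, 16))
        table = dice_scores(pred, truth, n_classes=3)
        micro, macro = dice_oracle(pred, truth, 3)
        assert table.loc["all", "micro"] == pytest.approx(micro)
        assert table.loc["all", "macro"] == pytest.approx(macro)

    def test_region_split_restricts_counts(self, rng):
        pred = rng.integers(0, 3, (64, 64))
        truth = rng.integers(0, 3, (64, 64))
        mask = make_grid_mask(64, 64, 32, 3)
        table = dice_scores(pred, truth, mask, n_classes=3)
        m_in, M_in = dice_oracle(pred[mask], truth[mask], 3)
        m_out, M_out = dice_oracle(pred[~mask], truth[~mask], 3)
        assert table.loc["edge_vicinity", "micro"] == pytest.approx(m_in)
        assert table.loc["centre", "macro"] == pytest.approx(M_out)

    def test_absent_class_policy(self):
        pred = np.array([0, 0, 1, 1])
        truth = np.array([0, 0, 1, 0])
        one = dice_scores(pred, truth, n_classes=3)  # class 2 absent everywhere
        skip = dice_scores(pred, truth, n_classes=3, absent="skip")
        d0, d1 = 4 / 5, 2 / 3
        assert one.loc["all", "macro"] == pytest.approx((d0 + d1 + 1.0) / 3)
        assert skip.loc["all", "macro"] == pytest.approx((d0 + d1) / 2)


class TestAdjustedScores:
    @pytest.fixture()
    def table(self):
        return pd.DataFrame(
            {
                "image_id": [0, 0, 0, 1, 1, 1],
                "method": ["no_overlap", "hann", "average"] * 2,
                "metric": ["ssim"] * 6,
                "region": ["all"] * 6,
                "raw": [0.93, 0.95, 0.90, 0.80, 0.86, 0.83],
            }
        )

    def test_baseline_is_zero_and_shift_is_exact(self, table):
        out = adjusted_scores(table)
        by = out.set_index(["image_id", "method"])["adjusted"]
        assert by.loc[(0, "no_overlap")] == 0.0
        assert by.loc[(1, "no_overlap")] == 0.0
        assert by.loc[(0, "hann")] == pytest.approx(0.02)
        assert by.loc[(1, "average")] == pytest.approx(0.03)

    def test_per_image_ordering_preserved(self, table):
        out = adjusted_scores(table)
        for _, sub in out.groupby("image_id"):
            assert np.array_equal(sub["raw"].rank(), sub["adjusted"].rank())

    def test_missing_baseline_rejected(self, table):
        with pytest.raises(ValueError, match="baseline"):
            adjusted_scores(table[table.method != "no_overlap"])


class TestPairedTTest:
    def test_hand_computed_example(self):
        # mean 1.25, sd 0.5, n=4 -> t = 1.25 / (0.5/2) = 5.0, df = 3
        res = paired_t_test([1.0, 1.0, 1.0, 2.0])
        assert res.statistic == pytest.approx(5.0)
        assert res.df == 3
        assert res.pvalue == pytest.approx(2 * stats.t.sf(5.0, 3))

    def test_df_convention(self, rng):
        assert paired_t_test(rng.normal(size=14)).df == 13

    def test_degenerate_inputs(self):
        assert paired_t_test(np.zeros(5)) == (0.0, 4, 1.0)
        t, df, p = paired_t_test(np.full(5, 0.2))
        assert math.isinf(t) and t > 0 and p == 0.0 and df == 4

    def test_order_invariance(self, rng):
        d = rng.normal(size=10)
        assert paired_t_test(d).pvalue == pytest.approx(paired_t_test(d[::-1]).pvalue)

    def test_too_few_differences_rejected(self):
        with pytest.raises(ValueError, match="two"):
            paired_t_test([0.1])


class TestExactSignTest:
    def test_all_positive_binomial_tail(self):
        assert exact_sign_test(np.ones(14)) == pytest.approx(2 * 0.5**14)

    def test_balanced_signs_cap_at_one(self):
        assert exact_sign_test([1] * 7 + [-1] * 7) == 1.0

    def test_ties_dropped(self):
        assert exact_sign_test([1.0, -1.0, 0.0]) == exact_sign_test([1.0, -1.0])

    def test_all_ties_undefined(self):
        with pytest.raises(ValueError, match="ties"):
            exact_sign_test(np.zeros(6))

    def test_order_invariance(self, rng):
        d = rng.normal(size=11)
        assert exact_sign_test(d) == exact_sign_test(d[::-1])


class TestRunBenchmark:
    def test_zero_noise_profile_collapses_all_methods(self):
        res = run_benchmark(
            2,
            height=192,
            width=192,
            patch=64,
            n_blobs=5,
            radius_range=(6.0, 12.0),
            profile=ArtefactProfile(0.0, 0.0),
            mask_half_width=3,
        )
        np.testing.assert_allclose(res.scores["adjusted"], 0.0, atol=1e-9)
        assert set(res.scores["method"]) == {
            "no_overlap", "average", "pyramidal", "hann", "bartlett_hann", "triangular"
        }

    def test_schema_and_test_matrices(self):
        res = run_benchmark(
            3,
            height=192,
            width=192,
            patch=64,
            n_blobs=5,
            radius_range=(6.0, 12.0),
            mask_half_width=3,
        )
        t = res.scores
        assert set(t.columns) == {"image_id", "method", "metric", "region", "raw", "adjusted"}
        assert set(t["metric"]) == {"ssim", "dice_micro", "dice_macro"}
        assert set(t.loc[t.metric == "ssim", "region"]) == {"all"}
        assert set(t.loc[t.metric != "ssim", "region"]) == {"centre", "edge_vicinity"}
        # 6 methods * (1 ssim + 2 metrics * 2 regions) rows per image
        assert len(t) == 3 * 6 * 5
        assert np.all(t.loc[t.method == "no_overlap", "adjusted"] == 0.0)
        assert set(res.test_matrices) == {
            "ssim:all",
            "dice_micro:centre",
            "dice_micro:edge_vicinity",
            "dice_macro:centre",
            "dice_macro:edge_vicinity",
        }
        mat = res.test_matrices["ssim:all"]
        assert mat.loc["hann", "no_overlap"] == mat.loc["no_overlap", "hann"]
        assert ((mat.fillna(1) >= 0) & (mat.fillna(0) <= 1)).all().all()
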