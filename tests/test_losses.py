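"""Loss algebra: hand-computed values, endpoint identities, gradients."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vesselseg.losses import (
    LossParams,
    NonDifferentiablePointWarning,
    PixelBatch,
    combined_cost,
    combined_cost_grad,
    cost_sensitive_ce,
    cost_sensitive_ce_grad,
    dice_loss,
    dice_loss_grad,
    gradient_check,
    hard_dice_coefficient,
)

EXACT = LossParams(dice_smooth=0.0)


class TestDiceLoss:
    def test_perfect_prediction_is_zero(self):
        y = np.array([1.0, 1, 0, 0, 1])
        assert dice_loss(PixelBatch(y, y.copy()), EXACT) == pytest.approx(0.0, abs=1e-12)

    def test_disjoint_supports_is_one(self):
        y = np.array([1.0, 1, 0, 0])
        p = np.array([0.0, 0, 1, 1])
        assert dice_loss(PixelBatch(y, p), EXACT) == pytest.approx(1.0, abs=1e-12)

    def test_half_overlap(self):
        # |A| = |B| = 10, overlap 5 -> 1 - 2*5/20 = 0.5
        y = np.zeros(30)
        y[:10] = 1
        p = np.zeros(30)
        p[5:15] = 1
        assert dice_loss(PixelBatch(y, p), EXACT) == pytest.approx(0.5, abs=1e-9)

    def test_range_and_empty_batch(self):
        with pytest.raises(ValueError):
            PixelBatch(np.array([]), np.array([]))

    @given(st.integers(0, 2**32 - 1))
    def test_bounded_in_unit_interval(self, seed):
        r = np.random.default_rng(seed)
        y = (r.uniform(size=40) < 0.3).astype(float)
        p = r.uniform(size=40)
        d = dice_loss(PixelBatch(y, p))
        assert 0.0 <= d <= 1.0

    def test_hard_dice_matches_soft_on_binary(self):
        r = np.random.default_rng(3)
        y = (r.uniform(size=50) < 0.4).astype(float)
        p = (r.uniform(size=50) < 0.4).astype(float)
        soft = dice_loss(PixelBatch(y, p), EXACT) if (p.sum() + y.sum()) else 0.0
        assert hard_dice_coefficient(p, y) == pytest.approx(1.0 - soft, abs=1e-12)


class TestCostSensitiveCE:
    def test_vessel_correct_side(self):
        b = PixelBatch(np.array([1.0]), np.array([0.9]))
        assert cost_sensitive_ce(b) == pytest.approx(-np.log(0.9), abs=1e-9)

    def test_vessel_misclassified_gets_sevenfold_weight(self):
        b = PixelBatch(np.array([1.0]), np.array([0.4]))
        assert cost_sensitive_ce(b) == pytest.approx(-7.0 * np.log(0.4), abs=1e-9)

    def test_background_never_penalty_weighted(self):
        b = PixelBatch(np.array([0.0]), np.array([0.1]))
        assert cost_sensitive_ce(b) == pytest.approx(-np.log(0.9), abs=1e-9)

    def test_replace_mode_uses_bare_penalty(self):
        b = PixelBatch(np.array([1.0]), np.array([0.4]))
        params = LossParams(penalty_mode="replace")
        assert cost_sensitive_ce(b, params) == pytest.approx(-6.0 * np.log(0.4), abs=1e-9)

    def test_out_of_range_prediction_rejected(self):
        with pytest.raises(ValueError):
            PixelBatch(np.array([1.0]), np.array([1.2]))

    @given(st.integers(0, 2**32 - 1))
    def test_dominates_plain_bce_when_indicator_fires(self, seed):
        r = np.random.default_rng(seed)
        y = (r.uniform(size=30) < 0.3).astype(float)
        p = r.uniform(0.01, 0.99, size=30)
        plain = LossParams(vessel_penalty=0.0)
        cs = cost_sensitive_ce(PixelBatch(y, p))
        bce = cost_sensitive_ce(PixelBatch(y, p), plain)
        if np.any((y == 1) & (p <= 0.5)):
            assert cs > bce
        else:
            assert cs == pytest.approx(bce, rel=1e-12)

    def test_monotone_in_p_for_vessel_pixels(self):
        # non-increasing on each side of the indicator kink
        for grid in (np.linspace(0.05, 0.45, 9), np.linspace(0.55, 0.95, 9)):
            vals = [cost_sensitive_ce(PixelBatch(np.array([1.0]), np.array([p])))
                    for p in grid]
            assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))


class TestCombinedCost:
    def test_alpha_one_is_dice(self):
        r = np.random.default_rng(0)
        y = (r.uniform(size=16) < 0.3).astype(float)
        p = r.uniform(size=16)
        b = PixelBatch(y, p)
        params = LossParams(alpha=1.0, lambda_l2=0.0)
        assert combined_cost(b, params) == dice_loss(b, params)

    def test_alpha_zero_is_ce(self):
        r = np.random.default_rng(1)
        y = (r.uniform(size=16) < 0.3).astype(float)
        p = r.uniform(size=16)
        b = PixelBatch(y, p)
        params = LossParams(alpha=0.0, lambda_l2=0.0)
        assert combined_cost(b, params) == cost_sensitive_ce(b, params)

    def test_l2_term_arithmetic(self):
        y = np.array([1.0, 0.0])
        p = np.array([0.8, 0.2])
        b = PixelBatch(y, p)
        params = LossParams(alpha=0.5, lambda_l2=0.1)
        expected = (0.5 * dice_loss(b, params) + 0.5 * cost_sensitive_ce(b, params)
                    + 0.5 * 0.1 * 4.0)
        assert combined_cost(b, params, weight_norm_sq=4.0) == pytest.approx(expected, abs=1e-12)

    def test_linear_in_alpha(self):
        r = np.random.default_rng(2)
        y = (r.uniform(size=20) < 0.3).astype(float)
        p = r.uniform(size=20)
        b = PixelBatch(y, p)
        vals = [combined_cost(b, LossParams(alpha=a, lambda_l2=0.0)) for a in (0.0, 0.5, 1.0)]
        assert vals[1] == pytest.approx(0.5 * (vals[0] + vals[2]), abs=1e-12)

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            LossParams(alpha=1.5)


class TestGradients:
    @pytest.mark.parametrize(
        "lossfn,gradfn",
        [
            (dice_loss, dice_loss_grad),
            (cost_sensitive_ce, cost_sensitive_ce_grad),
            (combined_cost, combined_cost_grad),
        ],
        ids=["dice", "ce", "combined"],
    )
    def test_matches_finite_differences(self, lossfn, gradfn):
        r = np.random.default_rng(7)
        y = (r.uniform(size=30) < 0.3).astype(float)
        # interior points away from the indicator kink and the [0,1] edges
        p = np.where(r.uniform(size=30) < 0.5,
                     r.uniform(0.05, 0.45, size=30),
                     r.uniform(0.55, 0.95, size=30))
        err = gradient_check(lossfn, gradfn, PixelBatch(y, p))
        assert err < 1e-4

    def test_kink_is_flagged(self):
        b = PixelBatch(np.array([1.0]), np.array([0.5]))
        with pytest.warns(NonDifferentiablePointWarning):
            gradient_check(cost_sensitive_ce, cost_sensitive_ce_grad, b)

    def test_multi_sample_normalization(self):
        # two images; gradient of the per-image-then-mean reduction
        r = np.random.default_rng(9)
        y = (r.uniform(size=(2, 12)) < 0.3).astype(float)
        p = r.uniform(0.55, 0.95, size=(2, 12))
        err = gradient_check(combined_cost, combined_cost_grad, PixelBatch(y, p))
        assert err < 1e-4
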