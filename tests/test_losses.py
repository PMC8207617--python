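"""Effective-number weighting and base losses."""

import numpy as np
import pytest

from microloc.losses import (
    EffectiveNumberModel,
    bce_base_loss,
    effective_number,
    eloss,
    eloss_weights,
    focal_base_loss,
)
from microloc.pipeline import ClassCountTable


def effective_number_recurrence(n: int, alpha: float) -> float:
    """Independent oracle: iterate Q_n = ((V-1)/V) Q_{n-1} + 1 with
    V = 1/(1-alpha), starting from Q_1 = 1."""
    q = 1.0
    for _ in range(n - 1):
        q = alpha * q + 1.0
    return q


class TestEffectiveNumber:
    @pytest.mark.parametrize("alpha", [0.0, 0.5, 0.9, 0.99])
    def test_single_sample_counts_as_one(self, alpha):
        assert effective_number(1, alpha) == 1.0

    def test_alpha_one_limit_is_n(self):
        assert effective_number(2, 1.0) == 2.0
        assert effective_number(1000, 1.0) == 1000.0

    def test_one_recurrence_step(self):
        # V = 10: Q_2 = (9/10) * 1 + 1 = 1.9
        assert np.isclose(effective_number(2, 0.9), 1.9)

    @pytest.mark.parametrize("alpha", [0.0, 0.5, 0.9, 0.99, 0.999])
    def test_closed_form_matches_recurrence(self, alpha):
        for n in [1, 2, 3, 10, 100, 1000]:
            assert np.isclose(
                effective_number(n, alpha),
                effective_number_recurrence(n, alpha),
                rtol=1e-10,
            )

    def test_monotone_in_n_and_bounded_by_volume(self):
        alpha = 0.95
        volume = 1 / (1 - alpha)
        q = effective_number(np.arange(1, 200), alpha)
        assert (np.diff(q) > 0).all()
        assert (q <= np.minimum(np.arange(1, 200), volume)).all()

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            effective_number(0, 0.5)
        with pytest.raises(ValueError):
            effective_number(5, 1.5)

    def test_model_volume(self):
        model = EffectiveNumberModel.from_counts(ClassCountTable(np.array([3, 7])), 0.9)
        assert np.isclose(model.volume, 10.0)
        assert np.isclose(model.Q[0], effective_number_recurrence(3, 0.9))


class TestELossWeights:
    def test_alpha_zero_uniform(self):
        w = eloss_weights(ClassCountTable(np.array([5, 5, 5])), 0.0)
        assert np.allclose(w.weights, 1.0)

    def test_alpha_one_inverse_frequency(self):
        w = eloss_weights(ClassCountTable(np.array([10, 1000])), 1.0, normalize=False)
        assert np.allclose(w.weights, [0.1, 0.001])

    def test_two_count_weight(self):
        w = eloss_weights(ClassCountTable(np.array([2])), 0.9, normalize=False)
        assert np.isclose(w.weights[0], 1 / 1.9)

    def test_weight_of_singleton_class_is_one(self):
        w = eloss_weights(ClassCountTable(np.array([1, 50])), 0.99, normalize=False)
        assert np.isclose(w.weights[0], 1.0)
        assert w.weights[1] < w.weights[0]

    def test_normalization_preserves_scale(self):
        counts = ClassCountTable(np.array([500, 50, 5, 1]))
        for alpha in (0.0, 0.9, 0.999):
            w = eloss_weights(counts, alpha, normalize=True)
            assert np.isclose(w.weights.sum(), 4.0)

    def test_interpolates_from_uniform_to_inverse_frequency(self):
        """Relative weight of the rarest class grows monotonically in
        alpha, from equal share to the inverse-frequency share."""
        counts = ClassCountTable(np.array([1000, 10]))
        shares = []
        for alpha in [0.0, 0.5, 0.9, 0.99, 0.999, 1.0]:
            w = eloss_weights(counts, alpha, normalize=False).weights
            shares.append(w[1] / w.sum())
        assert (np.diff(shares) >= 0).all()
        assert np.isclose(shares[0], 0.5)
        assert np.isclose(shares[-1], (1 / 10) / (1 / 10 + 1 / 1000))

    def test_zero_count_class_warns_and_gets_zero_weight(self):
        with pytest.warns(UserWarning, match="zero samples"):
            w = eloss_weights(ClassCountTable(np.array([5, 0])), 0.9)
        assert w.weights[1] == 0.0

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            eloss_weights(ClassCountTable(np.array([5])), 1.2)


class TestELoss:
    def test_unit_weights_give_plain_sum(self, rng):
        losses = rng.random(6)
        w = eloss_weights(ClassCountTable(np.full(6, 9)), 0.0)
        assert np.isclose(eloss(losses, w), losses.sum())

    def test_weighted_sum_arithmetic(self):
        w = eloss_weights(ClassCountTable(np.array([2, 4])), 0.5, normalize=False)
        # weights: (1-0.5)/(1-0.25)=2/3 and (1-0.5)/(1-0.0625)=8/15
        assert np.isclose(eloss(np.array([1.0, 1.0]), w), 2 / 3 + 8 / 15)

    def test_alpha_zero_equals_plain_bce_total(self, rng):
        probs = rng.uniform(0.05, 0.95, size=(16, 4))
        targets = (rng.random((16, 4)) < 0.3).astype(float)
        per_class = bce_base_loss(probs, targets).mean(axis=0)
        w = eloss_weights(ClassCountTable(np.array([40, 30, 20, 10])), 0.0)
        assert np.isclose(eloss(per_class, w), per_class.sum())

    def test_dimension_mismatch_rejected(self):
        w = eloss_weights(ClassCountTable(np.array([2, 4])), 0.5)
        with pytest.raises(ValueError):
            eloss(np.ones(3), w)

    def test_rare_class_gradient_share_grows_with_alpha(self):
        """Two-class toy: the rare class's share of the total gradient
        magnitude strictly increases with alpha."""
        counts = ClassCountTable(np.array([500, 5]))
        probs = np.array([[0.6, 0.4]])
        targets = np.array([[1.0, 1.0]])
        grad = probs - targets  # d BCE / d logit
        shares = []
        for alpha in [0.0, 0.9, 0.99, 0.999]:
            w = eloss_weights(counts, alpha, normalize=True).weights
            g = np.abs(w * grad[0])
            shares.append(g[1] / g.sum())
        assert (np.diff(shares) > 0).all()


class TestBaseLosses:
    def test_focal_gamma_zero_is_bce(self, rng):
        probs = rng.uniform(0.05, 0.95, size=(8, 3))
        targets = (rng.random((8, 3)) < 0.5).astype(float)
        assert np.allclose(
            focal_base_loss(probs, targets, gamma=0.0), bce_base_loss(probs, targets)
        )

    def test_focal_confident_correct_vanishes(self):
        loss = focal_base_loss(np.array([1 - 1e-7]), np.array([1.0]), gamma=2.0)
        assert loss[0] < 1e-6

    def test_focal_hand_value(self):
        # p_t = 0.5, gamma = 2 -> 0.25 * (-ln 0.5)
        loss = focal_base_loss(np.array([0.5]), np.array([1.0]), gamma=2.0)
        assert np.isclose(loss[0], 0.25 * -np.log(0.5))

    def test_out_of_range_probabilities_rejected(self):
        with pytest.raises(ValueError):
            focal_base_loss(np.array([1.2]), np.array([1.0]), gamma=1.0)
        with pytest.raises(ValueError):
            focal_base_loss(np.array([0.5]), np.array([1.0]), gamma=-1.0)
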