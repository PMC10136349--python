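"""Loss-suite tests: frozen hand-computed values, reduction identities,
order invariants, and finite-difference validation of every analytic
gradient."""

import math

import numpy as np
import pytest
from sklearn.metrics import log_loss

from triagekit import (
    CompositeParams,
    FocalParams,
    TverskyParams,
    class_balanced_focal,
    composite,
    cross_entropy,
    focal,
    focal_tversky,
    loss_gradient,
    tversky,
)
from triagekit.losses import LOSS_IDS, loss_value

from conftest import random_prob_batch

RNG = np.random.default_rng(20251)


def batches(n):
    return [random_prob_batch(RNG) for _ in range(n)]


class TestCrossEntropy:
    def test_half_probability_is_ln2(self):
        p = np.array([[0.5, 0.5]])
        y = np.array([[1.0, 0.0]])
        assert cross_entropy(p, y) == pytest.approx(math.log(2.0), rel=1e-12)

    def test_certain_prediction_is_zero_up_to_clip(self):
        p = np.array([[1.0, 0.0]])
        y = np.array([[1.0, 0.0]])
        assert cross_entropy(p, y) == pytest.approx(0.0, abs=1e-10)

    def test_two_row_hand_value(self):
        p = np.array([[0.9, 0.1], [0.4, 0.6]])
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        # (−ln 0.9 − ln 0.6)/2, frozen from a high-precision computation
        assert cross_entropy(p, y) == pytest.approx(0.30809306971190849, rel=1e-12)

    def test_agrees_with_sklearn_log_loss(self):
        for p, y in batches(20):
            labels = y.argmax(axis=1)
            expected = log_loss(labels, p, labels=list(range(p.shape[1])))
            assert cross_entropy(p, y) == pytest.approx(expected, rel=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cross_entropy(np.ones((2, 3)) / 3, np.eye(2))


class TestFocal:
    def test_gamma_zero_alpha_one_reduces_to_ce(self):
        for p, y in batches(25):
            assert focal(p, y, FocalParams(alpha=1.0, gamma=0.0)) == pytest.approx(
                cross_entropy(p, y), rel=1e-12
            )

    def test_single_row_hand_value(self):
        p = np.array([[0.9, 0.1]])
        y = np.array([[1.0, 0.0]])
        # 0.01 * (−ln 0.9), frozen from a high-precision computation
        assert focal(p, y, FocalParams(1.0, 2.0)) == pytest.approx(
            1.0536051565782630e-3, rel=1e-12
        )

    def test_vanishes_as_confidence_approaches_one(self):
        y = np.array([[1.0, 0.0]])
        vals = [focal(np.array([[1 - e, e]]), y) for e in (1e-2, 1e-4, 1e-6)]
        assert vals[0] > vals[1] > vals[2]
        assert vals[2] < 1e-11

    def test_pointwise_below_cross_entropy(self):
        for p, y in batches(25):
            assert focal(p, y, FocalParams(1.0, 2.0)) <= cross_entropy(p, y) + 1e-12


class TestClassBalancedFocal:
    def test_beta_zero_reduces_to_focal(self):
        for p, y in batches(25):
            counts = np.arange(1, p.shape[1] + 1) * 3
            assert class_balanced_focal(p, y, counts, beta_cb=0.0) == pytest.approx(
                focal(p, y), rel=1e-12
            )

    def test_equal_counts_reduce_to_focal(self):
        for p, y in batches(25):
            counts = np.full(p.shape[1], 7)
            assert class_balanced_focal(p, y, counts, beta_cb=0.9) == pytest.approx(
                focal(p, y), rel=1e-12
            )

    def test_hand_computed_raw_weights(self):
        # counts (9, 1), beta 0.9: raw weights (0.1/(1−0.9^9), 1.0)
        from triagekit.losses import _cb_weights

        w = _cb_weights(np.array([9, 1]), 0.9)
        raw = np.array([0.16324411477092318, 1.0])
        np.testing.assert_allclose(w, raw / raw.mean(), rtol=1e-12)

    def test_nonpositive_counts_rejected(self):
        p, y = np.array([[0.6, 0.4]]), np.array([[1.0, 0.0]])
        with pytest.raises(ValueError):
            class_balanced_focal(p, y, np.array([3, 0]), beta_cb=0.5)


class TestFocalTversky:
    def test_gamma_one_is_plain_tversky(self):
        for p, y in batches(25):
            params = TverskyParams(gamma=1.0)
            assert focal_tversky(p, y, params) == pytest.approx(
                tversky(p, y, params), rel=1e-12
            )

    def test_perfect_one_hot_probs_give_zero(self):
        y = np.eye(3)[[0, 1, 1]]
        assert focal_tversky(y.copy(), y) == pytest.approx(0.0, abs=1e-3)
        # the absent-class index smooths to 1, contributing nothing

    def test_worked_two_by_two_batch(self):
        p = np.array([[0.8, 0.2], [0.4, 0.6]])
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        # TI = (0.8/1.14, 0.6/0.86) up to epsilon smoothing; value frozen
        # from a high-precision rational computation with eps = 1e-6
        assert focal_tversky(p, y) == pytest.approx(0.81129474219068138, rel=1e-10)

    def test_nonnegative(self):
        for p, y in batches(25):
            assert focal_tversky(p, y) >= 0.0
            assert tversky(p, y) >= 0.0


class TestComposite:
    def test_lambda_one_is_focal(self):
        for p, y in batches(10):
            params = CompositeParams(lam=1.0)
            assert composite(p, y, params) == pytest.approx(
                focal(p, y, params.focal), rel=1e-12
            )

    def test_lambda_zero_is_focal_tversky(self):
        for p, y in batches(10):
            params = CompositeParams(lam=0.0)
            assert composite(p, y, params) == pytest.approx(
                focal_tversky(p, y, params.tversky), rel=1e-12
            )

    def test_default_mix_is_convex_combination(self):
        for p, y in batches(10):
            params = CompositeParams()  # lambda = 0.7
            expected = 0.7 * focal(p, y, params.focal) + 0.3 * focal_tversky(
                p, y, params.tversky
            )
            assert composite(p, y, params) == pytest.approx(expected, rel=1e-12)

    def test_between_components(self):
        for p, y in batches(25):
            for lam in (0.0, 0.3, 0.7, 1.0):
                params = CompositeParams(lam=lam)
                f = focal(p, y, params.focal)
                t = focal_tversky(p, y, params.tversky)
                c = composite(p, y, params)
                assert min(f, t) - 1e-12 <= c <= max(f, t) + 1e-12

    def test_lambda_domain(self):
        with pytest.raises(ValueError):
            CompositeParams(lam=1.5)


# --------------------------------------------------------------------------
# analytic gradients vs central finite differences
# --------------------------------------------------------------------------

def fd_gradient(loss_id, probs, targets, h=1e-5, **kw):
    grad = np.zeros_like(probs)
    for i in range(probs.shape[0]):
        for c in range(probs.shape[1]):
            up, down = probs.copy(), probs.copy()
            up[i, c] += h
            down[i, c] -= h
            grad[i, c] = (
                loss_value(loss_id, up, targets, **kw)
                - loss_value(loss_id, down, targets, **kw)
            ) / (2 * h)
    return grad


@pytest.mark.parametrize("loss_id", LOSS_IDS)
def test_gradients_match_finite_differences(loss_id):
    """Every analytic gradient agrees with the central-difference oracle on
    >= 100 random small batches (1e-6 relative tolerance)."""
    rng = np.random.default_rng(917)
    for _ in range(100):
        p, y = random_prob_batch(rng)
        kw = {}
        if loss_id == "cb_focal":
            kw = {"class_counts": rng.integers(1, 50, size=p.shape[1]),
                  "beta_cb": 0.99}
        analytic = loss_gradient(loss_id, p, y, **kw)
        numeric = fd_gradient(loss_id, p, y, **kw)
        np.testing.assert_allclose(analytic, numeric, rtol=1e-6, atol=1e-8)


def test_ce_gradient_closed_form():
    p = np.array([[0.7, 0.3], [0.2, 0.8]])
    y = np.array([[1.0, 0.0], [0.0, 1.0]])
    g = loss_gradient("ce", p, y)
    np.testing.assert_allclose(
        g, [[-1 / (2 * 0.7), 0.0], [0.0, -1 / (2 * 0.8)]], rtol=1e-12
    )


def test_focal_gradient_zero_at_certainty():
    p = np.array([[1.0, 0.0]])
    y = np.array([[1.0, 0.0]])
    g = loss_gradient("focal", p, y, FocalParams(1.0, 2.0))
    assert abs(g[0, 0]) < 1e-9


def test_unknown_loss_id_rejected():
    p, y = np.array([[0.6, 0.4]]), np.array([[1.0, 0.0]])
    with pytest.raises(ValueError):
        loss_gradient("hinge", p, y)
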