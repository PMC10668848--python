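"""Margin-softmax and reciprocal-point losses: closed forms, gradients,
hinge semantics and distance geometry."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from hypothesis.extra import numpy as hnp

from openherd.heads import (
    AMSoftmaxHead,
    ReciprocalPointSet,
    am_softmax_loss,
    amc_loss,
    arpl_class_probabilities,
    arpl_distance,
    combined_loss,
    combined_loss_grad,
    rp_ce_loss,
)
from conftest import finite_difference

EYE2 = np.array([[1.0, 0.0], [0.0, 1.0]])


def random_instance(seed, n=6, dim=5, n_classes=4):
    rng = np.random.default_rng(seed)
    features = rng.normal(size=(n, dim))
    labels = rng.integers(0, n_classes, n)
    head = AMSoftmaxHead.init(dim, n_classes, seed=seed)
    points = ReciprocalPointSet.init(dim, n_classes, seed=seed, init_sd=0.5, r_init=0.1)
    return features, labels, head, points


class TestAMSoftmax:
    @pytest.mark.parametrize("s,m,expected", [
        (1.0, 0.0, 0.31326168751822286),   # -log(e/(e+1)): plain softmax CE
        (1.0, 0.5, 0.47407698418010663),   # margin shifts the correct logit
        (10.0, 0.5, 0.006715348489118068),  # protocol scale/margin
    ])
    def test_two_class_closed_form(self, s, m, expected):
        head = AMSoftmaxHead(W=EYE2, s=s, m=m)
        loss = am_softmax_loss(np.array([[1.0, 0.0]]), [0], head)
        assert loss == pytest.approx(expected, abs=1e-9)

    def test_margin_zero_reduces_to_cross_entropy(self):
        # Eq. reduction: m=0 equals softmax CE on s-scaled cosine logits
        from scipy.special import log_softmax
        for seed in range(5):
            f, y, head, _ = random_instance(seed)
            head.m = 0.0
            fn = f / np.linalg.norm(f, axis=1, keepdims=True)
            Wn = head.W / np.linalg.norm(head.W, axis=0, keepdims=True)
            logits = head.s * fn @ Wn
            expected = -log_softmax(logits, axis=1)[np.arange(len(y)), y].mean()
            assert am_softmax_loss(f, y, head) == pytest.approx(expected, abs=1e-6)

    def test_loss_nondecreasing_in_margin(self):
        for seed in range(5):
            f, y, head, _ = random_instance(seed)
            losses = []
            for m in (0.0, 0.2, 0.5, 0.8):
                head.m = m
                losses.append(am_softmax_loss(f, y, head))
            assert np.all(np.diff(losses) >= -1e-12)

    def test_label_out_of_range(self):
        head = AMSoftmaxHead(W=EYE2)
        with pytest.raises(ValueError):
            am_softmax_loss(np.array([[1.0, 0.0]]), [2], head)
        with pytest.raises(ValueError):
            am_softmax_loss(np.zeros((0, 2)), [], head)


class TestDistance:
    def test_feature_at_point(self):
        pts = ReciprocalPointSet(P=np.array([[1.0, 2.0]]), R=np.zeros(1))
        d = arpl_distance(np.array([[1.0, 2.0]]), pts)
        assert d[0, 0] == pytest.approx(-(1.0 + 4.0))  # d_e = 0, score = -f.P

    def test_zero_feature(self):
        P = np.array([[1.0, 2.0], [3.0, -1.0]])
        pts = ReciprocalPointSet(P=P, R=np.zeros(2))
        d = arpl_distance(np.zeros((1, 2)), pts)
        np.testing.assert_allclose(d[0], np.sum(P**2, axis=1) / 2)

    def test_matches_scalar_loop(self):
        rng = np.random.default_rng(8)
        f = rng.normal(size=(4, 2))
        P = rng.normal(size=(3, 2))
        pts = ReciprocalPointSet(P=P, R=np.zeros(3))
        got = arpl_distance(f, pts)
        for i in range(4):
            for k in range(3):
                d_e = sum((f[i, j] - P[k, j]) ** 2 for j in range(2)) / 2
                dot = sum(f[i, j] * P[k, j] for j in range(2))
                assert got[i, k] == pytest.approx(d_e - dot, abs=1e-12)

    def test_dimension_mismatch(self):
        pts = ReciprocalPointSet(P=np.zeros((2, 3)), R=np.zeros(2))
        with pytest.raises(ValueError):
            arpl_distance(np.zeros((1, 4)), pts)


class TestDistanceSoftmax:
    def test_uniform_when_equal(self):
        p = arpl_class_probabilities(np.zeros((2, 5)), gamma=2.0)
        np.testing.assert_allclose(p, 1 / 5)

    def test_saturates_at_large_gap(self):
        p = arpl_class_probabilities(np.array([[100.0, 0.0]]), gamma=1.0)
        assert p[0, 0] > 1 - 1e-10

    def test_two_class_closed_form(self):
        p = arpl_class_probabilities(np.array([[1.0, 0.0]]), gamma=1.0)
        np.testing.assert_allclose(p[0], [np.e / (np.e + 1), 1 / (np.e + 1)], atol=1e-12)

    @given(hnp.arrays(np.float64, (3, 4), elements=st.floats(-50, 50)),
           st.floats(0.1, 10.0))
    def test_rows_normalise_and_argmax_preserved(self, d, gamma):
        p = arpl_class_probabilities(d, gamma)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(p >= 0)
        # the top-distance class receives the top probability (softmax is
        # monotone; exact argmax indices can differ only through float ties)
        rows = np.arange(len(d))
        assert np.all(p[rows, d.argmax(axis=1)] == p.max(axis=1))

    def test_gamma_must_be_positive(self):
        with pytest.raises(ValueError):
            arpl_class_probabilities(np.zeros((1, 2)), gamma=0.0)


class TestAMCHinge:
    def _points_1d(self, P, R):
        return ReciprocalPointSet(P=np.array([[float(P)]]), R=np.array([float(R)]))

    def test_inside_margin_inactive(self):
        pts = self._points_1d(0.0, 1.0)
        assert amc_loss(np.array([[np.sqrt(0.5)]]), [0], pts) == 0.0

    def test_outside_margin(self):
        pts = self._points_1d(0.0, 1.0)
        assert amc_loss(np.array([[np.sqrt(1.5)]]), [0], pts) == pytest.approx(0.5)

    def test_batch_mean_of_per_sample_hinges(self):
        pts = self._points_1d(0.0, 1.0)
        f = np.array([[np.sqrt(2.0)], [np.sqrt(0.5)]])  # d_e = 2.0 and 0.5
        assert amc_loss(f, [0, 0], pts) == pytest.approx(0.5)  # mean(1, 0)

    def test_zero_iff_all_within_margin(self):
        for seed in range(5):
            f, y, _, pts = random_instance(seed)
            diff = f - pts.P[y]
            d_e = np.sum(diff**2, axis=1) / pts.embed_dim
            loss = amc_loss(f, y, pts)
            assert (loss == 0.0) == bool(np.all(d_e <= pts.R[y]))

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            ReciprocalPointSet(P=np.zeros((1, 2)), R=np.array([-0.1]))


class TestCombined:
    def test_zero_weight_reduces_to_am(self):
        f, y, head, pts = random_instance(0)
        bd = combined_loss(f, y, head, pts, lambda_amc=0.0)
        assert bd.total == pytest.approx(am_softmax_loss(f, y, head), abs=1e-12)

    def test_inactive_hinge_contributes_nothing(self):
        f, y, head, pts = random_instance(1)
        pts.R[:] = 1e6  # every sample inside its margin
        bd = combined_loss(f, y, head, pts, lambda_amc=1.0)
        assert bd.amc_loss == 0.0
        assert bd.total == pytest.approx(bd.am_loss, abs=1e-12)

    def test_recomposition(self):
        for seed in range(5):
            f, y, head, pts = random_instance(seed)
            bd = combined_loss(f, y, head, pts, lambda_amc=0.37, lambda_rp_ce=0.7)
            expected = (am_softmax_loss(f, y, head) + 0.37 * amc_loss(f, y, pts)
                        + 0.7 * rp_ce_loss(f, y, pts))
            assert bd.total == pytest.approx(expected, abs=1e-6)

    def test_negative_weights_rejected(self):
        f, y, head, pts = random_instance(2)
        with pytest.raises(ValueError):
            combined_loss(f, y, head, pts, lambda_amc=-0.1)


class TestGradients:
    """Analytic gradients of the joint loss against central finite differences."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("lambdas", [(0.0, 0.0), (0.5, 0.0), (0.3, 0.8)])
    def test_all_parameter_gradients(self, seed, lambdas):
        lam_amc, lam_rp = lambdas
        f, y, head, pts = random_instance(seed)
        _, dfeat = combined_loss_grad(f, y, head, pts, lam_amc, lam_rp)

        def total():
            return combined_loss(f, y, head, pts, lam_amc, lam_rp).total

        checks = [("features", f, dfeat), ("W", head.W, head.grads["W"])]
        if lam_amc or lam_rp:
            checks += [("P", pts.P, pts.grads["P"]), ("R", pts.R, pts.grads["R"])]
        for name, arr, analytic in checks:
            numeric = finite_difference(total, arr, eps=1e-6)
            np.testing.assert_allclose(analytic, numeric, atol=1e-4,
                                       err_msg=f"{name} gradient mismatch")
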