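"""Open-set heads and losses: additive-margin softmax plus reciprocal points.

Two heads share one feature extractor:

* **AM-Softmax head** — softmax cross-entropy on cosine logits between the
  unit-normalised feature and unit-normalised class weight columns, scaled by
  ``s`` and with an additive margin ``m`` subtracted from the correct-class
  cosine.  The margin tightens each known class (intra-class compactness)
  while pushing classes apart (inter-class separability), which frees
  embedding space for unknown individuals.

* **Reciprocal-point head** — one learnable point per known class in an
  "extra-class" region of feature space, with a learnable per-class margin
  ``R``.  The adversarial margin-constraint (AMC) hinge
  ``max(d_e(f, P_k) - R_k, 0)`` bounds how far a class's features may drift
  from its reciprocal point, limiting open-space risk.  The combined distance
  ``d(f, P_k) = d_e(f, P_k) - f . P_k`` (dimension-averaged squared Euclidean
  distance minus dot product) drives unknown scoring: known samples end up
  far from reciprocal points, unknowns do not.

The joint training objective is ``L_AM + lambda_amc * L_AMC`` plus, by
default during training, a cross-entropy over the distance softmax
(``lambda_rp_ce``) — the discriminative signal that positions the
reciprocal points.  All losses come with analytic gradients (checked
against finite differences in the test suite) so they can train the numpy
backbone end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AMSoftmaxHead",
    "ReciprocalPointSet",
    "LossBreakdown",
    "am_softmax_loss",
    "am_softmax_logits",
    "arpl_distance",
    "arpl_class_probabilities",
    "amc_loss",
    "combined_loss",
    "combined_loss_grad",
]

_NORM_EPS = 1e-12


@dataclass
class AMSoftmaxHead:
    """Additive-margin softmax classification head.

    W : (embed_dim, C) weight matrix, one column per known class.
    s : logit scale; m : additive margin on the correct-class cosine.
    Both the feature vectors and the weight columns are unit-normalised
    before the cosine is taken, so pre-margin logits lie in [-s, s].
    """

    W: np.ndarray
    s: float = 10.0
    m: float = 0.5
    grads: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2:
            raise ValueError("W must be a (embed_dim, C) matrix")
        if self.s <= 0:
            raise ValueError("scale s must be positive")
        if self.m < 0:
            raise ValueError("margin m must be nonnegative")

    @property
    def n_classes(self) -> int:
        return self.W.shape[1]

    @property
    def embed_dim(self) -> int:
        return self.W.shape[0]

    @classmethod
    def init(cls, embed_dim: int, n_classes: int, s: float = 10.0, m: float = 0.5,
             seed: int = 0) -> "AMSoftmaxHead":
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA1]))
        W = rng.normal(0.0, np.sqrt(1.0 / embed_dim), (embed_dim, n_classes))
        return cls(W=W, s=s, m=m)


@dataclass
class ReciprocalPointSet:
    """Per-known-class reciprocal points with learnable margins.

    P : (K, embed_dim), one point per known class.
    R : (K,) nonnegative learnable margins (clamped at zero after updates).
    gamma : temperature of the softmax over distances.
    """

    P: np.ndarray
    R: np.ndarray
    gamma: float = 1.0
    grads: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.R = np.asarray(self.R, dtype=float)
        if self.P.ndim != 2 or self.R.shape != (self.P.shape[0],):
            raise ValueError("P must be (K, embed_dim) with one margin R per point")
        if np.any(self.R < 0):
            raise ValueError("margins R must be nonnegative")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")

    @property
    def n_classes(self) -> int:
        return self.P.shape[0]

    @property
    def embed_dim(self) -> int:
        return self.P.shape[1]

    @classmethod
    def init(cls, embed_dim: int, n_classes: int, gamma: float = 1.0, seed: int = 0,
             init_sd: float = 0.1, r_init: float = 0.0) -> "ReciprocalPointSet":
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA2]))
        P = rng.normal(0.0, init_sd, (n_classes, embed_dim))
        return cls(P=P, R=np.full(n_classes, float(r_init)), gamma=gamma)

    def clamp(self) -> None:
        """Project margins back to the feasible set (R >= 0); call after updates."""
        np.maximum(self.R, 0.0, out=self.R)


@dataclass(frozen=True)
class LossBreakdown:
    """Components of the joint objective.

    ``total = am + lambda_amc * amc + lambda_rp_ce * rp_ce``; the optional
    reciprocal-point cross-entropy term (softmax over ``gamma * d``) is the
    discriminative signal that positions the reciprocal points — with
    ``lambda_rp_ce = 0`` the objective reduces to AM-Softmax plus the AMC
    hinge alone.
    """

    am_loss: float
    amc_loss: float
    lambda_amc: float
    rp_ce_loss: float = 0.0
    lambda_rp_ce: float = 0.0

    @property
    def total(self) -> float:
        return (self.am_loss + self.lambda_amc * self.amc_loss
                + self.lambda_rp_ce * self.rp_ce_loss)


def _normalize(x: np.ndarray, axis: int) -> tuple[np.ndarray, np.ndarray]:
    norm = np.sqrt(np.sum(x * x, axis=axis, keepdims=True))
    if np.any(norm < _NORM_EPS):
        warnings.warn("unit-normalising a (near-)zero vector; it maps to zero", stacklevel=3)
    safe = np.maximum(norm, _NORM_EPS)
    return x / safe, safe


def _normalize_backward(dxn: np.ndarray, xn: np.ndarray, safe_norm: np.ndarray,
                        axis: int) -> np.ndarray:
    inner = np.sum(dxn * xn, axis=axis, keepdims=True)
    return (dxn - xn * inner) / safe_norm


def _check_labels(labels: np.ndarray, n_classes: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("batch must be nonempty")
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValueError(f"labels must lie in [0, {n_classes}), got range "
                         f"[{labels.min()}, {labels.max()}]")
    return labels.astype(int)


def am_softmax_logits(features: np.ndarray, head: AMSoftmaxHead,
                      apply_margin_to: np.ndarray | None = None) -> np.ndarray:
    """Scaled cosine logits ``s * (cos - m 1[c = label])`` for a batch."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != head.embed_dim:
        raise ValueError(f"feature dim {features.shape[1]} != head dim {head.embed_dim}")
    fn, _ = _normalize(features, axis=1)
    Wn, _ = _normalize(head.W, axis=0)
    cos = fn @ Wn
    if apply_margin_to is not None:
        cos = cos.copy()
        cos[np.arange(len(cos)), apply_margin_to] -= head.m
    return head.s * cos


def _am_forward_backward(features: np.ndarray, labels: np.ndarray, head: AMSoftmaxHead,
                         want_grad: bool):
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = _check_labels(labels, head.n_classes)
    if features.shape[0] != labels.shape[0]:
        raise ValueError("features and labels disagree on batch size")
    if features.shape[1] != head.embed_dim:
        raise ValueError(f"feature dim {features.shape[1]} != head dim {head.embed_dim}")

    fn, fnorm = _normalize(features, axis=1)
    Wn, wnorm = _normalize(head.W, axis=0)
    cos = fn @ Wn
    n = features.shape[0]
    rows = np.arange(n)
    logits = head.s * cos
    logits[rows, labels] -= head.s * head.m

    shifted = logits - logits.max(axis=1, keepdims=True)
    logz = np.log(np.sum(np.exp(shifted), axis=1)) + logits.max(axis=1)
    loss = float(np.mean(logz - logits[rows, labels]))
    if not want_grad:
        return loss, None, None

    p = np.exp(logits - logz[:, None])
    dlogits = p
    dlogits[rows, labels] -= 1.0
    dlogits /= n
    dcos = head.s * dlogits
    dfn = dcos @ Wn.T
    dWn = fn.T @ dcos
    dfeat = _normalize_backward(dfn, fn, fnorm, axis=1)
    dW = _normalize_backward(dWn, Wn, wnorm, axis=0)
    return loss, dfeat, dW


def am_softmax_loss(features: np.ndarray, labels: np.ndarray, head: AMSoftmaxHead) -> float:
    """Batch-mean additive-margin softmax loss.

    With ``m = 0`` this reduces exactly to softmax cross-entropy on the
    ``s``-scaled cosine logits; the margin is subtracted only from the
    correct-class cosine.
    """
    loss, _, _ = _am_forward_backward(features, labels, head, want_grad=False)
    return loss


def arpl_distance(features: np.ndarray, points: ReciprocalPointSet) -> np.ndarray:
    """Combined feature-to-reciprocal-point distances, ``(n, K)``.

    ``d(f, P_k) = d_e(f, P_k) - f . P_k`` with ``d_e`` the squared Euclidean
    distance divided by the embedding dimension.  Larger values mean the
    feature sits farther into known-class territory.
    """
    features = np.atleast_2d(np.asarray(features, dtype=float))
    if features.shape[1] != points.embed_dim:
        raise ValueError(
            f"feature dim {features.shape[1]} != reciprocal-point dim {points.embed_dim}")
    dot = features @ points.P.T
    sq = (np.sum(features**2, axis=1)[:, None] + np.sum(points.P**2, axis=1)[None, :]
          - 2.0 * dot)
    return sq / points.embed_dim - dot


def arpl_class_probabilities(distances: np.ndarray, gamma: float) -> np.ndarray:
    """Softmax over ``gamma * d``: class assignment follows maximum distance."""
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    z = gamma * np.atleast_2d(np.asarray(distances, dtype=float))
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _amc_forward_backward(features: np.ndarray, labels: np.ndarray,
                          points: ReciprocalPointSet, want_grad: bool):
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = _check_labels(labels, points.n_classes)
    if features.shape[1] != points.embed_dim:
        raise ValueError(
            f"feature dim {features.shape[1]} != reciprocal-point dim {points.embed_dim}")
    n = features.shape[0]
    diff = features - points.P[labels]
    d_e = np.sum(diff * diff, axis=1) / points.embed_dim
    slack = d_e - points.R[labels]
    active = slack > 0
    loss = float(np.mean(np.maximum(slack, 0.0)))
    if not want_grad:
        return loss, None, None, None

    coef = (2.0 / (points.embed_dim * n)) * active.astype(float)
    dfeat = coef[:, None] * diff
    dP = np.zeros_like(points.P)
    np.add.at(dP, labels, -dfeat)
    dR = np.zeros_like(points.R)
    np.add.at(dR, labels, -active.astype(float) / n)
    return loss, dfeat, dP, dR


def amc_loss(features: np.ndarray, labels: np.ndarray, points: ReciprocalPointSet) -> float:
    """Adversarial margin-constraint hinge, batch mean of
    ``max(d_e(f, P_k) - R_k, 0)`` with ``k`` each sample's own class."""
    loss, _, _, _ = _amc_forward_backward(features, labels, points, want_grad=False)
    return loss


def _rp_ce_forward_backward(features: np.ndarray, labels: np.ndarray,
                            points: ReciprocalPointSet, want_grad: bool):
    """Cross-entropy over the distance softmax (class = maximum distance)."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    labels = _check_labels(labels, points.n_classes)
    n, dim = features.shape
    d = arpl_distance(features, points)
    z = points.gamma * d
    shifted = z - z.max(axis=1, keepdims=True)
    logz = np.log(np.sum(np.exp(shifted), axis=1)) + z.max(axis=1)
    rows = np.arange(n)
    loss = float(np.mean(logz - z[rows, labels]))
    if not want_grad:
        return loss, None, None

    q = np.exp(z - logz[:, None])
    dz = q
    dz[rows, labels] -= 1.0
    dz *= points.gamma / n
    # d(f, P_k) = (||f||^2 + ||P_k||^2 - 2 f.P_k)/dim - f.P_k
    coef = 2.0 / dim
    row_sums = dz.sum(axis=1, keepdims=True)
    dfeat = coef * (features * row_sums - dz @ points.P) - dz @ points.P
    dP = coef * (points.P * dz.sum(axis=0)[:, None] - dz.T @ features) - dz.T @ features
    return loss, dfeat, dP


def rp_ce_loss(features: np.ndarray, labels: np.ndarray, points: ReciprocalPointSet) -> float:
    """Batch-mean cross-entropy of :func:`arpl_class_probabilities` against
    each sample's own class."""
    loss, _, _ = _rp_ce_forward_backward(features, labels, points, want_grad=False)
    return loss


def combined_loss(features: np.ndarray, labels: np.ndarray, head: AMSoftmaxHead,
                  points: ReciprocalPointSet, lambda_amc: float,
                  lambda_rp_ce: float = 0.0) -> LossBreakdown:
    """Joint objective ``L_AM + lambda_amc * L_AMC (+ lambda_rp_ce * L_RP)``."""
    if lambda_amc < 0 or lambda_rp_ce < 0:
        raise ValueError("loss weights must be nonnegative")
    return LossBreakdown(
        am_loss=am_softmax_loss(features, labels, head),
        amc_loss=amc_loss(features, labels, points),
        lambda_amc=lambda_amc,
        rp_ce_loss=rp_ce_loss(features, labels, points) if lambda_rp_ce > 0 else 0.0,
        lambda_rp_ce=lambda_rp_ce,
    )


def combined_loss_grad(features: np.ndarray, labels: np.ndarray, head: AMSoftmaxHead,
                       points: ReciprocalPointSet, lambda_amc: float,
                       lambda_rp_ce: float = 0.0) -> tuple[LossBreakdown, np.ndarray]:
    """Joint loss plus gradients.

    Returns ``(breakdown, dfeatures)`` and deposits parameter gradients in
    ``head.grads['W']``, ``points.grads['P']`` and ``points.grads['R']``.
    """
    if lambda_amc < 0 or lambda_rp_ce < 0:
        raise ValueError("loss weights must be nonnegative")
    am, dfeat_am, dW = _am_forward_backward(features, labels, head, want_grad=True)
    amc, dfeat_amc, dP, dR = _amc_forward_backward(features, labels, points, want_grad=True)
    head.grads["W"] = dW
    points.grads["P"] = lambda_amc * dP
    points.grads["R"] = lambda_amc * dR
    dfeat = dfeat_am + lambda_amc * dfeat_amc
    rp = 0.0
    if lambda_rp_ce > 0:
        rp, dfeat_rp, dP_rp = _rp_ce_forward_backward(features, labels, points,
                                                      want_grad=True)
        dfeat = dfeat + lambda_rp_ce * dfeat_rp
        points.grads["P"] = points.grads["P"] + lambda_rp_ce * dP_rp
    return LossBreakdown(am_loss=am, amc_loss=amc, lambda_amc=lambda_amc,
                         rp_ce_loss=rp, lambda_rp_ce=lambda_rp_ce), dfeat
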