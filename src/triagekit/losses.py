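"""Cost-sensitive loss suite on predicted-probability batches.

All losses take an N x C matrix of predicted class probabilities (rows
sum to 1) and an N x C one-hot target matrix, and return a scalar:

* ``cross_entropy``      — mean over rows of −log p(true class).
* ``focal``              — cross-entropy down-weighted per row by
  α(1 − p)^γ, so confidently-correct rows contribute little and training
  concentrates on the hard ones.
* ``class_balanced_focal`` — focal with a per-class "effective number"
  weight (1 − β)/(1 − β^{n_c}) on the true class, normalised to mean 1.
* ``tversky`` / ``focal_tversky`` — per class c, the Tversky index over
  the batch, TI_c = TP_c / (TP_c + α·FP_c + β·FN_c) in soft counts, with
  α weighting false positives and β false negatives; the loss is
  Σ_c (1 − TI_c)^{1/γ} (γ = 1 recovers plain Tversky).
* ``composite``          — λ·focal + (1 − λ)·focal-Tversky, the
  cost-sensitive objective used for imbalanced triage corpora (λ = 0.7).

``loss_gradient`` returns the analytic ∂L/∂p for every loss, for the
reference trainer to compose with the softmax Jacobian; each gradient is
validated against central finite differences in the test suite.

Conventions: natural logarithms; probabilities clipped to
[EPS_P, 1 − EPS_P] before any log; cross-entropy-family losses are means
over rows, Tversky-family losses are sums over classes of batch-level
indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FocalParams",
    "TverskyParams",
    "CompositeParams",
    "cross_entropy",
    "focal",
    "class_balanced_focal",
    "tversky",
    "focal_tversky",
    "composite",
    "loss_gradient",
    "LOSS_IDS",
]

#: Probability clip applied before logarithms.
EPS_P = 1e-12

LOSS_IDS = ("ce", "focal", "cb_focal", "tversky", "ftl", "composite")


@dataclass(frozen=True)
class FocalParams:
    """Focal-loss parameters: weighting factor α and focusing exponent γ."""

    alpha: float = 1.0
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.gamma < 0:
            raise ValueError("alpha and gamma must be >= 0")


@dataclass(frozen=True)
class TverskyParams:
    """Tversky-index parameters.

    ``alpha`` weights false positives, ``beta`` false negatives (defaults
    0.7/0.3: penalise missed members of a class harder than spurious
    ones); ``gamma`` is the focal exponent applied as (1 − TI)^{1/γ}
    (default 4/3); ``epsilon`` smooths empty classes to TI = 1.
    """

    alpha: float = 0.7
    beta: float = 0.3
    gamma: float = 4.0 / 3.0
    epsilon: float = 1e-6

    def __post_init__(self) -> None:
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass(frozen=True)
class CompositeParams:
    """Mix weight λ plus the two component parameter sets (λ = 0.7 default)."""

    lam: float = 0.7
    focal: FocalParams = field(default_factory=FocalParams)
    tversky: TverskyParams = field(default_factory=TverskyParams)

    def __post_init__(self) -> None:
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lambda must be in [0, 1]")


# --------------------------------------------------------------------------
# validation helpers
# --------------------------------------------------------------------------

def _check_batch(probs: np.ndarray, targets: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    probs = np.asarray(probs, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    if probs.ndim != 2 or probs.shape != targets.shape:
        raise ValueError(f"shape mismatch: probs {probs.shape}, targets {targets.shape}")
    if probs.shape[0] == 0:
        raise ValueError("empty batch")
    if not np.allclose(targets.sum(axis=1), 1.0) or not np.isin(targets, (0.0, 1.0)).all():
        raise ValueError("targets must be one-hot")
    return probs, targets


def _clip(probs: np.ndarray) -> np.ndarray:
    return np.clip(probs, EPS_P, 1.0 - EPS_P)


# --------------------------------------------------------------------------
# cross-entropy family (row means)
# --------------------------------------------------------------------------

def cross_entropy(probs: np.ndarray, targets: np.ndarray) -> float:
    """Mean over rows of −Σ_c y·log p (natural log)."""
    probs, targets = _check_batch(probs, targets)
    p = _clip(probs)
    return float(-(targets * np.log(p)).sum(axis=1).mean())


def focal(
    probs: np.ndarray, targets: np.ndarray, params: FocalParams = FocalParams()
) -> float:
    """Mean over rows of −Σ_c y·α(1 − p)^γ·log p.

    With γ = 0 and α = 1 this is exactly cross-entropy; as the true-class
    probability approaches 1 the row's contribution vanishes like
    (1 − p)^γ.
    """
    probs, targets = _check_batch(probs, targets)
    p = _clip(probs)
    term = params.alpha * (1.0 - p) ** params.gamma * (-np.log(p))
    return float((targets * term).sum(axis=1).mean())


def _cb_weights(class_counts: np.ndarray, beta_cb: float) -> np.ndarray:
    """Effective-number class weights, normalised to mean 1."""
    n = np.asarray(class_counts, dtype=np.float64)
    if (n <= 0).any():
        raise ValueError("class counts must be positive")
    if not 0.0 <= beta_cb < 1.0:
        raise ValueError("beta_cb must be in [0, 1)")
    if beta_cb == 0.0:
        raw = np.ones_like(n)
    else:
        raw = (1.0 - beta_cb) / (1.0 - beta_cb ** n)
    return raw / raw.mean()


def class_balanced_focal(
    probs: np.ndarray,
    targets: np.ndarray,
    class_counts: np.ndarray,
    beta_cb: float = 0.999,
    params: FocalParams = FocalParams(),
) -> float:
    """Focal loss with an effective-number weight on each row's true class.

    Rare classes (small n_c) receive weight near 1/(mean), abundant ones
    near (1 − β)·n_c-independent small values; β = 0 recovers plain focal.
    """
    probs, targets = _check_batch(probs, targets)
    w = _cb_weights(class_counts, beta_cb)
    if w.shape[0] != probs.shape[1]:
        raise ValueError("class_counts length must equal the class count")
    p = _clip(probs)
    term = params.alpha * (1.0 - p) ** params.gamma * (-np.log(p))
    row_w = targets @ w  # weight of each row's true class
    return float((row_w * (targets * term).sum(axis=1)).mean())


# --------------------------------------------------------------------------
# Tversky family (sum over classes of batch-level indices)
# --------------------------------------------------------------------------

def _tversky_index(
    probs: np.ndarray, targets: np.ndarray, params: TverskyParams
) -> np.ndarray:
    """Per-class soft Tversky index over the batch.

    With g the one-hot membership, the soft counts are TP_c = Σ_i p·g,
    FP_c = Σ_i p·(1 − g), FN_c = Σ_i (1 − p)·g; TI_c = (TP_c + ε) /
    (TP_c + α·FP_c + β·FN_c + ε).  A class absent from the batch has
    TP = FN = 0 and TI = ε/(α·FP + ε); with hard-correct probabilities it
    smooths to exactly 1.
    """
    tp = (probs * targets).sum(axis=0)
    fp = (probs * (1.0 - targets)).sum(axis=0)
    fn = ((1.0 - probs) * targets).sum(axis=0)
    eps = params.epsilon
    return (tp + eps) / (tp + params.alpha * fp + params.beta * fn + eps)


def focal_tversky(
    probs: np.ndarray, targets: np.ndarray, params: TverskyParams = TverskyParams()
) -> float:
    """Σ_c (1 − TI_c)^{1/γ}; γ = 1 gives the plain Tversky loss."""
    probs, targets = _check_batch(probs, targets)
    ti = _tversky_index(probs, targets, params)
    return float(((1.0 - ti) ** (1.0 / params.gamma)).sum())


def tversky(
    probs: np.ndarray, targets: np.ndarray, params: TverskyParams = TverskyParams()
) -> float:
    """Plain Tversky loss Σ_c (1 − TI_c) (the γ = 1 focal-Tversky)."""
    probs, targets = _check_batch(probs, targets)
    ti = _tversky_index(probs, targets, params)
    return float((1.0 - ti).sum())


def composite(
    probs: np.ndarray, targets: np.ndarray, params: CompositeParams = CompositeParams()
) -> float:
    """λ·focal + (1 − λ)·focal-Tversky."""
    return params.lam * focal(probs, targets, params.focal) + (
        1.0 - params.lam
    ) * focal_tversky(probs, targets, params.tversky)


# --------------------------------------------------------------------------
# analytic gradients w.r.t. probabilities
# --------------------------------------------------------------------------

def _grad_ce(probs: np.ndarray, targets: np.ndarray) -> np.ndarray:
    n = probs.shape[0]
    p = _clip(probs)
    return -targets / (n * p)


def _grad_focal(
    probs: np.ndarray, targets: np.ndarray, params: FocalParams
) -> np.ndarray:
    # d/dp [ -α(1-p)^γ log p ] = α γ (1-p)^(γ-1) log p − α (1-p)^γ / p
    n = probs.shape[0]
    p = _clip(probs)
    one_m = 1.0 - p
    if params.gamma == 0.0:
        d = -params.alpha / p
    else:
        d = (
            params.alpha * params.gamma * one_m ** (params.gamma - 1.0) * np.log(p)
            - params.alpha * one_m ** params.gamma / p
        )
    return targets * d / n


def _grad_cb_focal(
    probs: np.ndarray,
    targets: np.ndarray,
    class_counts: np.ndarray,
    beta_cb: float,
    params: FocalParams,
) -> np.ndarray:
    w = _cb_weights(class_counts, beta_cb)
    row_w = (targets @ w)[:, None]
    return row_w * _grad_focal(probs, targets, params)


def _grad_focal_tversky(
    probs: np.ndarray, targets: np.ndarray, params: TverskyParams, gamma: float | None = None
) -> np.ndarray:
    gamma = params.gamma if gamma is None else gamma
    eps = params.epsilon
    tp = (probs * targets).sum(axis=0)
    fp = (probs * (1.0 - targets)).sum(axis=0)
    fn = ((1.0 - probs) * targets).sum(axis=0)
    num = tp + eps
    den = tp + params.alpha * fp + params.beta * fn + eps
    ti = num / den
    # dTI_c/dp_ic: numerator derivative g, denominator derivative
    # g(1 − β) + α(1 − g)
    g = targets
    dnum = g
    dden = g * (1.0 - params.beta) + params.alpha * (1.0 - g)
    dti = (dnum * den - num[None, :] * dden) / den[None, :] ** 2
    # dL/dTI_c = −(1/γ)(1 − TI_c)^{1/γ − 1}
    one_m_ti = np.maximum(1.0 - ti, EPS_P)
    dl_dti = -(1.0 / gamma) * one_m_ti ** (1.0 / gamma - 1.0)
    return dl_dti[None, :] * dti


def loss_gradient(
    loss_id: str,
    probs: np.ndarray,
    targets: np.ndarray,
    params: object | None = None,
    class_counts: np.ndarray | None = None,
    beta_cb: float = 0.999,
) -> np.ndarray:
    """Analytic ∂L/∂p for any loss in :data:`LOSS_IDS`.

    The trainer composes this with the softmax Jacobian to get gradients
    w.r.t. logits.  ``params`` defaults per loss; ``class_counts`` and
    ``beta_cb`` apply only to ``cb_focal``.
    """
    probs, targets = _check_batch(probs, targets)
    if loss_id == "ce":
        return _grad_ce(probs, targets)
    if loss_id == "focal":
        return _grad_focal(probs, targets, params or FocalParams())
    if loss_id == "cb_focal":
        if class_counts is None:
            raise ValueError("cb_focal needs class_counts")
        return _grad_cb_focal(probs, targets, class_counts, beta_cb, params or FocalParams())
    if loss_id == "tversky":
        p = params or TverskyParams()
        return _grad_focal_tversky(probs, targets, p, gamma=1.0)
    if loss_id == "ftl":
        return _grad_focal_tversky(probs, targets, params or TverskyParams())
    if loss_id == "composite":
        cp = params or CompositeParams()
        return cp.lam * _grad_focal(probs, targets, cp.focal) + (
            1.0 - cp.lam
        ) * _grad_focal_tversky(probs, targets, cp.tversky)
    raise ValueError(f"unknown loss_id {loss_id!r}; expected one of {LOSS_IDS}")


def loss_value(
    loss_id: str,
    probs: np.ndarray,
    targets: np.ndarray,
    params: object | None = None,
    class_counts: np.ndarray | None = None,
    beta_cb: float = 0.999,
) -> float:
    """Dispatch to the loss named by ``loss_id`` (mirror of :func:`loss_gradient`)."""
    if loss_id == "ce":
        return cross_entropy(probs, targets)
    if loss_id == "focal":
        return focal(probs, targets, params or FocalParams())
    if loss_id == "cb_focal":
        if class_counts is None:
            raise ValueError("cb_focal needs class_counts")
        return class_balanced_focal(probs, targets, class_counts, beta_cb, params or FocalParams())
    if loss_id == "tversky":
        return tversky(probs, targets, params or TverskyParams())
    if loss_id == "ftl":
        return focal_tversky(probs, targets, params or TverskyParams())
    if loss_id == "composite":
        return composite(probs, targets, params or CompositeParams())
    raise ValueError(f"unknown loss_id {loss_id!r}; expected one of {LOSS_IDS}")
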