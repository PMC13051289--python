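"""Composite imbalance-aware training objective.

The objective combines four terms, all operating on per-example logit
vectors z in R^6:

* **Class-balanced focal loss with label-distribution-aware margins.**
  Classes are reweighted by the class-balanced estimator
  w_c proportional to (1 - beta) / (1 - beta^{n_c}) (normalised to mean 1
  across classes), a class-dependent margin m_c = C0 * n_c^{-1/4} is
  subtracted from the true-class logit, and focal cross-entropy
  -w_y (1 - p_y)^gamma log p_y is taken on the margin-shifted softmax.
* **R-Drop consistency.** The symmetric KL divergence between the softmax
  distributions of two stochastic (dropout-perturbed) forward passes of the
  same input.
* **Targeted pairwise margin penalty.** For bipolar-labelled examples only,
  hinge terms pushing the bipolar logit at least delta above the
  no-depression and atypical logits — the two classes it is most confused
  with.
* **Total.** L = 1/2 (focal^(1) + focal^(2)) + lambda_rd * RDrop
  + lambda_pair * Pair, averaged over the batch.

Class counts for weights and margins come from the training split only, so
no frequency information leaks from validation or test.  Analytic gradients
with respect to the logits are provided for the numpy trainer and are
checked against central finite differences in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import N_CLASSES, SubtypeLabel

__all__ = [
    "LossConfig",
    "ClassStats",
    "DualPassLogits",
    "class_balanced_weights",
    "ldam_margins",
    "softmax",
    "focal_ldam_loss",
    "rdrop_loss",
    "pairwise_margin_penalty",
    "total_loss",
    "total_loss_and_grads",
]


@dataclass
class LossConfig:
    """Hyperparameters of the composite objective (defaults are the published benchmark's)."""

    beta: float = 0.999
    gamma: float = 2.0
    c0: float = 0.5
    delta: float = 0.15
    lambda_rdrop: float = 0.5
    lambda_pair: float = 0.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta < 1.0:
            raise ValueError(f"beta must be in [0, 1), got {self.beta}")
        if self.gamma < 0 or self.c0 <= 0 or self.delta < 0:
            raise ValueError("gamma >= 0, c0 > 0 and delta >= 0 required")
        if self.lambda_rdrop < 0 or self.lambda_pair < 0:
            raise ValueError("loss weights must be non-negative")

    def to_dict(self) -> dict:
        return {
            "beta": self.beta,
            "gamma": self.gamma,
            "c0": self.c0,
            "delta": self.delta,
            "lambda_rdrop": self.lambda_rdrop,
            "lambda_pair": self.lambda_pair,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LossConfig":
        return cls(**d)


def class_balanced_weights(counts: Sequence[int], beta: float = 0.999) -> np.ndarray:
    """Class-balanced weights w_c = raw_c / mean_j raw_j with
    raw_c = (1 - beta) / (1 - beta^{n_c}).

    beta^{n_c} is evaluated as exp(n_c log beta) so counts in the thousands
    do not underflow.  The returned weights have mean exactly 1; beta -> 0
    collapses them all to 1.
    """
    n = np.asarray(counts, dtype=float)
    if np.any(n < 1):
        raise ValueError(f"all class counts must be >= 1, got {list(counts)}")
    if not 0.0 <= beta < 1.0:
        raise ValueError(f"beta must be in [0, 1), got {beta}")
    if beta == 0.0:
        raw = np.ones_like(n)
    else:
        raw = (1.0 - beta) / (1.0 - np.exp(n * np.log(beta)))
    return raw / raw.mean()


def ldam_margins(counts: Sequence[int], c0: float = 0.5) -> np.ndarray:
    """Label-distribution-aware margins m_c = c0 * n_c^{-1/4}: rarer classes
    get larger margins."""
    n = np.asarray(counts, dtype=float)
    if np.any(n < 1):
        raise ValueError(f"all class counts must be >= 1, got {list(counts)}")
    return c0 * n ** (-0.25)


@dataclass
class ClassStats:
    """Per-class counts with their derived weights and margins."""

    counts: np.ndarray
    weights: np.ndarray
    margins: np.ndarray

    @classmethod
    def from_counts(
        cls, counts: Sequence[int], config: LossConfig | None = None
    ) -> "ClassStats":
        config = config or LossConfig()
        counts = np.asarray(counts, dtype=int)
        return cls(
            counts=counts,
            weights=class_balanced_weights(counts, config.beta),
            margins=ldam_margins(counts, config.c0),
        )


@dataclass
class DualPassLogits:
    """Two stochastic forward-pass logit vectors for one labelled example."""

    z1: np.ndarray
    z2: np.ndarray
    label: SubtypeLabel

    def __post_init__(self) -> None:
        self.z1 = np.asarray(self.z1, dtype=float)
        self.z2 = np.asarray(self.z2, dtype=float)
        for z in (self.z1, self.z2):
            if z.shape != (N_CLASSES,) or not np.all(np.isfinite(z)):
                raise ValueError("logit vectors must be finite with length 6")


def softmax(z: np.ndarray) -> np.ndarray:
    """Numerically stable softmax."""
    z = np.asarray(z, dtype=float)
    e = np.exp(z - np.max(z))
    return e / e.sum()


def _log_softmax(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    m = np.max(z)
    return z - m - np.log(np.sum(np.exp(z - m)))


def focal_ldam_loss(
    logits: np.ndarray,
    label: SubtypeLabel,
    stats: ClassStats,
    config: LossConfig,
) -> float:
    """Class-balanced focal cross-entropy on margin-shifted logits."""
    loss, _ = _focal_ldam_with_grad(np.asarray(logits, float), label, stats, config)
    return loss


def _focal_ldam_with_grad(
    z: np.ndarray, label: SubtypeLabel, stats: ClassStats, config: LossConfig
) -> tuple[float, np.ndarray]:
    y = label.index
    z_shift = z.astype(float).copy()
    z_shift[y] -= stats.margins[y]
    log_p = _log_softmax(z_shift)
    s = np.exp(log_p)
    p_y = s[y]
    w = stats.weights[y]
    one_minus = max(1.0 - p_y, 0.0)
    loss = w * one_minus ** config.gamma * (-log_p[y])

    # dL/dp_y, then chain through the softmax Jacobian row for class y
    g = config.gamma
    if g == 0.0:
        dl_dp = -w / max(p_y, 1e-300)
    else:
        dl_dp = w * (
            -g * one_minus ** (g - 1.0) * (-log_p[y]) - one_minus ** g / max(p_y, 1e-300)
        )
    # dp_y/dz_k = p_y (delta_ky - s_k); margin shift has unit Jacobian
    grad = dl_dp * p_y * (np.eye(N_CLASSES)[y] - s)
    return float(loss), grad


def rdrop_loss(p1: np.ndarray, p2: np.ndarray) -> float:
    """Symmetric KL divergence 1/2 [KL(p1||p2) + KL(p2||p1)] between two
    predictive distributions; probabilities are clipped below at 1e-12."""
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    for name, p in (("p1", p1), ("p2", p2)):
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"{name} is not a probability vector (sum={p.sum()})")
    q1 = np.clip(p1, 1e-12, None)
    q2 = np.clip(p2, 1e-12, None)
    kl12 = float(np.sum(q1 * (np.log(q1) - np.log(q2))))
    kl21 = float(np.sum(q2 * (np.log(q2) - np.log(q1))))
    return 0.5 * (kl12 + kl21)


def _rdrop_grads(z1: np.ndarray, z2: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """Symmetric KL of softmax(z1), softmax(z2) and its gradients wrt z1, z2."""
    p = softmax(z1)
    q = softmax(z2)
    loss = rdrop_loss(p, q)
    cp = np.clip(p, 1e-12, None)
    cq = np.clip(q, 1e-12, None)
    log_ratio = np.log(cp) - np.log(cq)
    # d/dp_i of 1/2[KL(p||q)+KL(q||p)] = 1/2[log(p_i/q_i) + 1 - q_i/p_i]
    dl_dp = 0.5 * (log_ratio + 1.0 - cq / cp)
    dl_dq = 0.5 * (-log_ratio + 1.0 - cp / cq)
    jac_p = np.diag(p) - np.outer(p, p)
    jac_q = np.diag(q) - np.outer(q, q)
    return loss, jac_p @ dl_dp, jac_q @ dl_dq


def pairwise_margin_penalty(
    logits: np.ndarray, label: SubtypeLabel, delta: float = 0.15
) -> float:
    """Hinge penalty pushing the bipolar logit above no-depression and
    atypical by at least delta; zero for non-bipolar labels."""
    loss, _ = _pairwise_with_grad(np.asarray(logits, float), label, delta)
    return loss


def _pairwise_with_grad(
    z: np.ndarray, label: SubtypeLabel, delta: float
) -> tuple[float, np.ndarray]:
    grad = np.zeros(N_CLASSES)
    if label is not SubtypeLabel.BIPOLAR:
        return 0.0, grad
    b = SubtypeLabel.BIPOLAR.index
    loss = 0.0
    for other in (SubtypeLabel.NO_DEPRESSION, SubtypeLabel.ATYPICAL):
        o = other.index
        hinge = delta - (z[b] - z[o])
        if hinge > 0:
            loss += hinge
            grad[b] -= 1.0
            grad[o] += 1.0
    return float(loss), grad


def total_loss(
    batch: Sequence[DualPassLogits], stats: ClassStats, config: LossConfig
) -> float:
    """Mean over the batch of the composite per-example loss."""
    loss, _, _ = total_loss_and_grads(batch, stats, config)
    return loss


def total_loss_and_grads(
    batch: Sequence[DualPassLogits], stats: ClassStats, config: LossConfig
) -> tuple[float, np.ndarray, np.ndarray]:
    """Composite loss and its gradients with respect to both logit passes.

    Returns (loss, dL/dz1, dL/dz2) where the gradient arrays have shape
    (batch, 6) and include the 1/batch factor of the mean reduction.  The
    pairwise penalty is averaged over the two stochastic passes, mirroring
    the focal term's treatment.
    """
    if len(batch) == 0:
        raise ValueError("total_loss requires a non-empty batch")
    n = len(batch)
    g1 = np.zeros((n, N_CLASSES))
    g2 = np.zeros((n, N_CLASSES))
    total = 0.0
    for i, ex in enumerate(batch):
        f1, df1 = _focal_ldam_with_grad(ex.z1, ex.label, stats, config)
        f2, df2 = _focal_ldam_with_grad(ex.z2, ex.label, stats, config)
        rd, drd1, drd2 = _rdrop_grads(ex.z1, ex.z2)
        pp1, dpp1 = _pairwise_with_grad(ex.z1, ex.label, config.delta)
        pp2, dpp2 = _pairwise_with_grad(ex.z2, ex.label, config.delta)
        total += (
            0.5 * (f1 + f2)
            + config.lambda_rdrop * rd
            + config.lambda_pair * 0.5 * (pp1 + pp2)
        )
        g1[i] = 0.5 * df1 + config.lambda_rdrop * drd1 + config.lambda_pair * 0.5 * dpp1
        g2[i] = 0.5 * df2 + config.lambda_rdrop * drd2 + config.lambda_pair * 0.5 * dpp2
    return total / n, g1 / n, g2 / n
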