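"""Objective components: cross-stain triplet contrastive loss (plain and
virtual-sample variants), InfoNCE alternative, pseudo-label construction
with sharpening, MixUp virtual samples, and the combined training loss.

Differentiable pieces operate on :class:`classm.nn.Tensor`; plain numpy
arrays are accepted and the result is returned as numpy in that case.
Label vectors (true, pseudo, mixed) are always treated as constants — no
gradient flows through label construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .nn import Tensor, l2_distance, softmax
from .stainsep import ChannelPair

__all__ = [
    "LabelDistribution",
    "VirtualSample",
    "LossWeights",
    "triplet_contrastive",
    "infonce_contrastive",
    "sharpen",
    "pseudo_label",
    "mixup_pair",
    "mixup_batch",
    "contrastive_negatives",
    "total_loss",
    "cross_entropy",
]

#: Floor inside log to keep cross-entropy finite.
PROB_FLOOR = 1e-8


@dataclass(frozen=True)
class LabelDistribution:
    """A probability vector over classes with its provenance."""

    probs: np.ndarray
    provenance: str = "true"  # one of {"true", "pseudo", "mixed"}

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1:
            raise ValueError("label distribution must be a vector")
        if np.any(p < -1e-9) or abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"not a probability vector: {p}")
        if self.provenance not in ("true", "pseudo", "mixed"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        object.__setattr__(self, "probs", p)

    @classmethod
    def one_hot(cls, index: int, n_classes: int) -> "LabelDistribution":
        p = np.zeros(n_classes)
        p[index] = 1.0
        return cls(p, "true")


@dataclass(frozen=True)
class VirtualSample:
    """A MixUp virtual sample: mixed channel pair, mixed label, mixing weight."""

    h_image: np.ndarray
    e_image: np.ndarray
    label: LabelDistribution
    lambda_prime: float
    is_labeled: bool

    def __post_init__(self) -> None:
        if not 0.5 <= self.lambda_prime <= 1.0:
            raise ValueError("lambda_prime must lie in [0.5, 1]")


@dataclass(frozen=True)
class LossWeights:
    """Loss hyperparameters (full-scale defaults)."""

    lambda_u: float = 7.5
    lambda_c: float = 0.1
    margin: float = 37.0
    temperature: float = 0.5
    beta_alpha: float = 2.0
    k_augment: int = 2

    def __post_init__(self) -> None:
        if min(self.lambda_u, self.lambda_c, self.margin,
               self.beta_alpha) < 0:
            raise ValueError("loss weights must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.k_augment < 1:
            raise ValueError("K must be >= 1")


# ---------------------------------------------------------------------------
# Contrastive losses
# ---------------------------------------------------------------------------


def _maybe_numpy(result: Tensor, was_numpy: bool):
    if not was_numpy:
        return result
    data = result.data
    return float(data) if data.ndim == 0 else data


def triplet_contrastive(f_h_i, f_e_i, f_e_k, margin: float):
    """Per-sample triplet loss between H/E features:

    ``max(||f_H_i - f_E_i|| - ||f_H_i - f_E_k|| + m, 0)``

    with plain (unsquared) L2 norms.  Accepts single vectors or co-indexed
    batches; Tensors keep the autodiff graph, numpy inputs return numpy.
    """
    was_numpy = not isinstance(f_h_i, Tensor)
    f_h_i = Tensor.as_tensor(f_h_i)
    f_e_i = Tensor.as_tensor(f_e_i)
    f_e_k = Tensor.as_tensor(f_e_k)
    if not (f_h_i.shape == f_e_i.shape == f_e_k.shape):
        raise ValueError("feature shapes must match")
    axis = f_h_i.ndim - 1
    d_pos = l2_distance(f_h_i, f_e_i, axis=axis)
    d_neg = l2_distance(f_h_i, f_e_k, axis=axis)
    return _maybe_numpy((d_pos - d_neg + margin).relu(), was_numpy)


def infonce_contrastive(f_h, f_e, temperature: float):
    """Symmetric InfoNCE over cosine-similarity logits.

    The diagonal (same-sample H/E pair) is the positive; the loss is the
    mean of the H->E and E->H cross-entropies.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    was_numpy = not isinstance(f_h, Tensor)
    f_h = Tensor.as_tensor(f_h)
    f_e = Tensor.as_tensor(f_e)
    n = f_h.shape[0]
    if n < 2:
        raise ValueError("InfoNCE needs batch size >= 2 for negatives")

    def _normalize(f: Tensor) -> Tensor:
        norm = ((f * f).sum(axis=1, keepdims=True) + 1e-12).sqrt()
        return f / norm

    h = _normalize(f_h)
    e = _normalize(f_e)
    logits = (h @ e.transpose()) * (1.0 / temperature)  # (N, N)
    eye = np.eye(n)

    def _direction(lg: Tensor) -> Tensor:
        p = softmax(lg, axis=1)
        return -((p + PROB_FLOOR).log() * eye).sum(axis=1).mean()

    loss = (_direction(logits) + _direction(logits.transpose())) * 0.5
    return _maybe_numpy(loss, was_numpy)


# ---------------------------------------------------------------------------
# Pseudo-labels and MixUp
# ---------------------------------------------------------------------------


def sharpen(y: LabelDistribution | np.ndarray, temperature: float):
    """Raise class probabilities to 1/T and renormalize (entropy reduction)."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    probs = y.probs if isinstance(y, LabelDistribution) else np.asarray(y, float)
    powered = np.power(probs, 1.0 / temperature)
    sharpened = powered / powered.sum()
    if isinstance(y, LabelDistribution):
        return LabelDistribution(sharpened, y.provenance)
    return sharpened


def pseudo_label(model, sample, k: int, temperature: float,
                 augment_fn: Callable[[object, np.random.Generator], ChannelPair],
                 rng: np.random.Generator) -> LabelDistribution:
    """Average model predictions over K augmented views, then sharpen.

    ``augment_fn(sample, rng)`` must run the full configured pipeline (RGB
    jitter -> separation -> channel augmentation) and return a
    :class:`ChannelPair`.  No gradients flow through this construction.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    h_stack, e_stack = [], []
    for _ in range(k):
        pair = augment_fn(sample, rng)
        h_stack.append(pair.h_image)
        e_stack.append(pair.e_image)
    h = np.stack(h_stack)[:, None, :, :]
    e = np.stack(e_stack)[:, None, :, :]
    probs = model.forward(h, e).probs.data  # (K, C), detached
    mean = probs.mean(axis=0)
    return LabelDistribution(sharpen(mean, temperature), "pseudo")


def mixup_pair(x_i: ChannelPair, y_i: LabelDistribution,
               x_j: ChannelPair, y_j: LabelDistribution,
               alpha: float, rng: np.random.Generator,
               is_labeled: bool = True) -> VirtualSample:
    """Mix two samples on their separated channels: lambda' = max(lam, 1-lam).

    The virtual sample stays closer to its first parent and inherits its
    labeled/unlabeled membership.
    """
    if x_i.h_image.shape != x_j.h_image.shape:
        raise ValueError("channel shapes must match for MixUp")
    lam = float(rng.beta(alpha, alpha))
    lam_p = max(lam, 1.0 - lam)
    mixed_label = lam_p * y_i.probs + (1.0 - lam_p) * y_j.probs
    return VirtualSample(
        h_image=lam_p * x_i.h_image + (1.0 - lam_p) * x_j.h_image,
        e_image=lam_p * x_i.e_image + (1.0 - lam_p) * x_j.e_image,
        label=LabelDistribution(mixed_label, "mixed"),
        lambda_prime=lam_p,
        is_labeled=is_labeled,
    )


def mixup_batch(labeled: Sequence[tuple[ChannelPair, LabelDistribution]],
                unlabeled: Sequence[tuple[ChannelPair, LabelDistribution]],
                alpha: float, rng: np.random.Generator
                ) -> tuple[list[VirtualSample], list[VirtualSample]]:
    """MixUp every sample with a partner drawn from the shuffled union.

    Returns ``(L', U')`` with ``|L'| = |labeled|`` and ``|U'| = |unlabeled|``;
    membership follows the first parent's origin.
    """
    if not labeled:
        raise ValueError("labeled set must be non-empty during training")
    pool = list(labeled) + list(unlabeled)
    partners = rng.permutation(len(pool))
    out_l, out_u = [], []
    for idx, (pair, label) in enumerate(pool):
        pj, yj = pool[partners[idx]]
        virt = mixup_pair(pair, label, pj, yj, alpha, rng,
                          is_labeled=idx < len(labeled))
        (out_l if virt.is_labeled else out_u).append(virt)
    return out_l, out_u


def contrastive_negatives(n: int, rng: np.random.Generator) -> np.ndarray:
    """A random derangement of ``range(n)``: partner k != i for every i."""
    if n < 2:
        raise ValueError("need batch size >= 2 for contrastive negatives")
    while True:
        perm = rng.permutation(n)
        if not np.any(perm == np.arange(n)):
            return perm


# ---------------------------------------------------------------------------
# Combined loss
# ---------------------------------------------------------------------------


def cross_entropy(pred: Tensor, targets: np.ndarray) -> Tensor:
    """Mean -sum(y log y_hat) with natural log and a numeric floor."""
    t = Tensor(np.asarray(targets, dtype=float))
    return -((pred + PROB_FLOOR).log() * t).sum(axis=1).mean()


def total_loss(pred_labeled: Tensor, labels_l: np.ndarray,
               pred_unlabeled: Tensor | None, labels_u: np.ndarray | None,
               contrastive_terms: Tensor | None,
               weights: LossWeights, n_classes: int,
               contrastive_reduction: str = "mean") -> Tensor:
    """Combined objective: CE over L' + lambda_U * mean ||y - y_hat||^2 / C
    over U' + lambda_C * aggregated per-sample contrastive terms.

    The contrastive aggregation defaults to the mean over L' union U' so
    the weight is batch-size independent; ``contrastive_reduction="sum"``
    selects the literal unnormalized sum.
    """
    if pred_labeled is None or pred_labeled.shape[0] == 0:
        raise ValueError("labeled set must be non-empty")
    loss = cross_entropy(pred_labeled, labels_l)
    if pred_unlabeled is not None and pred_unlabeled.shape[0] > 0:
        diff = pred_unlabeled - Tensor(np.asarray(labels_u, dtype=float))
        sq = (diff * diff).sum(axis=1) * (1.0 / n_classes)
        loss = loss + weights.lambda_u * sq.mean()
    if contrastive_terms is not None and weights.lambda_c > 0:
        if contrastive_reduction == "mean":
            agg = contrastive_terms.mean()
        elif contrastive_reduction == "sum":
            agg = contrastive_terms.sum()
        else:
            raise ValueError(f"unknown reduction {contrastive_reduction!r}")
        loss = loss + weights.lambda_c * agg
    return loss
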