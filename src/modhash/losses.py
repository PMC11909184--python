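"""Training losses: characteristic classification, pairwise Cauchy
cross-entropy, and quantization, plus the continuous Hamming distance.

The pairwise loss treats the Cauchy similarity

    s_hat = γ / (γ + d_H(h_i, h_j))

as a predicted pair-similarity probability and scores it with binary
cross-entropy against the ground-truth similarity s ∈ {0, 1}; the
heavy-tailed Cauchy shape concentrates similar pairs within a small
Hamming ball.  The distance between relaxed codes is the cosine form

    d_H(h_i, h_j) = (K/2) · (1 − cos(h_i, h_j)),

which on binary codes equals the integer mismatch count exactly.

Reference (NumPy) implementations here define the contract; batched
autodiff versions used by the trainer are provided alongside and must
agree with them (tested).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._nn import Tensor, log_softmax
from .core_types import CharacteristicLabels, RelaxedHashCode
from .hashing import binarize_bits

#: floor applied to the Hamming distance inside logarithms; the s=0 branch
#: of the Cauchy cross-entropy is singular at d = 0.
DISTANCE_EPS = 1e-6

LOSS_TERMS = ("L1", "L2", "L3")


@dataclass(frozen=True)
class LossConfig:
    """Hyperparameters of the combined objective L = L1 + L2 + α·L3.

    ``gamma`` is the Cauchy scale (default K/4, resolved by the trainer when
    left as None); ``alpha`` weights the quantization term (paper default
    0.01); ``loss_subset`` activates a subset of terms for ablation runs.
    """

    gamma: float | None = None
    alpha: float = 0.01
    loss_subset: frozenset[str] = frozenset(LOSS_TERMS)
    #: when True the pairwise term also scores each sub-code's distance
    #: against that characteristic's own label match (scale K_k/4), which is
    #: what aligns every sub-code with its characteristic
    structured_pairs: bool = True

    def __post_init__(self) -> None:
        if self.gamma is not None and self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        unknown = set(self.loss_subset) - set(LOSS_TERMS)
        if unknown:
            raise ValueError(f"unknown loss terms: {sorted(unknown)}")

    def resolve_gamma(self, code_length: int) -> float:
        return float(self.gamma) if self.gamma is not None else code_length / 4.0


@dataclass
class LossBreakdown:
    """Per-term loss values for one step or epoch."""

    L1: float
    L2: float
    L3: float
    L: float


# ---------------------------------------------------------------------------
# Reference implementations (contract)
# ---------------------------------------------------------------------------

def _log_softmax_np(logits: np.ndarray) -> np.ndarray:
    m = logits.max(axis=-1, keepdims=True)
    z = logits - m
    return z - np.log(np.exp(z).sum(axis=-1, keepdims=True))


def classification_loss(
    logits_triple: Sequence[np.ndarray],
    labels: CharacteristicLabels | Sequence[CharacteristicLabels],
) -> float:
    """Sum of the three heads' cross-entropies, summed over samples.

    ``logits_triple`` is (modality, organ, disease) logits; each entry is a
    1-D vector for a single sample or a (B, classes) matrix for a batch.
    """
    single = isinstance(labels, CharacteristicLabels)
    label_list = [labels] if single else list(labels)
    total = 0.0
    for axis, char in enumerate(("modality", "organ", "disease")):
        logits = np.atleast_2d(np.asarray(logits_triple[axis], dtype=np.float64))
        if logits.shape[0] != len(label_list):
            raise ValueError("logits batch size does not match labels")
        idx = np.array([getattr(l, char) for l in label_list])
        if idx.min() < 0 or idx.max() >= logits.shape[1]:
            raise ValueError(f"{char} label out of range for {logits.shape[1]} classes")
        ls = _log_softmax_np(logits)
        total += -ls[np.arange(len(label_list)), idx].sum()
    return float(total)


def continuous_hamming(hi: np.ndarray, hj: np.ndarray) -> float:
    """d = (K/2)(1 − cos(hi, hj)); equals mismatch count on binary codes."""
    hi = np.asarray(hi, dtype=np.float64).ravel()
    hj = np.asarray(hj, dtype=np.float64).ravel()
    if hi.size != hj.size:
        raise ValueError("codes must have equal length")
    ni, nj = np.linalg.norm(hi), np.linalg.norm(hj)
    if ni == 0.0 or nj == 0.0:
        raise ValueError("zero-norm code has no direction")
    k = hi.size
    return float(k / 2.0 * (1.0 - hi @ hj / (ni * nj)))


def cauchy_similarity(hi: np.ndarray, hj: np.ndarray, gamma: float) -> float:
    """Predicted pair similarity s_hat = γ / (γ + d) ∈ (0, 1]."""
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    return gamma / (gamma + continuous_hamming(hi, hj))


def cauchy_loss(hi: np.ndarray, hj: np.ndarray, s: int, gamma: float) -> float:
    """Binary cross-entropy of the Cauchy similarity against s ∈ {0, 1}.

    The distance is floored at :data:`DISTANCE_EPS` inside the logarithms,
    which makes the loss total (finite for all inputs).
    """
    if s not in (0, 1):
        raise ValueError("pair similarity s must be 0 or 1")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    d = max(continuous_hamming(hi, hj), DISTANCE_EPS)
    s_hat = gamma / (gamma + d)
    return float(-(s * np.log(s_hat) + (1 - s) * np.log(1.0 - s_hat)))


def cauchy_loss_direct(hi: np.ndarray, hj: np.ndarray, s: int, gamma: float) -> float:
    """The algebraically expanded form s·log(d/γ) + log(1 + γ/d).

    Equivalent to :func:`cauchy_loss` for s ∈ {0, 1}; kept as the expanded
    identity (cross-checked in tests).
    """
    d = max(continuous_hamming(hi, hj), DISTANCE_EPS)
    return float(s * np.log(d / gamma) + np.log(1.0 + gamma / d))


def quantization_loss(h: RelaxedHashCode | np.ndarray) -> float:
    """‖h − sign(h)‖₂ per code, summed over the batch; 0 iff h is binary."""
    values = h.values if isinstance(h, RelaxedHashCode) else np.asarray(h, dtype=np.float64)
    values = np.atleast_2d(values)
    b = binarize_bits(values).astype(np.float64)
    return float(np.linalg.norm(values - b, axis=1).sum())


def total_loss(L1: float, L2: float, L3: float, cfg: LossConfig) -> LossBreakdown:
    """Combine terms as L = L1 + L2 + α·L3, zeroing inactive subset members."""
    active = cfg.loss_subset
    l1 = L1 if "L1" in active else 0.0
    l2 = L2 if "L2" in active else 0.0
    l3 = L3 if "L3" in active else 0.0
    return LossBreakdown(L1=l1, L2=l2, L3=l3, L=l1 + l2 + cfg.alpha * l3)


# ---------------------------------------------------------------------------
# Batched autodiff versions (used by the trainer)
# ---------------------------------------------------------------------------

def batch_classification_loss(
    logits: dict[str, Tensor], labels: Sequence[CharacteristicLabels]
) -> Tensor:
    """Tensor version of :func:`classification_loss` (summed over batch)."""
    total: Tensor | None = None
    for char, head_logits in logits.items():
        n_classes = head_logits.shape[1]
        idx = np.array([getattr(l, char) for l in labels])
        onehot = np.zeros((len(labels), n_classes))
        onehot[np.arange(len(labels)), idx] = 1.0
        term = -(Tensor(onehot) * log_softmax(head_logits, axis=1)).sum()
        total = term if total is None else total + term
    assert total is not None
    return total


def pairwise_hamming_matrix(h: Tensor) -> Tensor:
    """All-pairs continuous Hamming distances of batch codes (B, K) -> (B, B)."""
    k = h.shape[1]
    norms = ((h * h).sum(axis=1, keepdims=True) + 1e-12).sqrt()
    hn = h / norms
    cos = hn @ hn.T
    return (1.0 - cos) * (k / 2.0)


def batch_cauchy_loss(h: Tensor, similarity: np.ndarray, gamma: float) -> Tensor:
    """Mean Cauchy cross-entropy over all unordered within-batch pairs.

    ``similarity`` is the (B, B) 0/1 ground-truth matrix; only the strict
    upper triangle contributes.  Averaging (not summing) over pairs keeps
    the learning rate decoupled from the batch size.
    """
    b = h.shape[0]
    if b < 2:
        raise ValueError("need a batch of at least 2 samples to form pairs")
    d = pairwise_hamming_matrix(h)
    # floor the distance: max(d, eps) = eps + relu(d - eps)
    d = (d - DISTANCE_EPS).relu() + DISTANCE_EPS
    log_s_hat = Tensor(np.full((b, b), gamma)).log() - (d + gamma).log()
    log_one_minus = d.log() - (d + gamma).log()
    s = np.asarray(similarity, dtype=np.float64)
    term = -(Tensor(s) * log_s_hat + Tensor(1.0 - s) * log_one_minus)
    mask = np.triu(np.ones((b, b)), k=1)
    n_pairs = b * (b - 1) // 2
    return (Tensor(mask) * term).sum() * (1.0 / n_pairs)


def batch_quantization_loss(h: Tensor) -> Tensor:
    """Tensor version of :func:`quantization_loss` (summed over batch)."""
    b = binarize_bits(h.data).astype(np.float64)  # constant target
    diff = h - Tensor(b)
    return (((diff * diff).sum(axis=1) + 1e-12).sqrt()).sum()
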