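"""Loss arithmetic for a predictive-coding training objective.

Three pure functions, no training loop:

* :func:`cpc_loss` — the contrastive predictive-coding (InfoNCE) loss of a
  predicted embedding against one positive and a set of negatives at
  temperature tau, using cosine similarity.  The denominator includes the
  positive term, which keeps the loss non-negative.
* :func:`mixture_weight` — the contribution-balancing rule: given a target
  mixture weight alpha and the two current loss values, the effective
  weight alpha' is chosen so that the high-level term contributes exactly
  the fraction alpha of the total:

      alpha' = alpha * L_lm / ((1 - alpha) * L_high + alpha * L_lm)

  With alpha = 0.5 both terms contribute 50% of the total, and the
  endpoints alpha = 0 / alpha = 1 reduce to pure language modelling /
  pure high-level prediction.
* :func:`mixture_loss` — the balanced total
  ``alpha' * L_high + (1 - alpha') * L_lm``.

A helper draws negatives from a queue without replacement, excluding the
positive's slot.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "LossConfig",
    "cpc_loss",
    "mixture_weight",
    "mixture_loss",
    "sample_negative_indices",
    "toy_demo",
]


@dataclass
class LossConfig:
    """Hyper-parameters of the contrastive objective."""

    alpha: float = 0.5
    tau: float = 0.1
    n_negatives: int = 2000
    queue_size: int = 2500

    def __post_init__(self) -> None:
        if not 0 <= self.alpha <= 1:
            raise InvalidParameterError("alpha must lie in [0, 1]")
        if self.tau <= 0:
            raise InvalidParameterError("tau must be positive")
        if self.n_negatives < 1 or self.queue_size < 1:
            raise InvalidParameterError("n_negatives and queue_size must be >= 1")
        if self.n_negatives > self.queue_size:
            raise InvalidParameterError("n_negatives cannot exceed queue_size")


def _cosine(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.atleast_2d(np.asarray(b, dtype=float))
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b, axis=1)
    if na == 0 or np.any(nb == 0):
        raise InvalidInputError("cosine similarity undefined for zero vectors")
    return (b @ a) / (na * nb)


def cpc_loss(
    predicted: np.ndarray,
    positive: np.ndarray,
    negatives: Sequence[np.ndarray] | np.ndarray,
    config: LossConfig = None,
) -> float:
    """Contrastive predictive-coding loss (InfoNCE with cosine similarity).

    ``-log( e^{S(p, pos)/tau} / (e^{S(p, pos)/tau} + sum_neg e^{S(p, neg)/tau}) )``
    computed with log-sum-exp stabilisation; always >= 0.
    """
    if config is None:
        config = LossConfig()
    negatives = np.atleast_2d(np.asarray(negatives, dtype=float))
    if negatives.shape[0] == 0:
        raise InvalidInputError("at least one negative sample is required")
    s_pos = float(_cosine(predicted, np.atleast_2d(positive))[0]) / config.tau
    s_neg = _cosine(predicted, negatives) / config.tau
    return float(logsumexp(np.concatenate([[s_pos], s_neg])) - s_pos)


def mixture_weight(alpha: float, loss_high: float, loss_lm: float) -> float:
    """Effective mixture weight alpha' balancing the two loss contributions.

    Guarantees ``alpha' * L_high / (alpha' * L_high + (1 - alpha') * L_lm)
    == alpha`` for any positive losses, so alpha is the *share* of the
    total contributed by the high-level term.
    """
    if not 0 <= alpha <= 1:
        raise InvalidParameterError("alpha must lie in [0, 1]")
    if loss_high <= 0 or loss_lm <= 0:
        raise InvalidParameterError("losses must be strictly positive")
    return alpha * loss_lm / ((1 - alpha) * loss_high + alpha * loss_lm)


def mixture_loss(loss_high: float, loss_lm: float, alpha: float) -> float:
    """Balanced total loss ``alpha' * L_high + (1 - alpha') * L_lm``."""
    ap = mixture_weight(alpha, loss_high, loss_lm)
    return ap * loss_high + (1 - ap) * loss_lm


def sample_negative_indices(
    queue_size: int,
    n_negatives: int,
    positive_index: Optional[int] = None,
    rng: np.random.Generator = None,
) -> np.ndarray:
    """Draw ``n_negatives`` distinct queue slots, excluding the positive's."""
    if rng is None:
        rng = np.random.default_rng()
    pool = np.arange(queue_size)
    if positive_index is not None:
        if not 0 <= positive_index < queue_size:
            raise InvalidParameterError("positive_index out of range")
        pool = np.delete(pool, positive_index)
    if n_negatives > len(pool):
        raise InvalidParameterError(
            f"cannot draw {n_negatives} negatives from a pool of {len(pool)}"
        )
    return rng.choice(pool, size=n_negatives, replace=False)


def toy_demo(alpha: float = 0.5, seed: int = 0, dim: int = 32,
             queue_size: int = 50, n_negatives: int = 20) -> dict:
    """Seeded toy batch illustrating the loss arithmetic (used by the CLI)."""
    rng = np.random.default_rng(seed)
    config = LossConfig(alpha=alpha, n_negatives=n_negatives, queue_size=queue_size)
    positive = rng.standard_normal(dim)
    predicted = positive + 0.5 * rng.standard_normal(dim)
    queue = rng.standard_normal((queue_size, dim))
    idx = sample_negative_indices(queue_size, n_negatives, positive_index=0, rng=rng)
    l_high = cpc_loss(predicted, positive, queue[idx], config)
    l_lm = float(rng.uniform(2.5, 4.0))  # stand-in next-word cross-entropy
    ap = mixture_weight(alpha, l_high, l_lm)
    total = mixture_loss(l_high, l_lm, alpha)
    return {
        "alpha": alpha,
        "cpc_loss": l_high,
        "lm_loss": l_lm,
        "alpha_prime": ap,
        "total_loss": total,
    }
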