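"""Training losses for ordinal classification.

Seven losses are provided.  Four are baselines from the literature:

* ``ce`` — plain cross-entropy, which ignores class order entirely;
* ``oe`` — ordinal encoding: mean binary cross-entropy of K-1 sigmoid outputs
  against the cumulative code of the label;
* ``bu`` — binomial-unimodal: cross-entropy through a binomial output head;
* ``pu`` — Poisson-unimodal: cross-entropy through a Poisson/softmax head.

Three are non-parametric unimodality-promoting losses built from a margin
penalty on consecutive class probabilities:

* ``co``  — cross-entropy plus the pairwise unimodality penalty (margin 0);
* ``co2`` — the same penalty with margin ``delta`` (default 0.05): consecutive
  probabilities must rise by at least ``delta`` before the true class and fall
  by at least ``delta`` after it;
* ``ho2`` — the entropy of the prediction replaces cross-entropy as the base
  term, so the loss only asks for a low-entropy distribution that is
  ``delta``-strictly unimodal and peaked at the true class.

All logarithms are natural.  Probabilities are clamped at ``1e-12`` before any
log so degenerate outputs yield large but finite losses.

Two conventions exist for which consecutive pairs the penalty sums cover.  In
``non_overlapping`` mode (the default) the rising pairs are k < k* and the
falling pairs k >= k*, so the penalty is zero exactly on the delta-strictly
unimodal distributions peaked at k*.  In ``as_printed`` mode the rising sum
includes k = k* as well, which forces a floor of ``2*delta`` on the penalty at
the peak transition; it is kept as a switch for literal fidelity to the
formulation the non-overlapping mode rationalizes.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

import numpy as np

from .encodings import OrdinalLabel, as_class_probabilities, encode_cumulative

__all__ = [
    "BoundaryMode",
    "LossConfig",
    "LossValue",
    "LOSS_NAMES",
    "cross_entropy",
    "unimodal_penalty",
    "co_loss",
    "co2_loss",
    "ho2_loss",
    "oe_loss",
    "bu_loss",
    "pu_loss",
    "batch_unimodal_penalty",
    "batch_unimodal_penalty_grad",
]

EPS = 1e-12

#: Names accepted wherever a loss is selected by string.
LOSS_NAMES = ("ce", "oe", "bu", "pu", "co", "co2", "ho2")


class BoundaryMode(str, enum.Enum):
    """Which consecutive pairs the unimodality penalty sums cover."""

    NON_OVERLAPPING = "non_overlapping"
    AS_PRINTED = "as_printed"


@dataclass(frozen=True)
class LossConfig:
    """Hyperparameters shared by the penalized losses.

    Parameters
    ----------
    lambda_weight:
        Relative weight of the unimodality penalty, >= 0.
    delta_margin:
        Minimum required difference between consecutive probabilities
        (dimensionless, in [0, 1)).  0.05 is a sensible default margin.
    boundary_mode:
        See module docstring.
    temperature:
        Softmax temperature of the Poisson head (kept constant at 1).
    """

    lambda_weight: float = 1.0
    delta_margin: float = 0.05
    boundary_mode: BoundaryMode = BoundaryMode.NON_OVERLAPPING
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_weight < 0:
            raise ValueError("lambda_weight must be >= 0")
        if not (0 <= self.delta_margin < 1):
            raise ValueError("delta_margin must lie in [0, 1)")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        object.__setattr__(self, "boundary_mode", BoundaryMode(self.boundary_mode))


@dataclass(frozen=True)
class LossValue:
    """A loss decomposed as ``total = base_term + lambda_weight * penalty_term``."""

    total: float
    base_term: float
    penalty_term: float
    lambda_weight: float = 0.0


def _neg_log(p: float) -> float:
    return float(-np.log(max(p, EPS)))


def cross_entropy(label: OrdinalLabel, probs: np.ndarray) -> LossValue:
    """Cross-entropy ``-log(p[k*])``: maximize the probability of the true class."""
    probs = as_class_probabilities(probs)
    if probs.size != label.K:
        raise ValueError("probability vector length does not match label K")
    base = _neg_log(probs[label.k_star - 1])
    return LossValue(total=base, base_term=base, penalty_term=0.0)


def unimodal_penalty(
    label: OrdinalLabel, probs: np.ndarray, config: LossConfig
) -> float:
    """Pairwise margin penalty for deviations from unimodality peaked at k*.

    Rising pairs before the peak contribute ``ReLU(delta + p_k - p_{k+1})``,
    falling pairs after it ``ReLU(delta + p_{k+1} - p_k)``; with ``delta = 0``
    this is the plain CO penalty.
    """
    probs = as_class_probabilities(probs)
    if probs.size != label.K:
        raise ValueError("probability vector length does not match label K")
    pen = batch_unimodal_penalty(
        np.array([label.k_star]),
        probs[None, :],
        delta=config.delta_margin,
        mode=config.boundary_mode,
    )
    return float(pen[0])


def _pair_masks(
    k_star: np.ndarray, K: int, mode: BoundaryMode
) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (N, K-1) of the rising (left) and falling (right) pairs.

    Pair m (0-based, m = 0..K-2) couples classes m+1 and m+2 (1-based).
    """
    m = np.arange(K - 1)[None, :]
    k = np.asarray(k_star, dtype=int)[:, None]
    if BoundaryMode(mode) is BoundaryMode.NON_OVERLAPPING:
        left = (m + 1) < k
    else:  # as printed: the rising sum includes k = k*
        left = (m + 1) <= k
    right = (m + 1) >= k
    return left, right


def batch_unimodal_penalty(
    k_star: np.ndarray,
    probs: np.ndarray,
    delta: float,
    mode: BoundaryMode = BoundaryMode.NON_OVERLAPPING,
) -> np.ndarray:
    """Vectorized unimodality penalty for N samples; returns shape (N,)."""
    probs = np.asarray(probs, dtype=float)
    N, K = probs.shape
    left, right = _pair_masks(k_star, K, mode)
    rise = np.maximum(delta + probs[:, :-1] - probs[:, 1:], 0.0)
    fall = np.maximum(delta + probs[:, 1:] - probs[:, :-1], 0.0)
    return np.sum(rise * left, axis=1) + np.sum(fall * right, axis=1)


def batch_unimodal_penalty_grad(
    k_star: np.ndarray,
    probs: np.ndarray,
    delta: float,
    mode: BoundaryMode = BoundaryMode.NON_OVERLAPPING,
) -> np.ndarray:
    """Gradient of :func:`batch_unimodal_penalty` w.r.t. ``probs``; shape (N, K).

    ReLU subgradient 0 is used at the kinks.
    """
    probs = np.asarray(probs, dtype=float)
    N, K = probs.shape
    left, right = _pair_masks(k_star, K, mode)
    rise_active = (((delta + probs[:, :-1] - probs[:, 1:]) > 0) & left).astype(float)
    fall_active = (((delta + probs[:, 1:] - probs[:, :-1]) > 0) & right).astype(float)
    grad = np.zeros_like(probs)
    grad[:, :-1] += rise_active - fall_active
    grad[:, 1:] += fall_active - rise_active
    return grad


def _entropy(probs: np.ndarray) -> float:
    p = np.clip(probs, EPS, None)
    return float(-np.sum(probs * np.log(p)))


def co_loss(label: OrdinalLabel, probs: np.ndarray, config: LossConfig) -> LossValue:
    """Cross-entropy plus the margin-free unimodality penalty (delta forced to 0)."""
    cfg = replace(config, delta_margin=0.0)
    base = cross_entropy(label, probs).base_term
    pen = unimodal_penalty(label, probs, cfg)
    return LossValue(
        total=base + config.lambda_weight * pen,
        base_term=base,
        penalty_term=pen,
        lambda_weight=config.lambda_weight,
    )


def co2_loss(label: OrdinalLabel, probs: np.ndarray, config: LossConfig) -> LossValue:
    """Cross-entropy plus the delta-margin unimodality penalty."""
    base = cross_entropy(label, probs).base_term
    pen = unimodal_penalty(label, probs, config)
    return LossValue(
        total=base + config.lambda_weight * pen,
        base_term=base,
        penalty_term=pen,
        lambda_weight=config.lambda_weight,
    )


def ho2_loss(label: OrdinalLabel, probs: np.ndarray, config: LossConfig) -> LossValue:
    """Prediction entropy plus the delta-margin unimodality penalty.

    Replacing cross-entropy by the entropy ``H(p) = -sum p_k log p_k`` drops the
    hard one-hot target: any low-entropy, delta-strictly unimodal distribution
    peaked at the true class achieves a near-minimal loss.
    """
    probs_v = as_class_probabilities(probs)
    if probs_v.size != label.K:
        raise ValueError("probability vector length does not match label K")
    base = _entropy(probs_v)
    pen = unimodal_penalty(label, probs_v, config)
    return LossValue(
        total=base + config.lambda_weight * pen,
        base_term=base,
        penalty_term=pen,
        lambda_weight=config.lambda_weight,
    )


def oe_loss(label: OrdinalLabel, raw_outputs: np.ndarray) -> LossValue:
    """Mean binary cross-entropy of K-1 outputs against the cumulative code."""
    raw = np.asarray(raw_outputs, dtype=float)
    if raw.ndim != 1 or raw.size != label.K - 1:
        raise ValueError("raw_outputs must have length K-1")
    if np.any(raw < 0) or np.any(raw > 1):
        raise ValueError("raw_outputs must lie in [0, 1]")
    targets = encode_cumulative(label)
    p = np.clip(raw, EPS, 1 - EPS)
    bce = -(targets * np.log(p) + (1 - targets) * np.log(1 - p))
    base = float(bce.mean())
    return LossValue(total=base, base_term=base, penalty_term=0.0)


def bu_loss(label: OrdinalLabel, probs_from_binomial_head: np.ndarray) -> LossValue:
    """Negative log of the binomial-head probability at the true class."""
    return cross_entropy(label, probs_from_binomial_head)


def pu_loss(label: OrdinalLabel, probs_from_poisson_head: np.ndarray) -> LossValue:
    """Negative log of the Poisson-head probability at the true class."""
    return cross_entropy(label, probs_from_poisson_head)
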