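"""Parametric unimodal output heads and inference rules.

The binomial head maps a single sigmoid output ``q`` to the binomial(K-1, q)
probability mass function over the K classes, so ``q = 0`` puts all mass on
class 1 and ``q = 1`` on class K.  The Poisson head evaluates the log Poisson
PMF at class offsets 0..K-1 and renormalizes with a temperature-tau softmax.
Both families are unimodal over classes for every parameter value.

Two inference rules turn a class-probability vector into a predicted class:
the mode (argmax, ties to the lowest index) and the expectation trick
(round the probability-weighted mean class index, half-up, clamped to 1..K).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln, softmax

from .encodings import OrdinalLabel, as_class_probabilities

__all__ = [
    "BinomialHeadParam",
    "PoissonHeadParam",
    "binomial_probabilities",
    "poisson_probabilities",
    "predict_mode",
    "predict_expectation",
    "rate_from_score",
]


@dataclass(frozen=True)
class BinomialHeadParam:
    """Success probability ``q`` in [0, 1] — the single sigmoid output."""

    q: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.q <= 1.0):
            raise ValueError("q must lie in [0, 1]")


@dataclass(frozen=True)
class PoissonHeadParam:
    """Poisson rate > 0 and softmax temperature tau > 0 (default 1)."""

    rate: float
    temperature: float = 1.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError("rate must be > 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


def binomial_probabilities(param: BinomialHeadParam, K: int) -> np.ndarray:
    """Class probabilities ``p_k = C(K-1, k-1) q^(k-1) (1-q)^(K-k)``, k = 1..K."""
    if K < 2:
        raise ValueError("K must be >= 2")
    probs = stats.binom.pmf(np.arange(K), K - 1, param.q)
    return probs / probs.sum()


def poisson_probabilities(param: PoissonHeadParam, K: int) -> np.ndarray:
    """Temperature softmax of the log Poisson PMF at counts 0..K-1."""
    if K < 2:
        raise ValueError("K must be >= 2")
    k = np.arange(K)
    scores = k * np.log(param.rate) - param.rate - gammaln(k + 1)
    return softmax(scores / param.temperature)


def rate_from_score(z: float, eps: float = 1e-6) -> float:
    """Softplus link mapping an unconstrained network output to a positive rate."""
    return float(np.logaddexp(0.0, z) + eps)


def predict_mode(probs: np.ndarray) -> OrdinalLabel:
    """Argmax class; ties are broken toward the lowest class index."""
    probs = as_class_probabilities(probs)
    return OrdinalLabel(k_star=int(np.argmax(probs)) + 1, K=probs.size)


def predict_expectation(probs: np.ndarray) -> OrdinalLabel:
    """Round the expected class index sum_k k p_k (half-up), clamped to 1..K."""
    probs = as_class_probabilities(probs)
    K = probs.size
    expectation = float(np.sum(np.arange(1, K + 1) * probs))
    k = int(np.floor(expectation + 0.5))
    return OrdinalLabel(k_star=min(max(k, 1), K), K=K)
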