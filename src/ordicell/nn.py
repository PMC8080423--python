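"""A small NumPy feed-forward framework for the reference models.

Provides exactly what the experiment harness needs: dense/ReLU/dropout layers,
a 3-block convolutional backbone for small images, the Adam optimizer, a
reduce-on-plateau learning-rate schedule, and differentiable adapters that map
raw network outputs to each of the seven training losses.  Every adapter
returns both the mean batch loss and its analytic gradient with respect to the
raw outputs; the gradients are checked against numerical differentiation in
the test suite.

Class labels entering the adapters are 1-based integer arrays, consistent with
the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, gammaln

from .encodings import OrdinalLabel
from .losses import (
    EPS,
    BoundaryMode,
    LossConfig,
    batch_unimodal_penalty,
    batch_unimodal_penalty_grad,
)

__all__ = [
    "Dense",
    "ReLU",
    "Dropout",
    "Conv2D",
    "MaxPool2D",
    "Flatten",
    "Sequential",
    "Adam",
    "ReduceLROnPlateau",
    "SoftmaxOrdinalLoss",
    "OrdinalEncodingLoss",
    "BinomialUnimodalLoss",
    "PoissonUnimodalLoss",
    "make_loss_adapter",
    "TrainSettings",
    "TrainHistory",
    "train_model",
    "predict_probabilities",
]


# --------------------------------------------------------------------------
# layers
# --------------------------------------------------------------------------


class Layer:
    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Fully connected layer with He-normal initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.gW[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.W.T


class ReLU(Layer):
    def forward(self, x, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float):
        if not (0 <= p < 1):
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p

    def forward(self, x, train=False, rng=None):
        if not train or self.p == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Conv2D(Layer):
    """3x3 same-padding convolution on NCHW arrays (stride 1)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        fan_in = c_in * kernel * kernel
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                            size=(c_out, c_in, kernel, kernel))
        self.b = np.zeros(c_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.kernel = kernel

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train=False, rng=None):
        k = self.kernel
        pad = k // 2
        self._xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
        N, C, H, W = x.shape
        out = np.tile(self.b[None, :, None, None], (N, 1, H, W)).astype(float)
        for di in range(k):
            for dj in range(k):
                patch = self._xp[:, :, di:di + H, dj:dj + W]
                out += np.tensordot(patch, self.W[:, :, di, dj], axes=([1], [1])
                                    ).transpose(0, 3, 1, 2)
        return out

    def backward(self, grad):
        k = self.kernel
        pad = k // 2
        N, Co, H, W = grad.shape
        gxp = np.zeros_like(self._xp)
        self.gb[...] = grad.sum(axis=(0, 2, 3))
        for di in range(k):
            for dj in range(k):
                patch = self._xp[:, :, di:di + H, dj:dj + W]
                self.gW[:, :, di, dj] = np.tensordot(grad, patch,
                                                     axes=([0, 2, 3], [0, 2, 3]))
                gxp[:, :, di:di + H, dj:dj + W] += np.tensordot(
                    grad, self.W[:, :, di, dj], axes=([1], [0])
                ).transpose(0, 3, 1, 2)
        return gxp[:, :, pad:-pad or None, pad:-pad or None]


class MaxPool2D(Layer):
    """2x2 max pooling (even spatial dims required)."""

    def forward(self, x, train=False, rng=None):
        N, C, H, W = x.shape
        if H % 2 or W % 2:
            raise ValueError("MaxPool2D requires even spatial dimensions")
        win = x.reshape(N, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        win = win.reshape(N, C, H // 2, W // 2, 4)
        self._idx = win.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(win, self._idx[..., None], axis=-1)[..., 0]

    def backward(self, grad):
        N, C, H, W = self._shape
        gwin = np.zeros((N, C, H // 2, W // 2, 4))
        np.put_along_axis(gwin, self._idx[..., None], grad[..., None], axis=-1)
        gwin = gwin.reshape(N, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return gwin.reshape(N, C, H, W)


class Flatten(Layer):
    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def grads(self):
        return [g for layer in self.layers for g in layer.grads()]

    def forward(self, x, train=False, rng=None):
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


# --------------------------------------------------------------------------
# optimization
# --------------------------------------------------------------------------


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class ReduceLROnPlateau:
    """Multiply the lr by ``factor`` after ``patience`` epochs without improvement.

    "Improvement" means the monitored epoch loss dropping by more than
    ``min_delta`` below the best value seen so far.
    """

    def __init__(self, optimizer: Adam, factor: float = 0.9, patience: int = 10,
                 min_delta: float = 1e-4):
        if not (0 < factor < 1):
            raise ValueError("factor must lie in (0, 1)")
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.min_delta = min_delta
        self.best = np.inf
        self.stagnant = 0

    def step(self, epoch_loss: float) -> None:
        if epoch_loss < self.best - self.min_delta:
            self.best = epoch_loss
            self.stagnant = 0
        else:
            self.stagnant += 1
            if self.stagnant >= self.patience:
                self.optimizer.lr *= self.factor
                self.stagnant = 0


# --------------------------------------------------------------------------
# loss adapters: raw outputs z -> (mean loss, dLoss/dz, class probabilities)
# --------------------------------------------------------------------------


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _chain_through_softmax(p: np.ndarray, dldp: np.ndarray) -> np.ndarray:
    """Jacobian-vector product dL/dz given p = softmax(z) and dL/dp."""
    inner = np.sum(p * dldp, axis=1, keepdims=True)
    return p * (dldp - inner)


class LossAdapter:
    """Maps raw network outputs to a loss value and class probabilities."""

    name: str

    def out_width(self, K: int) -> int:
        raise NotImplementedError

    def probabilities(self, z: np.ndarray, K: int) -> np.ndarray:
        raise NotImplementedError

    def value_and_grad(self, z: np.ndarray, k_star: np.ndarray,
                       K: int) -> tuple[float, np.ndarray]:
        raise NotImplementedError


class SoftmaxOrdinalLoss(LossAdapter):
    """CE and the penalized softmax losses co / co2 / ho2 on K logits."""

    def __init__(self, kind: str, config: LossConfig | None = None):
        if kind not in ("ce", "co", "co2", "ho2"):
            raise ValueError(f"unknown softmax loss kind {kind!r}")
        self.name = kind
        self.config = config or LossConfig()

    def out_width(self, K: int) -> int:
        return K

    def probabilities(self, z, K):
        return _softmax(z)

    def _delta(self) -> float:
        return 0.0 if self.name == "co" else self.config.delta_margin

    def value_and_grad(self, z, k_star, K):
        N = z.shape[0]
        p = _softmax(z)
        idx = (np.arange(N), np.asarray(k_star, int) - 1)
        onehot = np.zeros_like(p)
        onehot[idx] = 1.0
        if self.name == "ho2":
            pc = np.clip(p, EPS, None)
            base = -np.sum(p * np.log(pc), axis=1)
            dbase_dp = -(np.log(pc) + 1.0)
            dz = _chain_through_softmax(p, dbase_dp)
        else:
            base = -np.log(np.clip(p[idx], EPS, None))
            dz = p - onehot  # exact CE-through-softmax gradient
        total = base
        if self.name != "ce" and self.config.lambda_weight > 0:
            lam, delta = self.config.lambda_weight, self._delta()
            mode = self.config.boundary_mode
            pen = batch_unimodal_penalty(k_star, p, delta, mode)
            dpen_dp = batch_unimodal_penalty_grad(k_star, p, delta, mode)
            total = base + lam * pen
            dz = dz + lam * _chain_through_softmax(p, dpen_dp)
        return float(total.mean()), dz / N


class OrdinalEncodingLoss(LossAdapter):
    """Mean BCE of K-1 sigmoid outputs against the cumulative label code."""

    name = "oe"

    def out_width(self, K: int) -> int:
        return K - 1

    def probabilities(self, z, K):
        s = expit(z)
        c = np.minimum.accumulate(s, axis=1)
        p = np.empty((z.shape[0], K))
        p[:, 0] = 1.0 - c[:, 0]
        p[:, 1:-1] = c[:, :-1] - c[:, 1:]
        p[:, -1] = c[:, -1]
        return p

    def value_and_grad(self, z, k_star, K):
        N = z.shape[0]
        s = expit(z)
        m = np.arange(1, K)[None, :]
        t = (m < np.asarray(k_star, int)[:, None]).astype(float)
        sc = np.clip(s, EPS, 1 - EPS)
        bce = -(t * np.log(sc) + (1 - t) * np.log(1 - sc))
        loss = bce.mean(axis=1)
        dz = (s - t) / (K - 1) / N
        return float(loss.mean()), dz


class BinomialUnimodalLoss(LossAdapter):
    """Single sigmoid output through the binomial(K-1, q) head."""

    name = "bu"
    _clip = 1e-7

    def out_width(self, K: int) -> int:
        return 1

    def probabilities(self, z, K):
        q = np.clip(expit(z[:, 0]), self._clip, 1 - self._clip)
        k = np.arange(K)[None, :]
        logpmf = (
            gammaln(K) - gammaln(k + 1) - gammaln(K - k)
            + k * np.log(q[:, None]) + (K - 1 - k) * np.log(1 - q[:, None])
        )
        p = np.exp(logpmf)
        return p / p.sum(axis=1, keepdims=True)

    def value_and_grad(self, z, k_star, K):
        N = z.shape[0]
        sig = expit(z[:, 0])
        q = np.clip(sig, self._clip, 1 - self._clip)
        k = np.asarray(k_star, int) - 1  # successes, 0..K-1
        logpmf = (
            gammaln(K) - gammaln(k + 1) - gammaln(K - k)
            + k * np.log(q) + (K - 1 - k) * np.log(1 - q)
        )
        loss = -logpmf
        dldq = -(k / q - (K - 1 - k) / (1 - q))
        dz = (dldq * sig * (1 - sig))[:, None] / N
        return float(loss.mean()), dz


class PoissonUnimodalLoss(LossAdapter):
    """Single output mapped by softplus to a Poisson rate, softmax over log-PMF."""

    name = "pu"
    _eps = 1e-6

    def __init__(self, config: LossConfig | None = None):
        self.config = config or LossConfig()

    def out_width(self, K: int) -> int:
        return 1

    def _rate(self, z):
        return np.logaddexp(0.0, z[:, 0]) + self._eps

    def _scores(self, rate, K):
        k = np.arange(K)[None, :]
        return k * np.log(rate[:, None]) - rate[:, None] - gammaln(k + 1)

    def probabilities(self, z, K):
        tau = self.config.temperature
        return _softmax(self._scores(self._rate(z), K) / tau)

    def value_and_grad(self, z, k_star, K):
        N = z.shape[0]
        tau = self.config.temperature
        rate = self._rate(z)
        p = _softmax(self._scores(rate, K) / tau)
        idx = (np.arange(N), np.asarray(k_star, int) - 1)
        loss = -np.log(np.clip(p[idx], EPS, None))
        onehot = np.zeros_like(p)
        onehot[idx] = 1.0
        ds_drate = np.arange(K)[None, :] / rate[:, None] - 1.0
        dldrate = np.sum((p - onehot) * ds_drate, axis=1) / tau
        dz = (dldrate * expit(z[:, 0]))[:, None] / N
        return float(loss.mean()), dz


def make_loss_adapter(name: str, config: LossConfig | None = None) -> LossAdapter:
    """Build the adapter for a loss selected by name."""
    if name in ("ce", "co", "co2", "ho2"):
        return SoftmaxOrdinalLoss(name, config)
    if name == "oe":
        return OrdinalEncodingLoss()
    if name == "bu":
        return BinomialUnimodalLoss()
    if name == "pu":
        return PoissonUnimodalLoss(config)
    raise ValueError(f"unknown loss {name!r}")


# --------------------------------------------------------------------------
# training loop
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class TrainSettings:
    """Optimization schedule (Adam + reduce-on-plateau)."""

    epochs: int = 100
    lr: float = 1e-4
    batch_size: int = 32
    plateau_patience: int = 10
    plateau_factor: float = 0.9
    plateau_min_delta: float = 1e-4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if not (0 < self.plateau_factor < 1):
            raise ValueError("plateau_factor must lie in (0, 1)")


@dataclass
class TrainHistory:
    epoch_losses: list[float] = field(default_factory=list)
    lr_trace: list[float] = field(default_factory=list)


def train_model(
    model: Sequential,
    adapter: LossAdapter,
    X: np.ndarray,
    y: np.ndarray,
    K: int,
    settings: TrainSettings,
) -> TrainHistory:
    """Minibatch-train *model* in place; returns per-epoch loss and lr traces.

    ``y`` holds 1-based class labels.  The learning rate drops by the plateau
    factor whenever the epoch-mean training loss stagnates for ``patience``
    epochs; the trace records the lr in force during each epoch.
    """
    rng = np.random.default_rng(settings.seed)
    opt = Adam(model.params(), lr=settings.lr)
    sched = ReduceLROnPlateau(
        opt, factor=settings.plateau_factor, patience=settings.plateau_patience,
        min_delta=settings.plateau_min_delta,
    )
    history = TrainHistory()
    n = X.shape[0]
    for _ in range(settings.epochs):
        history.lr_trace.append(opt.lr)
        order = rng.permutation(n)
        losses, weights = [], []
        for start in range(0, n, settings.batch_size):
            idx = order[start:start + settings.batch_size]
            z = model.forward(X[idx], train=True, rng=rng)
            loss, dz = adapter.value_and_grad(z, y[idx], K)
            model.backward(dz)
            opt.step(model.grads())
            losses.append(loss)
            weights.append(idx.size)
        epoch_loss = float(np.average(losses, weights=weights))
        history.epoch_losses.append(epoch_loss)
        sched.step(epoch_loss)
    return history


def predict_probabilities(
    model: Sequential, adapter: LossAdapter, X: np.ndarray, K: int,
    batch_size: int = 256,
) -> np.ndarray:
    """Evaluate the model and map raw outputs to class probabilities."""
    chunks = [
        adapter.probabilities(model.forward(X[i:i + batch_size], train=False), K)
        for i in range(0, X.shape[0], batch_size)
    ]
    return np.vstack(chunks)
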