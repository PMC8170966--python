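"""NumPy neural-network backends: a small MLP and a two-block CNN.

Both operate on FCGR grayscale images scaled to [0, 1].  The MLP flattens
its input and uses three 50-unit ReLU hidden layers; the CNN uses two
conv(3x3, "same") + batch-norm + ReLU + 2x2 max-pool blocks (64 then 32
filters) followed by 100- and 50-unit fully connected layers with dropout
0.5.  Training minimizes softmax cross-entropy with the Adamax optimizer
(learning rate 0.001); all randomness (weight init, batch shuffling,
dropout masks) flows from one seeded generator, so runs are reproducible
and scoring is deterministic (dropout and batch statistics are disabled at
inference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


# -- layers -------------------------------------------------------------------


class _Layer:
    params: list[np.ndarray]
    grads: list[np.ndarray]

    def __init__(self) -> None:
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray, train: bool, rng: np.random.Generator) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(_Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / n_in)  # He init for ReLU stacks
        self.W = rng.standard_normal((n_in, n_out)) * scale
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dout):
        self.grads[0][...] = self._x.T @ dout
        self.grads[1][...] = dout.sum(axis=0)
        return dout @ self.W.T


class ReLU(_Layer):
    def forward(self, x, train, rng):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(_Layer):
    def __init__(self, p: float) -> None:
        super().__init__()
        self.p = p

    def forward(self, x, train, rng):
        if not train or self.p == 0.0:
            return x
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class BatchNorm(_Layer):
    """Batch normalization over all axes except the channel axis.

    For (B, C, H, W) inputs the statistics pool over B, H and W per channel;
    for (B, F) inputs over B per feature.  Inference uses running statistics.
    """

    def __init__(self, n_channels: int, momentum: float = 0.9, eps: float = 1e-5) -> None:
        super().__init__()
        self.gamma = np.ones(n_channels)
        self.beta = np.zeros(n_channels)
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n_channels)
        self.running_var = np.ones(n_channels)

    def _axes_and_shape(self, x):
        if x.ndim == 4:
            return (0, 2, 3), (1, -1, 1, 1)
        return (0,), (1, -1)

    def forward(self, x, train, rng):
        axes, shape = self._axes_and_shape(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._axes, self._shape = axes, shape
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(shape)) / self._std.reshape(shape)
        self._n = x.size // x.shape[1] if x.ndim == 4 else x.shape[0]
        self._train = train
        return self.gamma.reshape(shape) * self._xhat + self.beta.reshape(shape)

    def backward(self, dout):
        axes, shape = self._axes, self._shape
        self.grads[0][...] = (dout * self._xhat).sum(axis=axes)
        self.grads[1][...] = dout.sum(axis=axes)
        g = self.gamma.reshape(shape)
        if not self._train:
            return dout * g / self._std.reshape(shape)
        n = self._n
        dxhat = dout * g
        term = (
            dxhat
            - dxhat.mean(axis=axes).reshape(shape)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes).reshape(shape)
        )
        return term / self._std.reshape(shape)


class Conv3x3(_Layer):
    """3x3 convolution with "same" zero padding, via im2col."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / (c_in * 9))
        self.W = rng.standard_normal((c_out, c_in * 9)) * scale
        self.b = np.zeros(c_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]
        self.c_in = c_in
        self.c_out = c_out

    @staticmethod
    def _im2col(x: np.ndarray) -> np.ndarray:
        B, C, H, W = x.shape
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        cols = np.empty((B, C, 9, H, W), dtype=x.dtype)
        k = 0
        for di in range(3):
            for dj in range(3):
                cols[:, :, k] = xp[:, :, di : di + H, dj : dj + W]
                k += 1
        return cols.reshape(B, C * 9, H * W)

    def forward(self, x, train, rng):
        B, C, H, W = x.shape
        self._shape = x.shape
        self._cols = self._im2col(x)  # (B, C*9, H*W)
        out = np.einsum("fk,bkp->bfp", self.W, self._cols) + self.b[None, :, None]
        return out.reshape(B, self.c_out, H, W)

    def backward(self, dout):
        B, C, H, W = self._shape
        dflat = dout.reshape(B, self.c_out, H * W)
        self.grads[0][...] = np.einsum("bfp,bkp->fk", dflat, self._cols)
        self.grads[1][...] = dflat.sum(axis=(0, 2))
        dcols = np.einsum("fk,bfp->bkp", self.W, dflat).reshape(B, C, 9, H, W)
        dx = np.zeros((B, C, H + 2, W + 2))
        k = 0
        for di in range(3):
            for dj in range(3):
                dx[:, :, di : di + H, dj : dj + W] += dcols[:, :, k]
                k += 1
        return dx[:, :, 1 : 1 + H, 1 : 1 + W]


class MaxPool2(_Layer):
    """2x2 max pooling with stride 2."""

    def forward(self, x, train, rng):
        B, C, H, W = x.shape
        xr = x.reshape(B, C, H // 2, 2, W // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        xr = xr.reshape(B, C, H // 2, W // 2, 4)
        self._arg = xr.argmax(axis=-1)
        self._shape = x.shape
        return np.take_along_axis(xr, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, dout):
        B, C, H, W = self._shape
        dxr = np.zeros((B, C, H // 2, W // 2, 4))
        np.put_along_axis(dxr, self._arg[..., None], dout[..., None], axis=-1)
        dxr = dxr.reshape(B, C, H // 2, W // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dxr.reshape(B, C, H, W)


class Flatten(_Layer):
    def forward(self, x, train, rng):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


# -- optimizer and model ------------------------------------------------------


class Adamax:
    """Adam variant using the infinity norm of the gradient."""

    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.u = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for p, g, m, u in zip(self.params, self.grads, self.m, self.u):
            m *= self.b1
            m += (1 - self.b1) * g
            np.maximum(self.b2 * u, np.abs(g), out=u)
            p -= (self.lr / (1 - self.b1**self.t)) * m / (u + self.eps)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


@dataclass
class NeuralModel:
    layers: list
    input_shape: tuple[int, ...]  # per-sample shape, e.g. (C, 64, 64) or (F,)
    seed: int
    backend: str = "mlp"
    history: list[float] = field(default_factory=list)

    def _forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        X = self._prepare(X)
        logits = self._forward(X, train=False, rng=None)
        return _softmax(logits)[:, 1]

    def _prepare(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        expected = (X.shape[0], *self.input_shape)
        if self.backend == "mlp" and X.ndim > 2:
            X = X.reshape(X.shape[0], -1)
        if X.shape != (X.shape[0], *self.input_shape):
            raise ValueError(f"input shape {X.shape[1:]} != expected {self.input_shape}")
        return X


def _fit(model: NeuralModel, X, y, epochs, lr, batch_size, rng) -> None:
    n = len(y)
    T = np.asarray(y, dtype=int)
    params, grads = [], []
    for layer in model.layers:
        params += layer.params
        grads += layer.grads
    opt = Adamax(params, grads, lr=lr)
    for _ in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, tb = X[idx], T[idx]
            logits = model._forward(xb, train=True, rng=rng)
            probs = _softmax(logits)
            loss = -np.log(probs[np.arange(len(tb)), tb] + 1e-12).mean()
            epoch_loss += loss * len(tb)
            dlogits = probs.copy()
            dlogits[np.arange(len(tb)), tb] -= 1.0
            dlogits /= len(tb)
            dout = dlogits
            for layer in reversed(model.layers):
                dout = layer.backward(dout)
            opt.step()
        model.history.append(epoch_loss / n)


def train_mlp(
    features: np.ndarray,
    labels: np.ndarray,
    epochs: int = 5,
    lr: float = 1e-3,
    batch_size: int = 64,
    hidden: tuple[int, ...] = (50, 50, 50),
    seed: int = 0,
) -> NeuralModel:
    """Three 50-unit ReLU hidden layers, softmax output, Adamax, 5 epochs."""
    X = np.asarray(features, dtype=float)
    if X.ndim > 2:
        X = X.reshape(X.shape[0], -1)
    rng = np.random.default_rng(seed)
    layers: list[_Layer] = []
    n_in = X.shape[1]
    for h in hidden:
        layers += [Dense(n_in, h, rng), ReLU()]
        n_in = h
    layers.append(Dense(n_in, 2, rng))
    model = NeuralModel(layers=layers, input_shape=(X.shape[1],), seed=seed, backend="mlp")
    _fit(model, X, np.asarray(labels), epochs, lr, batch_size, rng)
    return model


def train_cnn(
    images: np.ndarray,
    labels: np.ndarray,
    epochs: int = 20,
    lr: float = 1e-3,
    batch_size: int = 64,
    seed: int = 0,
) -> NeuralModel:
    """Two conv+BN+ReLU+pool blocks (64, 32 filters), FC 100/50 with dropout.

    Input must be (n, C, 64, 64) with pixel values in [0, 1]; feature maps
    shrink 64 -> 32 -> 16 so the flattened width is 16 * 16 * 32 = 8192.
    """
    X = np.asarray(images, dtype=float)
    if X.ndim != 4 or X.shape[2:] != (64, 64):
        raise ValueError(f"expected (n, C, 64, 64) images, got {X.shape}")
    C = X.shape[1]
    rng = np.random.default_rng(seed)
    layers: list[_Layer] = [
        Conv3x3(C, 64, rng),
        BatchNorm(64),
        ReLU(),
        MaxPool2(),
        Conv3x3(64, 32, rng),
        BatchNorm(32),
        ReLU(),
        MaxPool2(),
        Flatten(),
        Dense(16 * 16 * 32, 100, rng),
        ReLU(),
        Dropout(0.5),
        Dense(100, 50, rng),
        ReLU(),
        Dropout(0.5),
        Dense(50, 2, rng),
    ]
    model = NeuralModel(layers=layers, input_shape=(C, 64, 64), seed=seed, backend="cnn")
    _fit(model, X, np.asarray(labels), epochs, lr, batch_size, rng)
    return model
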