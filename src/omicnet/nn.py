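"""A small NumPy neural-network engine for the multi-branch CNN.

Implements exactly the layers the architecture needs — 1-D convolution along
the feature axis, Leaky-ReLU, global max/mean pooling, batch normalization,
dropout, dense layers — with hand-written backpropagation, an Adam
optimizer, softmax cross-entropy and mean-squared-error losses, and
gradients with respect to the *inputs* for saliency maps. Everything is
seeded through ``numpy.random.Generator`` so that rebuilding a network with
the same seed reproduces its initial weights bit for bit.

Layers follow a uniform protocol: ``forward(x, train)`` caches whatever the
matching ``backward(dy)`` needs, and ``params()`` yields (name, value,
gradient) triples for the optimizer.
"""

from __future__ import annotations

import numpy as np


class Layer:
    """Base layer: stateless unless it owns parameters."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self):
        return []


class Conv1D(Layer):
    """1-D convolution along the feature axis, stride 1, 'same' padding.

    Input (n, length, in_channels) -> output (n, length, filters). Weights
    are He-initialized; the kernel spans ``kernel`` consecutive features
    across all input channels.
    """

    def __init__(self, in_channels: int, filters: int, kernel: int, rng: np.random.Generator):
        self.in_channels = in_channels
        self.filters = filters
        self.kernel = kernel
        fan_in = kernel * in_channels
        self.w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(kernel * in_channels, filters))
        self.b = np.zeros(filters)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def _patches(self, x: np.ndarray) -> np.ndarray:
        n, length, c = x.shape
        pl = (self.kernel - 1) // 2
        pr = self.kernel - 1 - pl
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        # (n, length, kernel, c): window j at output position i reads xp[i + j]
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        # sliding_window_view returns (n, length, c, kernel); put kernel before c
        return np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(
            n, length, self.kernel * c
        )

    def forward(self, x, train=False):
        self._x_shape = x.shape
        self._patches_cache = self._patches(x)
        return self._patches_cache @ self.w + self.b

    def backward(self, dy):
        n, length, c = self._x_shape
        patches = self._patches_cache
        self.dw += patches.reshape(-1, patches.shape[-1]).T @ dy.reshape(-1, self.filters)
        self.db += dy.sum(axis=(0, 1))
        dpatches = (dy @ self.w.T).reshape(n, length, self.kernel, c)
        pl = (self.kernel - 1) // 2
        pr = self.kernel - 1 - pl
        dxp = np.zeros((n, length + pl + pr, c))
        for j in range(self.kernel):
            dxp[:, j : j + length, :] += dpatches[:, :, j, :]
        return dxp[:, pl : pl + length, :]

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x, train=False):
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.slope * dy)


class GlobalMaxPool(Layer):
    """(n, length, channels) -> (n, channels), max over the feature axis."""

    def forward(self, x, train=False):
        self._shape = x.shape
        self._argmax = x.argmax(axis=1)
        return np.take_along_axis(x, self._argmax[:, None, :], axis=1)[:, 0, :]

    def backward(self, dy):
        dx = np.zeros(self._shape)
        np.put_along_axis(dx, self._argmax[:, None, :], dy[:, None, :], axis=1)
        return dx


class GlobalMeanPool(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.mean(axis=1)

    def backward(self, dy):
        n, length, c = self._shape
        return np.broadcast_to(dy[:, None, :] / length, self._shape).copy()


class MaxPool1D(Layer):
    """Non-overlapping windowed max along the feature axis (keeps position
    information, unlike the global pools). Pads the tail with -inf."""

    def __init__(self, pool_size: int):
        self.pool_size = pool_size

    def forward(self, x, train=False):
        n, length, c = x.shape
        self._shape = x.shape
        k = self.pool_size
        n_win = -(-length // k)
        pad = n_win * k - length
        if pad:
            x = np.pad(x, ((0, 0), (0, pad), (0, 0)), constant_values=-np.inf)
        xw = x.reshape(n, n_win, k, c)
        self._argmax = xw.argmax(axis=2)  # (n, n_win, c)
        return np.take_along_axis(xw, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        n, length, c = self._shape
        k = self.pool_size
        n_win = dy.shape[1]
        dxw = np.zeros((n, n_win, k, c))
        np.put_along_axis(dxw, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        return dxw.reshape(n, n_win * k, c)[:, :length, :]


class Flatten(Layer):
    """(n, length, channels) -> (n, length * channels)."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train=False):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.dw += self._x.T @ dy
        self.db += dy.sum(axis=0)
        return dy @ self.w.T

    def params(self):
        return [("w", self.w, self.dw), ("b", self.b, self.db)]


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class BatchNorm(Layer):
    """Batch normalization over a flat (n, dim) representation.

    Training uses batch statistics and maintains running estimates
    (momentum 0.9); inference normalizes with the running estimates, in
    which case backpropagation reduces to a per-unit rescaling.
    """

    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(dim)
        self.beta = np.zeros(dim)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x, train=False):
        self._train = train
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mu
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mu, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._istd
        return self.gamma * self._xhat + self.beta

    def backward(self, dy):
        self.dgamma += (dy * self._xhat).sum(axis=0)
        self.dbeta += dy.sum(axis=0)
        if not self._train:
            return dy * self.gamma * self._istd
        n = dy.shape[0]
        dxhat = dy * self.gamma
        return (
            self._istd
            / n
            * (n * dxhat - dxhat.sum(axis=0) - self._xhat * (dxhat * self._xhat).sum(axis=0))
        )

    def params(self):
        return [("gamma", self.gamma, self.dgamma), ("beta", self.beta, self.dbeta)]


# ---------------------------------------------------------------------------


class MultiBranchNet:
    """One convolutional branch per omics modality, pooled, concatenated,
    batch-normalized, then a dense head with dropout.

    ``forward`` takes a list of per-modality tensors (n, features, channels)
    and returns logits: (n, 2) for binary classification (softmax applied by
    the loss / ``predict_proba``) or (n, 1) for regression.
    """

    def __init__(
        self,
        input_shapes,
        task: str,
        n_conv_layers: int = 2,
        filters: int = 16,
        kernel_size: int = 5,
        pooling: str = "local",
        pool_size: int = 4,
        dense_sizes=(64, 16),
        dropout: float = 0.5,
        leaky_slope: float = 0.01,
        batch_norm: bool = True,
        seed: int = 0,
    ):
        if not 1 <= len(input_shapes) <= 3:
            raise ValueError(
                f"got {len(input_shapes)} input modalities; the network takes "
                "up to three omics types"
            )
        for length, channels in input_shapes:
            if length < 1 or channels < 1:
                raise ValueError(f"non-positive input shape ({length}, {channels})")
        if task not in ("classification", "regression"):
            raise ValueError(f"unknown task {task!r}")
        rng = np.random.default_rng(seed)
        self.task = task
        self.input_shapes = list(input_shapes)
        self.branches = []
        concat_dim = 0
        if pooling not in ("local", "max", "mean"):
            raise ValueError(f"unknown pooling mode {pooling!r}")
        for length, channels in input_shapes:
            layers = []
            in_ch = channels
            for _ in range(n_conv_layers):
                layers.append(Conv1D(in_ch, filters, kernel_size, rng))
                layers.append(LeakyReLU(leaky_slope))
                in_ch = filters
            if pooling == "local":
                layers.append(MaxPool1D(pool_size))
                layers.append(Flatten())
                concat_dim += -(-length // pool_size) * in_ch
            else:
                layers.append(GlobalMaxPool() if pooling == "max" else GlobalMeanPool())
                concat_dim += in_ch
            self.branches.append(layers)
        self.norm = BatchNorm(concat_dim) if batch_norm else None
        self.head = []
        n_in = concat_dim
        self._dropout_rng = np.random.default_rng(seed + 1)
        for size in dense_sizes:
            self.head.append(Dense(n_in, size, rng))
            self.head.append(LeakyReLU(leaky_slope))
            self.head.append(Dropout(dropout, self._dropout_rng))
            n_in = size
        self.out_dim = 2 if task == "classification" else 1
        self.head.append(Dense(n_in, self.out_dim, rng))

    # -- plumbing ----------------------------------------------------------

    def _all_layers(self):
        for branch in self.branches:
            yield from branch
        if self.norm is not None:
            yield self.norm
        yield from self.head

    def parameters(self):
        for layer in self._all_layers():
            yield from layer.params()

    def n_parameters(self) -> int:
        return sum(p.size for _, p, _ in self.parameters())

    def zero_grad(self) -> None:
        for _, _, g in self.parameters():
            g[...] = 0.0

    # -- forward / backward ------------------------------------------------

    def forward(self, xs, train: bool = False) -> np.ndarray:
        if len(xs) != len(self.branches):
            raise ValueError(
                f"expected {len(self.branches)} input tensors, got {len(xs)}"
            )
        pooled = []
        for x, branch in zip(xs, self.branches):
            h = np.asarray(x, dtype=float)
            for layer in branch:
                h = layer.forward(h, train)
            pooled.append(h)
        self._widths = [p.shape[1] for p in pooled]
        h = np.concatenate(pooled, axis=1)
        if self.norm is not None:
            h = self.norm.forward(h, train)
        for layer in self.head:
            h = layer.forward(h, train)
        return h

    def backward(self, dlogits: np.ndarray):
        """Backpropagate from d(loss)/d(logits); returns per-modality input
        gradients (also accumulates parameter gradients)."""
        d = dlogits
        for layer in reversed(self.head):
            d = layer.backward(d)
        if self.norm is not None:
            d = self.norm.backward(d)
        dxs = []
        offset = 0
        for width, branch in zip(self._widths, self.branches):
            db = d[:, offset : offset + width]
            for layer in reversed(branch):
                db = layer.backward(db)
            dxs.append(db)
            offset += width
        return dxs

    def predict_proba(self, xs) -> np.ndarray:
        if self.task != "classification":
            raise ValueError("predict_proba is for classification networks")
        return softmax(self.forward(xs, train=False))

    def predict(self, xs) -> np.ndarray:
        out = self.forward(xs, train=False)
        return out[:, 0] if self.task == "regression" else softmax(out)

    def input_gradients(self, xs, class_index: int | None = None):
        """d(score)/d(input) per modality, evaluated in inference mode.

        For classification the score is the *pre-softmax* logit of
        ``class_index`` (or of each sample's predicted class when None),
        which avoids softmax saturation; for regression it is the predicted
        value itself.
        """
        logits = self.forward(xs, train=False)
        self.zero_grad()
        seed_grad = np.zeros_like(logits)
        if self.task == "regression":
            seed_grad[:, 0] = 1.0
        else:
            if class_index is None:
                idx = logits.argmax(axis=1)
            else:
                idx = np.full(logits.shape[0], class_index)
            seed_grad[np.arange(logits.shape[0]), idx] = 1.0
        dxs = self.backward(seed_grad)
        self.zero_grad()
        return dxs


# ---------------------------------------------------------------------------
# losses and optimizer


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(logits: np.ndarray, y: np.ndarray):
    """Softmax cross-entropy. ``y`` holds integer class indices.

    Returns (mean loss, d loss / d logits)."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), y] + eps).mean()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    return loss, dlogits / n


def mse_loss(pred: np.ndarray, y: np.ndarray):
    """Mean squared error on a (n, 1) prediction column."""
    y = np.asarray(y, dtype=float).reshape(-1, 1)
    diff = pred - y
    loss = float((diff**2).mean())
    return loss, 2.0 * diff / diff.size


class Adam:
    """Adam with bias-corrected moments and decoupled weight decay.

    Weight decay is applied AdamW-style (directly to the parameters, not
    through the gradient moments) and skips biases and normalization
    parameters."""

    def __init__(
        self,
        net: MultiBranchNet,
        lr: float = 1e-3,
        beta1=0.9,
        beta2=0.999,
        eps=1e-8,
        weight_decay: float = 0.0,
    ):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p) for _, p, _ in net.parameters()]
        self.v = [np.zeros_like(p) for _, p, _ in net.parameters()]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for (name, p, g), m, v in zip(self.net.parameters(), self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and name == "w":
                p -= self.lr * self.weight_decay * p
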