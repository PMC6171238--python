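"""Minimal feed-forward / convolutional neural-network engine in numpy.

Provides exactly the pieces the diagnostic classifiers need — dense and 2D
convolutional layers (stride 1, "same" padding), batch normalisation,
inverted dropout, ReLU, a sigmoid output trained with a class-weighted
cross-entropy, Adam, and an early-stopping loop that restores the best
validation weights.  Everything is seeded through ``numpy.random.Generator``
so training is bit-reproducible.

Shapes: dense layers take (n, features); conv layers take (n, channels,
height, width).
"""

from __future__ import annotations

import copy

import numpy as np

EPS_PROB = 1e-7  # probability clipping in the loss


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Layer:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params(self) -> list[dict]:
        return []


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)  # He initialisation for ReLU stacks
        self.W = rng.standard_normal((n_in, n_out)) * scale
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x, train):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.dW = self._x.T @ grad
        self.db = grad.sum(axis=0)
        return grad @ self.W.T

    def params(self):
        return [
            {"value": self.W, "grad": self.dW},
            {"value": self.b, "grad": self.db},
        ]


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    def __init__(self, rate: float, rng: np.random.Generator):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class BatchNorm(Layer):
    """Batch normalisation over the batch (and spatial axes for conv input)."""

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(n_features)
        self.beta = np.zeros(n_features)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def _to2d(self, x):
        if x.ndim == 4:  # (n, c, h, w) -> (n*h*w, c)
            self._shape = x.shape
            return x.transpose(0, 2, 3, 1).reshape(-1, x.shape[1])
        self._shape = None
        return x

    def _from2d(self, x2):
        if self._shape is None:
            return x2
        n, c, h, w = self._shape
        return x2.reshape(n, h, w, c).transpose(0, 3, 1, 2)

    def forward(self, x, train):
        x2 = self._to2d(x)
        if train:
            mean = x2.mean(axis=0)
            var = x2.var(axis=0)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x2 - mean) / self._std
        return self._from2d(self.gamma * self._xhat + self.beta)

    def backward(self, grad):
        g2 = self._to2d(grad)
        n = g2.shape[0]
        self.dgamma = (g2 * self._xhat).sum(axis=0)
        self.dbeta = g2.sum(axis=0)
        dxhat = g2 * self.gamma
        dx = (dxhat - dxhat.mean(axis=0) - self._xhat * (dxhat * self._xhat).mean(axis=0)) / self._std
        return self._from2d(dx)

    def params(self):
        return [
            {"value": self.gamma, "grad": self.dgamma},
            {"value": self.beta, "grad": self.dbeta},
        ]


class Conv2D(Layer):
    """Stride-1 2D convolution with "same" padding, via im2col."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator):
        if kernel < 1:
            raise ValueError("kernel size must be >= 1")
        self.k = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        scale = np.sqrt(2.0 / (in_ch * kernel * kernel))
        self.W = rng.standard_normal((in_ch * kernel * kernel, out_ch)) * scale
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        pad = kernel - 1
        self._pad_before = pad // 2
        self._pad_after = pad - pad // 2

    def _im2col(self, x):
        # patch layout: (kernel offset, channel) so only k*k slice copies are
        # needed; the weight matrix rows follow the same ordering
        n, c, h, w = x.shape
        xp = np.pad(
            x,
            ((0, 0), (0, 0), (self._pad_before, self._pad_after), (self._pad_before, self._pad_after)),
        )
        k = self.k
        cols = np.empty((n, h, w, k * k * c))
        for di in range(k):
            for dj in range(k):
                off = (di * k + dj) * c
                cols[:, :, :, off : off + c] = xp[:, :, di : di + h, dj : dj + w].transpose(0, 2, 3, 1)
        return cols

    def forward(self, x, train):
        if self.k > x.shape[2] or self.k > x.shape[3]:
            raise ValueError("kernel larger than input grid")
        self._xshape = x.shape
        self._cols = self._im2col(x)  # (n, h, w, c*k*k)
        out = self._cols @ self.W + self.b  # (n, h, w, out_ch)
        return out.transpose(0, 3, 1, 2)

    def backward(self, grad):
        n, c, h, w = self._xshape
        g = grad.transpose(0, 2, 3, 1)  # (n, h, w, out_ch)
        self.dW = self._cols.reshape(-1, self.W.shape[0]).T @ g.reshape(-1, self.out_ch)
        self.db = g.sum(axis=(0, 1, 2))
        dcols = g @ self.W.T  # (n, h, w, c*k*k)
        hp = h + self._pad_before + self._pad_after
        wp = w + self._pad_before + self._pad_after
        dxp = np.zeros((n, c, hp, wp))
        k = self.k
        for di in range(k):
            for dj in range(k):
                off = (di * k + dj) * c
                dxp[:, :, di : di + h, dj : dj + w] += dcols[:, :, :, off : off + c].transpose(0, 3, 1, 2)
        return dxp[:, :, self._pad_before : self._pad_before + h, self._pad_before : self._pad_before + w]

    def params(self):
        return [
            {"value": self.W, "grad": self.dW},
            {"value": self.b, "grad": self.db},
        ]


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class Network:
    """A feature stack followed by a dense logit head, with an optional skip
    connection that concatenates the flattened raw input onto the features
    entering the first dense head layer."""

    def __init__(self, feature_layers: list[Layer], head_layers: list[Layer], skip: bool):
        self.feature_layers = feature_layers
        self.head_layers = head_layers
        self.skip = skip

    def layers(self) -> list[Layer]:
        return self.feature_layers + self.head_layers

    def params(self) -> list[dict]:
        return [p for layer in self.layers() for p in layer.params()]

    def n_params(self) -> int:
        return sum(p["value"].size for p in self.params())

    def forward_logit(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        h = x
        for layer in self.feature_layers:
            h = layer.forward(h, train)
        if h.ndim > 2:
            raise RuntimeError("feature stack must end flattened")
        if self.skip:
            raw = x.reshape(x.shape[0], -1)
            h = np.concatenate([h, raw], axis=1)
            self._n_feat = h.shape[1] - raw.shape[1]
        for layer in self.head_layers:
            h = layer.forward(h, train)
        return h[:, 0]

    def backward(self, dlogit: np.ndarray) -> None:
        g = dlogit[:, None]
        for layer in reversed(self.head_layers):
            g = layer.backward(g)
        if self.skip:
            g = g[:, : self._n_feat]
        for layer in reversed(self.feature_layers):
            g = layer.backward(g)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return sigmoid(self.forward_logit(x, train=False))

    def get_state(self) -> list[np.ndarray]:
        state = [p["value"].copy() for p in self.params()]
        for layer in self.layers():
            if isinstance(layer, BatchNorm):
                state += [layer.running_mean.copy(), layer.running_var.copy()]
        return state

    def set_state(self, state: list[np.ndarray]) -> None:
        ps = self.params()
        for p, s in zip(ps, state[: len(ps)]):
            p["value"][...] = s
        extra = state[len(ps) :]
        i = 0
        for layer in self.layers():
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = extra[i]
                layer.running_var[...] = extra[i + 1]
                i += 2


# ---------------------------------------------------------------------------
# loss and optimiser
# ---------------------------------------------------------------------------


def weighted_bce_from_logits(
    logits: np.ndarray, y: np.ndarray, w_c: float
) -> tuple[float, np.ndarray]:
    """Mean class-weighted cross-entropy and its gradient w.r.t. the logits.

    The positive-class term carries weight w_c; w_c = 1 recovers the standard
    cross-entropy.
    """
    p = np.clip(sigmoid(logits), EPS_PROB, 1 - EPS_PROB)
    loss = float(np.mean(-w_c * y * np.log(p) - (1 - y) * np.log(1 - p)))
    dlogit = (-w_c * y * (1 - p) + (1 - y) * p) / len(y)
    return loss, dlogit


class Adam:
    def __init__(self, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: list[np.ndarray] | None = None
        self.v: list[np.ndarray] | None = None

    def step(self, params: list[dict]) -> None:
        if self.m is None:
            self.m = [np.zeros_like(p["value"]) for p in params]
            self.v = [np.zeros_like(p["value"]) for p in params]
        self.t += 1
        for p, m, v in zip(params, self.m, self.v):
            g = p["grad"]
            m[...] = self.beta1 * m + (1 - self.beta1) * g
            v[...] = self.beta2 * v + (1 - self.beta2) * g**2
            mhat = m / (1 - self.beta1**self.t)
            vhat = v / (1 - self.beta2**self.t)
            p["value"] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------


def fit(
    model: Network,
    X: np.ndarray,
    y: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    w_c: float,
    max_epochs: int = 200,
    patience: int = 10,
    batch_size: int = 64,
    learning_rate: float = 1e-3,
    seed: int = 0,
) -> dict:
    """Minibatch Adam with early stopping on validation loss.

    Stops when the validation loss has not improved for ``patience`` epochs
    and restores the weights of the best epoch.  Returns a history dict with
    per-epoch train/validation losses.
    """
    rng = np.random.default_rng(seed)
    opt = Adam(lr=learning_rate)
    history: dict = {"train_loss": [], "val_loss": []}
    best_loss = np.inf
    best_state = model.get_state()
    since_best = 0
    n = len(y)
    y = np.asarray(y, dtype=float)
    y_val = np.asarray(y_val, dtype=float)
    for epoch in range(max_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            logits = model.forward_logit(X[idx], train=True)
            loss, dlogit = weighted_bce_from_logits(logits, y[idx], w_c)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {epoch}: {loss}"
                )
            model.backward(dlogit)
            opt.step(model.params())
            epoch_loss += loss * len(idx)
        val_logits = model.forward_logit(X_val, train=False)
        val_loss, _ = weighted_bce_from_logits(val_logits, y_val, w_c)
        history["train_loss"].append(epoch_loss / n)
        history["val_loss"].append(val_loss)
        if val_loss < best_loss - 1e-6:
            best_loss = val_loss
            best_state = model.get_state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
    model.set_state(best_state)
    history["best_val_loss"] = best_loss
    return history
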