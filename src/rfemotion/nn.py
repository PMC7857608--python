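"""A compact NumPy deep-learning engine for the Y-shaped fusion network.

The network fuses two branches: a 1-D branch (two Conv1D + MaxPool1D stages
with 32 then 64 feature maps, followed by an LSTM cell that consumes the
Conv1D feature sequence and keeps its last hidden state) for the time-domain
signal, and a 2-D branch (two Conv2D + MaxPool2D stages, 32 then 64 feature
maps, flattened through a dense projection) for the wavelet scaleogram
image. Branch outputs are concatenated and passed through a dense layer,
dropout and a 4-way softmax. The ECG variant omits the LSTM (its
hand-crafted feature vector is not a time sequence) and replaces the 1-D
branch with a dense branch over the selected features.

Everything is explicit NumPy: im2col convolutions, BPTT through the LSTM,
inverted dropout, Adam, softmax cross-entropy. Training is deterministic
for a fixed seed.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class TrainingDivergedError(RuntimeError):
    """Loss became non-finite during training."""


# ---------------------------------------------------------------------------
# layers


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _glorot(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        self.params["W"] = _glorot(rng, (n_in, n_out), n_in, n_out)
        self.params["b"] = np.zeros(n_out)

    def forward(self, x, train):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, grad):
        self.grads["W"] = self._x.T @ grad
        self.grads["b"] = grad.sum(axis=0)
        return grad @ self.params["W"].T


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class Dropout(Layer):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        self.p = p
        self.rng = rng

    def forward(self, x, train):
        if not train or self.p <= 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, grad):
        return grad if self._mask is None else grad * self._mask


class Conv1D(Layer):
    """Same-padding 1-D convolution; x is (N, L, C_in)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.k = kernel
        self.params["W"] = _glorot(rng, (kernel, c_in, c_out),
                                   kernel * c_in, kernel * c_out)
        self.params["b"] = np.zeros(c_out)

    def forward(self, x, train):
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, k - 1 - p), (0, 0)))
        # cols[n, l, c, i] = xp[n, l + i, c]
        cols = sliding_window_view(xp, k, axis=1)
        self._cols = cols
        self._in_shape = x.shape
        return np.einsum("nlci,icf->nlf", cols, self.params["W"],
                         optimize=True) + self.params["b"]

    def backward(self, grad):
        k = self.k
        n, L, _ = self._in_shape
        p = k // 2
        self.grads["W"] = np.einsum("nlci,nlf->icf", self._cols, grad, optimize=True)
        self.grads["b"] = grad.sum(axis=(0, 1))
        dcols = np.einsum("nlf,icf->nlci", grad, self.params["W"], optimize=True)
        dxp = np.zeros((n, L + k - 1, self._in_shape[2]))
        for i in range(k):
            dxp[:, i:i + L, :] += dcols[:, :, :, i]
        return dxp[:, p:p + L, :]


class MaxPool1D(Layer):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, train):
        n, L, c = x.shape
        L2 = L // self.size
        xr = x[:, :L2 * self.size].reshape(n, L2, self.size, c)
        self._idx = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, grad):
        n, L, c = self._in_shape
        L2 = grad.shape[1]
        out = np.zeros((n, L2, self.size, c))
        hot = np.eye(self.size)[self._idx]           # (n, L2, c, size)
        out += np.moveaxis(hot, 3, 2) * grad[:, :, None, :]
        dx = np.zeros(self._in_shape)
        dx[:, :L2 * self.size] = out.reshape(n, L2 * self.size, c)
        return dx


class Conv2D(Layer):
    """Same-padding 2-D convolution; x is (N, H, W, C_in)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        super().__init__()
        self.k = kernel
        self.params["W"] = _glorot(rng, (kernel, kernel, c_in, c_out),
                                   kernel * kernel * c_in, kernel * kernel * c_out)
        self.params["b"] = np.zeros(c_out)

    def forward(self, x, train):
        k = self.k
        p = k // 2
        xp = np.pad(x, ((0, 0), (p, k - 1 - p), (p, k - 1 - p), (0, 0)))
        cols = sliding_window_view(xp, (k, k), axis=(1, 2))  # (n, H, W, C, k, k)
        self._cols = cols
        self._in_shape = x.shape
        return np.einsum("nhwcij,ijcf->nhwf", cols, self.params["W"],
                         optimize=True) + self.params["b"]

    def backward(self, grad):
        k = self.k
        n, H, W, c = self._in_shape
        p = k // 2
        self.grads["W"] = np.einsum("nhwcij,nhwf->ijcf", self._cols, grad,
                                    optimize=True)
        self.grads["b"] = grad.sum(axis=(0, 1, 2))
        dcols = np.einsum("nhwf,ijcf->nhwcij", grad, self.params["W"], optimize=True)
        dxp = np.zeros((n, H + k - 1, W + k - 1, c))
        for i in range(k):
            for j in range(k):
                dxp[:, i:i + H, j:j + W, :] += dcols[:, :, :, :, i, j]
        return dxp[:, p:p + H, p:p + W, :]


class MaxPool2D(Layer):
    def __init__(self, size: int = 2):
        super().__init__()
        self.size = size

    def forward(self, x, train):
        s = self.size
        n, H, W, c = x.shape
        H2, W2 = H // s, W // s
        xr = (x[:, :H2 * s, :W2 * s]
              .reshape(n, H2, s, W2, s, c)
              .transpose(0, 1, 3, 2, 4, 5)
              .reshape(n, H2, W2, s * s, c))
        self._idx = xr.argmax(axis=3)
        self._in_shape = x.shape
        return xr.max(axis=3)

    def backward(self, grad):
        s = self.size
        n, H, W, c = self._in_shape
        H2, W2 = grad.shape[1], grad.shape[2]
        hot = np.eye(s * s)[self._idx]               # (n, H2, W2, c, s*s)
        scattered = np.moveaxis(hot, 4, 3) * grad[:, :, :, None, :]
        dx = np.zeros(self._in_shape)
        dx[:, :H2 * s, :W2 * s] = (scattered
                                   .reshape(n, H2, W2, s, s, c)
                                   .transpose(0, 1, 3, 2, 4, 5)
                                   .reshape(n, H2 * s, W2 * s, c))
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._in_shape)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -50, 50)))


class LSTM(Layer):
    """Single LSTM cell unrolled over the sequence; returns the last hidden
    state. x is (N, T, C_in); output (N, H). Forget-gate bias initialised
    to 1 (standard stabilisation)."""

    def __init__(self, c_in: int, hidden: int, rng: np.random.Generator):
        super().__init__()
        self.h = hidden
        self.params["Wx"] = _glorot(rng, (c_in, 4 * hidden), c_in, 4 * hidden)
        self.params["Wh"] = _glorot(rng, (hidden, 4 * hidden), hidden, 4 * hidden)
        b = np.zeros(4 * hidden)
        b[hidden:2 * hidden] = 1.0
        self.params["b"] = b

    def forward(self, x, train):
        n, T, _ = x.shape
        H = self.h
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        self._x = x
        self._cache = []
        for t in range(T):
            z = x[:, t] @ self.params["Wx"] + h @ self.params["Wh"] + self.params["b"]
            i = _sigmoid(z[:, :H])
            f = _sigmoid(z[:, H:2 * H])
            g = np.tanh(z[:, 2 * H:3 * H])
            o = _sigmoid(z[:, 3 * H:])
            c_new = f * c + i * g
            tanh_c = np.tanh(c_new)
            h_new = o * tanh_c
            self._cache.append((h, c, i, f, g, o, tanh_c))
            h, c = h_new, c_new
        return h

    def backward(self, grad):
        x = self._x
        n, T, c_in = x.shape
        H = self.h
        dWx = np.zeros_like(self.params["Wx"])
        dWh = np.zeros_like(self.params["Wh"])
        db = np.zeros_like(self.params["b"])
        dx = np.zeros_like(x)
        dh = grad
        dc = np.zeros((n, H))
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, tanh_c = self._cache[t]
            do = dh * tanh_c
            dc = dc + dh * o * (1 - tanh_c ** 2)
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dz = np.concatenate([di * i * (1 - i), df * f * (1 - f),
                                 dg * (1 - g ** 2), do * o * (1 - o)], axis=1)
            dWx += x[:, t].T @ dz
            dWh += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ self.params["Wx"].T
            dh = dz @ self.params["Wh"].T
            dc = dc * f
        self.grads["Wx"], self.grads["Wh"], self.grads["b"] = dWx, dWh, db
        return dx


# ---------------------------------------------------------------------------
# loss and optimiser


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(probs: np.ndarray, onehot: np.ndarray) -> float:
    return float(-(onehot * np.log(np.clip(probs, 1e-12, None))).sum()
                 / probs.shape[0])


class Adam:
    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.layers = layers
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        for li, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                g = layer.grads[name]
                key = (li, name)
                m = self.m.setdefault(key, np.zeros_like(p))
                v = self.v.setdefault(key, np.zeros_like(p))
                m[:] = self.b1 * m + (1 - self.b1) * g
                v[:] = self.b2 * v + (1 - self.b2) * g * g
                mhat = m / (1 - self.b1 ** self.t)
                vhat = v / (1 - self.b2 ** self.t)
                p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# the Y-shaped network


class FusionNetwork:
    """Two-branch fusion network with a 4-way softmax head.

    RF mode: ``seq_shape=(T, C)`` activates the Conv1D/MaxPool1D/LSTM branch,
    ``image_shape=(H, W)`` the Conv2D/MaxPool2D branch. ECG mode: pass
    ``feature_dim`` instead of ``seq_shape`` — the LSTM is omitted because
    the selected IBI features do not form a time sequence.
    """

    def __init__(self, image_shape: tuple[int, int],
                 seq_shape: tuple[int, int] | None = None,
                 feature_dim: int | None = None,
                 n_classes: int = 4,
                 conv_channels: tuple[int, int] = (32, 64),
                 kernel_1d: int = 7, kernel_2d: int = 3,
                 lstm_hidden: int = 64, dense_units: int = 64,
                 dropout: float = 0.25, seed: int = 0):
        if seq_shape is None and feature_dim is None:
            raise ValueError("need a 1-D sequence branch or a feature branch")
        rng = np.random.default_rng(seed)
        c1, c2 = conv_channels
        self.seq_shape = seq_shape
        self.image_shape = image_shape
        self.feature_dim = feature_dim
        self.n_classes = n_classes

        self.seq_layers: list[Layer] = []
        branch_dims = 0
        if seq_shape is not None:
            T, C = seq_shape
            self.seq_layers = [
                Conv1D(C, c1, kernel_1d, rng), ReLU(), MaxPool1D(2),
                Conv1D(c1, c2, kernel_1d, rng), ReLU(), MaxPool1D(2),
                LSTM(c2, lstm_hidden, rng),
            ]
            branch_dims += lstm_hidden

        H, W = image_shape
        flat = (H // 4) * (W // 4) * c2
        self.img_layers: list[Layer] = [
            Conv2D(1, c1, kernel_2d, rng), ReLU(), MaxPool2D(2),
            Conv2D(c1, c2, kernel_2d, rng), ReLU(), MaxPool2D(2),
            Flatten(), Dense(flat, dense_units, rng), ReLU(),
        ]
        branch_dims += dense_units

        self.feat_layers: list[Layer] = []
        if feature_dim is not None:
            self.feat_layers = [Dense(feature_dim, dense_units // 2, rng), ReLU()]
            branch_dims += dense_units // 2

        self.head_layers: list[Layer] = [
            Dense(branch_dims, dense_units, rng), ReLU(),
            Dropout(dropout, np.random.default_rng(seed + 1)),
            Dense(dense_units, n_classes, rng),
        ]

    @property
    def layers(self) -> list[Layer]:
        return self.seq_layers + self.img_layers + self.feat_layers + self.head_layers

    def n_parameters(self) -> int:
        return sum(p.size for layer in self.layers for p in layer.params.values())

    @staticmethod
    def _run(layers: list[Layer], x: np.ndarray, train: bool) -> np.ndarray:
        for layer in layers:
            x = layer.forward(x, train)
        return x

    def forward(self, inputs: dict[str, np.ndarray], train: bool = False) -> np.ndarray:
        """Class probabilities (N, n_classes).

        ``inputs`` keys: ``"image"`` (N, H, W) always; ``"seq"`` (N, T, C) in
        RF mode; ``"features"`` (N, feature_dim) in ECG mode.
        """
        parts = []
        self._split = []
        if self.seq_layers:
            out = self._run(self.seq_layers, inputs["seq"], train)
            parts.append(out)
            self._split.append(out.shape[1])
        img = inputs["image"][..., None]
        out = self._run(self.img_layers, img, train)
        parts.append(out)
        self._split.append(out.shape[1])
        if self.feat_layers:
            out = self._run(self.feat_layers, inputs["features"], train)
            parts.append(out)
            self._split.append(out.shape[1])
        fused = np.concatenate(parts, axis=1)
        logits = self._run(self.head_layers, fused, train)
        return softmax(logits)

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits
        for layer in reversed(self.head_layers):
            grad = layer.backward(grad)
        chunks = np.split(grad, np.cumsum(self._split)[:-1], axis=1)
        pos = 0
        if self.seq_layers:
            g = chunks[pos]
            pos += 1
            for layer in reversed(self.seq_layers):
                g = layer.backward(g)
        g = chunks[pos]
        pos += 1
        for layer in reversed(self.img_layers):
            g = layer.backward(g)
        if self.feat_layers:
            g = chunks[pos]
            for layer in reversed(self.feat_layers):
                g = layer.backward(g)


def train_network(net: FusionNetwork, inputs: dict[str, np.ndarray],
                  onehot: np.ndarray, epochs: int = 60, batch_size: int = 8,
                  learning_rate: float = 1e-3, seed: int = 0,
                  validation_fraction: float = 0.0, patience: int = 10,
                  ) -> dict[str, list[float]]:
    """Minimise cross-entropy with Adam; returns the training curve.

    With ``validation_fraction > 0`` a tail split is held out and training
    stops early once validation loss has not improved for ``patience``
    epochs (best parameters are restored). Deterministic for fixed seed.
    """
    rng = np.random.default_rng(seed)
    n = onehot.shape[0]
    idx = rng.permutation(n)
    n_val = int(round(validation_fraction * n))
    val_idx, train_idx = idx[:n_val], idx[n_val:]

    def subset(ids):
        return {k: v[ids] for k, v in inputs.items()}

    opt = Adam(net.layers, lr=learning_rate)
    history: dict[str, list[float]] = {"loss": [], "val_loss": []}
    best_val = np.inf
    best_params = None
    stale = 0
    for epoch in range(epochs):
        order = rng.permutation(train_idx.size)
        epoch_loss = 0.0
        for start in range(0, train_idx.size, batch_size):
            batch = train_idx[order[start:start + batch_size]]
            probs = net.forward(subset(batch), train=True)
            loss = cross_entropy(probs, onehot[batch])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}: {loss}")
            epoch_loss += loss * batch.size
            dlogits = (probs - onehot[batch]) / batch.size
            net.backward(dlogits)
            opt.step()
        history["loss"].append(epoch_loss / train_idx.size)
        if n_val > 0:
            val_probs = net.forward(subset(val_idx), train=False)
            val_loss = cross_entropy(val_probs, onehot[val_idx])
            history["val_loss"].append(val_loss)
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_params = [{k: v.copy() for k, v in layer.params.items()}
                               for layer in net.layers]
                stale = 0
            else:
                stale += 1
                if stale >= patience:
                    break
    if best_params is not None:
        for layer, saved in zip(net.layers, best_params):
            for k in layer.params:
                layer.params[k][:] = saved[k]
    return history
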