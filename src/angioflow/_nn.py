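"""Minimal seeded neural-network engine for the velocity-correction models.

Implements exactly the three small architectures the package trains
(an MLP, a 1D CNN and an LSTM over the 4-feature input) with hand-coded
backpropagation and an Adam optimizer.  Everything is plain numpy and
fully deterministic under a fixed seed, which keeps repeated
cross-validation runs byte-reproducible on a single thread.
"""

from __future__ import annotations

import numpy as np

__all__ = ["AdamOptimizer", "MLPNet", "ConvNet1D", "LSTMNet", "lstm_cell_step",
           "fit_network", "LOSS_FUNCTIONS"]


def relu(x):
    return np.maximum(x, 0.0)


def sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def mse_loss(pred, target):
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


def mae_loss(pred, target):
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


LOSS_FUNCTIONS = {"mse": mse_loss, "mae": mae_loss}


class AdamOptimizer:
    """Adam with the conventional defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict, clip_norm: float | None = 1.0):
        if clip_norm is not None:
            total = np.sqrt(sum(float(np.sum(g * g)) for g in grads.values()))
            if total > clip_norm:
                scale = clip_norm / total
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1.0 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1.0 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)


# ---------------------------------------------------------------------------
# MLP


class MLPNet:
    """Fully connected ReLU network, 4 -> hidden... -> 2, linear output.

    Dropout (default rate 0.02) is applied after the first hidden layer
    during training only, with inverted scaling.
    """

    def __init__(self, n_in: int = 4, hidden=(10,), n_out: int = 2,
                 dropout: float = 0.02, seed: int = 0):
        rng = np.random.default_rng(seed)
        dims = [n_in, *hidden, n_out]
        self.params = {}
        self.n_layers = len(dims) - 1
        for l in range(self.n_layers):
            fan_in = dims[l]
            self.params[f"W{l}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                              (dims[l], dims[l + 1]))
            self.params[f"b{l}"] = np.zeros(dims[l + 1])
        self.dropout = dropout
        self._cache = None

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        acts = [x]
        drop_mask = None
        h = x
        for l in range(self.n_layers):
            z = h @ self.params[f"W{l}"] + self.params[f"b{l}"]
            if l < self.n_layers - 1:
                h = relu(z)
                if l == 0 and train and self.dropout > 0:
                    if rng is None:
                        raise ValueError("training forward pass needs an rng")
                    drop_mask = (rng.random(h.shape) >= self.dropout) / (1.0 - self.dropout)
                    h = h * drop_mask
            else:
                h = z
            acts.append(h)
        self._cache = (acts, drop_mask)
        return h

    def backward(self, dout):
        acts, drop_mask = self._cache
        grads = {}
        dh = dout
        for l in range(self.n_layers - 1, -1, -1):
            a_in = acts[l]
            grads[f"W{l}"] = a_in.T @ dh
            grads[f"b{l}"] = dh.sum(axis=0)
            if l > 0:
                dh = dh @ self.params[f"W{l}"].T
                post = acts[l]
                if l == 1 and drop_mask is not None:
                    # acts[1] already includes the dropout scaling; the ReLU
                    # gate and mask share the same sparsity pattern
                    dh = dh * drop_mask
                dh = dh * (post > 0)
        return grads

    def predict(self, x):
        return self.forward(np.asarray(x, float), train=False)


# ---------------------------------------------------------------------------
# 1D CNN


class ConvNet1D:
    """Three same-padded 1D convolutions over the feature sequence.

    Input is the 4-feature vector viewed as a length-4, single-channel
    sequence; ReLU activations, a max-pool (k=2) after the first
    convolution, and a linear regression head.
    """

    def __init__(self, n_in: int = 4, channels=(8, 16, 16), n_out: int = 2,
                 kernel: int = 3, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.L = n_in
        self.kernel = kernel
        c0 = 1
        self.params = {}
        for i, c in enumerate(channels):
            fan_in = c0 * kernel
            self.params[f"Wc{i}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                                               (c, c0, kernel))
            self.params[f"bc{i}"] = np.zeros(c)
            c0 = c
        self.pool_len = self.L // 2
        flat = channels[-1] * self.pool_len
        self.params["Wd"] = rng.normal(0.0, np.sqrt(2.0 / flat), (flat, n_out))
        self.params["bd"] = np.zeros(n_out)
        self.n_conv = len(channels)
        self._cache = None

    @staticmethod
    def _conv(x, W, b):
        # x: (N, C_in, L) zero-padded same; W: (C_out, C_in, K)
        # im2col: one matmul per convolution instead of K shifted products
        N, C, L = x.shape
        K = W.shape[2]
        p = K // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        cols = np.lib.stride_tricks.sliding_window_view(xp, K, axis=2)  # (N,C,L,K)
        cols = cols.reshape(N, C, L, K).transpose(0, 2, 1, 3).reshape(N * L, C * K)
        out = cols @ W.reshape(W.shape[0], C * K).T                    # (N*L, O)
        out = out.reshape(N, L, W.shape[0]).transpose(0, 2, 1)
        return out + b[None, :, None], (xp, cols)

    @staticmethod
    def _conv_backward(dout, cache, W):
        xp, cols = cache
        N, C, Lp = xp.shape
        O, _, K = W.shape
        L = dout.shape[2]
        p = K // 2
        dmat = dout.transpose(0, 2, 1).reshape(N * L, O)               # (N*L, O)
        dW = (dmat.T @ cols).reshape(O, C, K)
        db = dout.sum(axis=(0, 2))
        dcols = (dmat @ W.reshape(O, C * K)).reshape(N, L, C, K)
        dxp = np.zeros_like(xp)
        for k in range(K):
            dxp[:, :, k:k + L] += dcols[:, :, :, k].transpose(0, 2, 1)
        return dW, db, dxp[:, :, p:p + L]

    def forward(self, x, train: bool = False, rng=None):
        x = np.asarray(x, float)[:, None, :]          # (N, 1, L)
        cache = {"x": x}
        h = x
        for i in range(self.n_conv):
            z, conv_cache = self._conv(h, self.params[f"Wc{i}"], self.params[f"bc{i}"])
            a = relu(z)
            cache[f"conv{i}"] = conv_cache
            cache[f"z{i}"] = z
            if i == 0:
                # max pool k=2 stride 2
                n, c, L = a.shape
                a2 = a.reshape(n, c, L // 2, 2)
                idx = a2.argmax(axis=3)
                a = a2.max(axis=3)
                cache["pool_idx"] = idx
                cache["pool_shape"] = (n, c, L)
            h = a
        flat = h.reshape(h.shape[0], -1)
        cache["flat_in"] = flat
        cache["last_shape"] = h.shape
        out = flat @ self.params["Wd"] + self.params["bd"]
        self._cache = cache
        return out

    def backward(self, dout):
        cache = self._cache
        grads = {"Wd": cache["flat_in"].T @ dout, "bd": dout.sum(axis=0)}
        dh = (dout @ self.params["Wd"].T).reshape(cache["last_shape"])
        for i in range(self.n_conv - 1, -1, -1):
            if i == 0:
                n, c, L = cache["pool_shape"]
                da = np.zeros((n, c, L // 2, 2))
                idx = cache["pool_idx"]
                nn_, cc_, pp_ = np.ogrid[:n, :c, :L // 2]
                da[nn_, cc_, pp_, idx] = dh
                dh = da.reshape(n, c, L)
            dz = dh * (cache[f"z{i}"] > 0)
            dW, db, dh = self._conv_backward(dz, cache[f"conv{i}"],
                                             self.params[f"Wc{i}"])
            grads[f"Wc{i}"] = dW
            grads[f"bc{i}"] = db
        return grads

    def predict(self, x):
        return self.forward(np.asarray(x, float), train=False)


# ---------------------------------------------------------------------------
# LSTM


def lstm_cell_step(weights: dict, x_t: np.ndarray, h_prev: np.ndarray,
                   c_prev: np.ndarray, cache: dict | None = None):
    """One LSTM cell update.

    Gates follow the standard formulation: input, forget and output gates
    are sigmoids of ``[h_prev, x_t]`` affine maps, the candidate state is
    a tanh, the cell state is ``f * c_prev + i * c_tilde`` and the output
    is ``o * tanh(c)``.  ``weights`` holds ``w_i, w_f, w_c, w_o`` of shape
    (H, H + n_in) and biases ``b_i, b_f, b_c, b_o`` of shape (H,).
    Returns ``(h_t, c_t)``; pass a dict as ``cache`` to collect the gate
    activations for backpropagation.
    """
    z = np.concatenate([h_prev, x_t], axis=-1)
    i_g = sigmoid(z @ weights["w_i"].T + weights["b_i"])
    f_g = sigmoid(z @ weights["w_f"].T + weights["b_f"])
    c_tilde = np.tanh(z @ weights["w_c"].T + weights["b_c"])
    o_g = sigmoid(z @ weights["w_o"].T + weights["b_o"])
    c_t = f_g * c_prev + i_g * c_tilde
    h_t = o_g * np.tanh(c_t)
    if cache is not None:
        cache.update(z=z, i=i_g, f=f_g, c_tilde=c_tilde, o=o_g,
                     c_prev=c_prev, c=c_t)
    return h_t, c_t


class LSTMNet:
    """LSTM over the features read as a length-4 sequence of scalars.

    The final hidden state feeds a ReLU dense layer and a linear
    2-output regression head.
    """

    def __init__(self, n_in: int = 4, hidden: int = 10, dense: int = 10,
                 n_out: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.T = n_in
        self.H = hidden
        scale = 1.0 / np.sqrt(hidden + 1)
        self.params = {}
        for g in ("i", "f", "c", "o"):
            self.params[f"w_{g}"] = rng.normal(0.0, scale, (hidden, hidden + 1))
            self.params[f"b_{g}"] = np.zeros(hidden)
        self.params["b_f"] += 1.0          # standard forget-gate bias init
        self.params["W1"] = rng.normal(0.0, np.sqrt(2.0 / hidden), (hidden, dense))
        self.params["b1"] = np.zeros(dense)
        self.params["W2"] = rng.normal(0.0, np.sqrt(2.0 / dense), (dense, n_out))
        self.params["b2"] = np.zeros(n_out)
        self._cache = None

    def forward(self, x, train: bool = False, rng=None):
        x = np.asarray(x, float)
        n = x.shape[0]
        h = np.zeros((n, self.H))
        c = np.zeros((n, self.H))
        caches = []
        for t in range(self.T):
            cache = {}
            h, c = lstm_cell_step(self.params, x[:, t:t + 1], h, c, cache)
            caches.append(cache)
        z1 = h @ self.params["W1"] + self.params["b1"]
        a1 = relu(z1)
        out = a1 @ self.params["W2"] + self.params["b2"]
        self._cache = (x, caches, h, z1, a1)
        return out

    def backward(self, dout):
        x, caches, h_last, z1, a1 = self._cache
        grads = {k: np.zeros_like(v) for k, v in self.params.items()}
        grads["W2"] = a1.T @ dout
        grads["b2"] = dout.sum(axis=0)
        da1 = dout @ self.params["W2"].T
        dz1 = da1 * (z1 > 0)
        grads["W1"] = h_last.T @ dz1
        grads["b1"] = dz1.sum(axis=0)
        dh = dz1 @ self.params["W1"].T
        dc = np.zeros_like(dh)
        for t in range(self.T - 1, -1, -1):
            cc = caches[t]
            tanh_c = np.tanh(cc["c"])
            do = dh * tanh_c
            dc = dc + dh * cc["o"] * (1.0 - tanh_c**2)
            di = dc * cc["c_tilde"]
            df = dc * cc["c_prev"]
            dct = dc * cc["i"]
            dc_prev = dc * cc["f"]
            dzi = di * cc["i"] * (1.0 - cc["i"])
            dzf = df * cc["f"] * (1.0 - cc["f"])
            dzc = dct * (1.0 - cc["c_tilde"]**2)
            dzo = do * cc["o"] * (1.0 - cc["o"])
            z = cc["z"]
            dz = np.zeros_like(z)
            for name, dg in (("i", dzi), ("f", dzf), ("c", dzc), ("o", dzo)):
                grads[f"w_{name}"] += dg.T @ z
                grads[f"b_{name}"] += dg.sum(axis=0)
                dz += dg @ self.params[f"w_{name}"]
            dh = dz[:, : self.H]
            dc = dc_prev
        return grads

    def predict(self, x):
        return self.forward(np.asarray(x, float), train=False)


# ---------------------------------------------------------------------------
# Training loop


def fit_network(net, x, y, loss: str = "mae", epochs: int = 100,
                batch_size: int = 32, lr: float = 1e-3, seed: int = 0,
                history: list | None = None, lr_decay: bool = True):
    """Mini-batch Adam training, deterministic under the seed.

    A cosine decay of the learning rate to 2% of its initial value is on
    by default: the MAE loss has constant-magnitude gradients, so without
    decay Adam dithers around the optimum with amplitude ~lr instead of
    converging.  Raises on a NaN loss (diverged optimization) rather than
    returning a silently broken model.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    loss_fn = LOSS_FUNCTIONS[loss]
    rng = np.random.default_rng(seed)
    opt = AdamOptimizer(net.params, lr=lr)
    n = x.shape[0]
    for epoch in range(epochs):
        if lr_decay:
            frac = epoch / max(epochs - 1, 1)
            opt.lr = lr * (0.02 + 0.98 * 0.5 * (1.0 + np.cos(np.pi * frac)))
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            pred = net.forward(x[idx], train=True, rng=rng)
            value, dout = loss_fn(pred, y[idx])
            if not np.isfinite(value):
                raise FloatingPointError(
                    f"loss became non-finite at epoch {epoch}")
            grads = net.backward(dout)
            opt.step(net.params, grads)
            epoch_loss += value
            n_batches += 1
        if history is not None:
            history.append(epoch_loss / max(n_batches, 1))
    return net
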