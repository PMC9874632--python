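"""Minimal NumPy layers with exact analytic gradients.

Only what the multiplet labeler needs: a bank of parallel same-padded
1-D convolutions over a single input channel, time-distributed dense
layers, a bidirectional LSTM, and elementwise activations.  Every layer
implements ``forward(x)`` (caching what backward needs) and
``backward(dy)`` (returning ``dx`` and filling ``grads``).  Gradients
are verified against central finite differences in the test suite.

Shapes follow the sequence-labeling convention ``(batch, time, channels)``;
the raw spectrum enters as ``(batch, time)``.
"""

from __future__ import annotations

import numpy as np


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int, dtype):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int, dtype):
    a = rng.normal(size=(max(rows, cols), min(rows, cols)))
    q, _ = np.linalg.qr(a)
    return np.ascontiguousarray(q[:rows, :cols]).astype(dtype)


def _sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Layer:
    """Base: parameter/grad dicts keyed by name."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def n_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def zero_grad(self) -> None:
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class ConvBank(Layer):
    """Parallel 1-D convolutions on one input channel, channel-concatenated.

    Each branch is a same-padded convolution with its own kernel size and
    ``filters`` output channels, followed by ELU.  Output has
    ``len(kernel_sizes) * filters`` channels, aligned 1:1 with the input
    points (zero padding: ``(k-1)//2`` left, ``k//2`` right).
    """

    def __init__(self, kernel_sizes, filters: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.kernel_sizes = tuple(int(k) for k in kernel_sizes)
        self.filters = int(filters)
        self.dtype = dtype
        for k in self.kernel_sizes:
            self.params[f"W{k}"] = _glorot(rng, (k, filters), k, filters, dtype)
            self.params[f"b{k}"] = np.zeros(filters, dtype=dtype)
        self.zero_grad()

    @property
    def out_channels(self) -> int:
        return len(self.kernel_sizes) * self.filters

    def _windows(self, x: np.ndarray, k: int) -> np.ndarray:
        b, t = x.shape
        left, right = (k - 1) // 2, k // 2
        xp = np.zeros((b, t + k - 1), dtype=x.dtype)
        xp[:, left : left + t] = x
        return np.lib.stride_tricks.sliding_window_view(xp, k, axis=1)  # (B, T, k)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 2:
            raise ValueError("ConvBank expects (batch, time) input")
        if x.shape[1] < max(self.kernel_sizes):
            raise ValueError(
                f"input length {x.shape[1]} is shorter than the largest "
                f"kernel {max(self.kernel_sizes)}"
            )
        x = x.astype(self.dtype, copy=False)
        self._x = x
        outs, caches = [], []
        for k in self.kernel_sizes:
            win = self._windows(x, k)
            z = win @ self.params[f"W{k}"] + self.params[f"b{k}"]
            a = np.where(z > 0, z, np.expm1(z))  # ELU
            outs.append(a)
            caches.append(z)
        self._z = caches
        return np.concatenate(outs, axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, t = self._x.shape
        dx = np.zeros_like(self._x)
        for i, k in enumerate(self.kernel_sizes):
            dyk = dy[..., i * self.filters : (i + 1) * self.filters]
            z = self._z[i]
            dz = dyk * np.where(z > 0, 1.0, np.exp(np.minimum(z, 0.0)))
            win = self._windows(self._x, k)
            self.grads[f"W{k}"] += np.einsum("btk,btf->kf", win, dz)
            self.grads[f"b{k}"] += dz.sum(axis=(0, 1))
            dwin = dz @ self.params[f"W{k}"].T  # (B, T, k)
            left = (k - 1) // 2
            dxp = np.zeros((b, t + k - 1), dtype=self.dtype)
            for j in range(k):
                dxp[:, j : j + t] += dwin[:, :, j]
            dx += dxp[:, left : left + t]
        return dx


class Dense(Layer):
    """Time-distributed affine map with optional activation.

    Acts on the last axis, so the same weights apply at every time step.
    ``activation`` is one of None, "relu", "elu".
    """

    def __init__(
        self,
        d_in: int,
        d_out: int,
        rng: np.random.Generator,
        activation: str | None = None,
        dtype=np.float32,
    ):
        super().__init__()
        self.activation = activation
        self.params["W"] = _glorot(rng, (d_in, d_out), d_in, d_out, dtype)
        self.params["b"] = np.zeros(d_out, dtype=dtype)
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        z = x @ self.params["W"] + self.params["b"]
        self._z = z
        if self.activation == "relu":
            return np.maximum(z, 0.0)
        if self.activation == "elu":
            return np.where(z > 0, z, np.expm1(z))
        return z

    def backward(self, dy: np.ndarray) -> np.ndarray:
        z = self._z
        if self.activation == "relu":
            dz = dy * (z > 0)
        elif self.activation == "elu":
            dz = dy * np.where(z > 0, 1.0, np.exp(np.minimum(z, 0.0)))
        else:
            dz = dy
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dz2 = dz.reshape(-1, dz.shape[-1])
        self.grads["W"] += x2.T @ dz2
        self.grads["b"] += dz2.sum(axis=0)
        return dz @ self.params["W"].T


class _LSTMDirection(Layer):
    """One direction of an LSTM; gate order (i, f, g, o), single bias.

    Forget-gate bias initialized to 1 to ease early gradient flow.
    """

    def __init__(self, d_in: int, units: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.units = units
        self.params["Wx"] = _glorot(rng, (d_in, 4 * units), d_in, units, dtype)
        self.params["Wh"] = np.concatenate(
            [_orthogonal(rng, units, units, dtype) for _ in range(4)], axis=1
        )
        b = np.zeros(4 * units, dtype=dtype)
        b[units : 2 * units] = 1.0
        self.params["b"] = b
        self.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t, _ = x.shape
        u = self.units
        zin = x @ self.params["Wx"] + self.params["b"]  # (B, T, 4U)
        Wh = self.params["Wh"]
        h = np.zeros((b, u), dtype=x.dtype)
        c = np.zeros((b, u), dtype=x.dtype)
        I = np.empty((b, t, u), dtype=x.dtype)
        F = np.empty_like(I)
        G = np.empty_like(I)
        O = np.empty_like(I)
        C = np.empty_like(I)
        TC = np.empty_like(I)
        H = np.empty_like(I)
        for step in range(t):
            z = zin[:, step] + h @ Wh
            i = _sigmoid(z[:, :u])
            f = _sigmoid(z[:, u : 2 * u])
            g = np.tanh(z[:, 2 * u : 3 * u])
            o = _sigmoid(z[:, 3 * u :])
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            I[:, step], F[:, step], G[:, step], O[:, step] = i, f, g, o
            C[:, step], TC[:, step], H[:, step] = c, tc, h
        self._cache = (x, I, F, G, O, C, TC, H)
        return H

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, I, F, G, O, C, TC, H = self._cache
        b, t, _ = x.shape
        u = self.units
        Wh = self.params["Wh"]
        dZ = np.empty((b, t, 4 * u), dtype=x.dtype)
        dh_next = np.zeros((b, u), dtype=x.dtype)
        dc_next = np.zeros((b, u), dtype=x.dtype)
        dWh = np.zeros_like(Wh)
        for step in range(t - 1, -1, -1):
            i, f, g, o = I[:, step], F[:, step], G[:, step], O[:, step]
            c, tc = C[:, step], TC[:, step]
            c_prev = C[:, step - 1] if step > 0 else np.zeros_like(c)
            h_prev = H[:, step - 1] if step > 0 else np.zeros_like(dh_next)
            dh = dy[:, step] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [
                    di * i * (1.0 - i),
                    df * f * (1.0 - f),
                    dg * (1.0 - g * g),
                    do * o * (1.0 - o),
                ],
                axis=1,
            )
            dZ[:, step] = dz
            dWh += h_prev.T @ dz
            dh_next = dz @ Wh.T
        x2 = x.reshape(-1, x.shape[-1])
        dz2 = dZ.reshape(-1, 4 * u)
        self.grads["Wx"] += x2.T @ dz2
        self.grads["Wh"] += dWh
        self.grads["b"] += dz2.sum(axis=0)
        return dZ @ self.params["Wx"].T


class BiLSTM(Layer):
    """Bidirectional LSTM, outputs concatenated: ``(B, T, 2*units)``."""

    def __init__(self, d_in: int, units: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.fwd = _LSTMDirection(d_in, units, rng, dtype)
        self.bwd = _LSTMDirection(d_in, units, rng, dtype)

    @property
    def sublayers(self):
        return (self.fwd, self.bwd)

    def n_parameters(self) -> int:
        return self.fwd.n_parameters() + self.bwd.n_parameters()

    def zero_grad(self) -> None:
        self.fwd.zero_grad()
        self.bwd.zero_grad()

    def forward(self, x: np.ndarray) -> np.ndarray:
        hf = self.fwd.forward(x)
        hb = self.bwd.forward(x[:, ::-1])[:, ::-1]
        return np.concatenate([hf, hb], axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        u = self.fwd.units
        dxf = self.fwd.backward(np.ascontiguousarray(dy[..., :u]))
        dxb = self.bwd.backward(np.ascontiguousarray(dy[:, ::-1, u:]))[:, ::-1]
        return dxf + dxb


class Pool1D(Layer):
    """Pool the time axis by an integer factor (no parameters).

    ``mode`` is "max" (default; preserves sharp peak-detector responses
    that mean-pooling would dilute) or "mean".  A trailing partial
    window is padded by edge replication.  Shortening the sequence
    before the recurrent layer cuts CPU cost and eases long-range peak
    counting; predictions are brought back to full resolution by
    :class:`LinearUpsample1D`.
    """

    def __init__(self, factor: int, mode: str = "max"):
        super().__init__()
        if factor < 1:
            raise ValueError("pool factor must be >= 1")
        if mode not in ("max", "mean"):
            raise ValueError("pool mode must be 'max' or 'mean'")
        self.factor = factor
        self.mode = mode

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.factor == 1:
            return x
        b, t, c = x.shape
        self._t = t
        pad = (-t) % self.factor
        if pad:
            x = np.concatenate([x, np.repeat(x[:, -1:], pad, axis=1)], axis=1)
        self._tp = x.shape[1]
        xw = x.reshape(b, self._tp // self.factor, self.factor, c)
        if self.mode == "mean":
            return xw.mean(axis=2)
        self._argmax = xw.argmax(axis=2)  # (B, T/f, C)
        return np.take_along_axis(xw, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.factor == 1:
            return dy
        b, tp_f, c = dy.shape
        if self.mode == "mean":
            dxp = np.repeat(dy / self.factor, self.factor, axis=1)
        else:
            dxw = np.zeros((b, tp_f, self.factor, c), dtype=dy.dtype)
            np.put_along_axis(dxw, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
            dxp = dxw.reshape(b, self._tp, c)
        dx = dxp[:, : self._t]
        extra = dxp[:, self._t :]
        if extra.shape[1]:
            dx = dx.copy()
            dx[:, -1] += extra.sum(axis=1)
        return dx


class LinearUpsample1D(Layer):
    """Linearly interpolate a pooled sequence back to a target length.

    Output position ``i`` reads pooled coordinate ``(i + 0.5)/factor - 0.5``
    (bin centers), clamped at the ends; backward scatters the same weights.
    """

    def __init__(self, factor: int):
        super().__init__()
        self.factor = factor

    def set_target_length(self, t: int) -> None:
        self._t = t

    def forward(self, z: np.ndarray) -> np.ndarray:
        if self.factor == 1:
            return z
        b, tp, c = z.shape
        s = (np.arange(self._t) + 0.5) / self.factor - 0.5
        s = np.clip(s, 0.0, tp - 1.0)
        lo = np.floor(s).astype(int)
        hi = np.minimum(lo + 1, tp - 1)
        w = (s - lo)[None, :, None]
        self._cache = (lo, hi, w, tp)
        return (1.0 - w) * z[:, lo] + w * z[:, hi]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.factor == 1:
            return dy
        lo, hi, w, tp = self._cache
        b, _, c = dy.shape
        dz = np.zeros((b, tp, c), dtype=dy.dtype)
        np.add.at(dz, (slice(None), lo), (1.0 - w) * dy)
        np.add.at(dz, (slice(None), hi), w * dy)
        return dz


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_with_softmax(
    logits: np.ndarray, labels: np.ndarray, class_weights: np.ndarray | None = None
) -> tuple[float, np.ndarray, np.ndarray]:
    """(Optionally class-weighted) mean per-point categorical cross-entropy.

    Returns (loss, probabilities, dlogits) with the gradient already
    averaged over all points (weights normalized to mean 1), ready for
    backprop.
    """
    probs = softmax(logits)
    idx = tuple(np.indices(labels.shape)) + (labels,)
    logp = -np.log(np.clip(probs[idx], 1e-12, None))
    dlogits = probs.copy()
    dlogits[idx] -= 1.0
    if class_weights is None:
        n = int(np.prod(labels.shape))
        return float(np.mean(logp)), probs, dlogits / n
    w = np.asarray(class_weights, dtype=probs.dtype)[labels]
    wsum = float(w.sum())
    loss = float((w * logp).sum() / wsum)
    return loss, probs, dlogits * (w / wsum)[..., None]
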