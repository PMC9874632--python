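"""Point-wise sequence labeler: conv bank -> dense -> BiLSTM -> dense stack -> softmax.

The model maps a spectrum of any length N (N at least the largest conv
kernel) to an N x n_classes row-stochastic matrix, one probability row
per spectral point.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BiLSTM,
    ConvBank,
    Dense,
    LinearUpsample1D,
    Pool1D,
    cross_entropy_with_softmax,
    softmax,
)


class SequenceLabeler:
    """The assembled network.

    Structure (activations in parentheses): parallel Conv1D bank (ELU),
    time-distributed dense (ELU), bidirectional LSTM, a strictly
    decreasing time-distributed dense stack (ReLU on all but the last,
    which feeds the softmax output).
    """

    def __init__(
        self,
        kernel_sizes=(4, 16, 64, 256),
        conv_filters: int = 16,
        post_conv_dense: int = 64,
        lstm_units: int = 256,
        lstm_layers: int = 1,
        dense_stack=(512, 454, 136, 8),
        temporal_pool: int = 1,
        seed: int = 0,
        dtype=np.float32,
    ):
        rng = np.random.default_rng(seed)
        self.dtype = dtype
        self.kernel_sizes = tuple(kernel_sizes)
        self.n_classes = int(dense_stack[-1])
        self.conv = ConvBank(kernel_sizes, conv_filters, rng, dtype)
        self.pool = Pool1D(temporal_pool)
        self.upsample = LinearUpsample1D(temporal_pool)
        self.pre = Dense(self.conv.out_channels, post_conv_dense, rng, activation="elu", dtype=dtype)
        self.lstms = [BiLSTM(post_conv_dense, lstm_units, rng, dtype)]
        for _ in range(lstm_layers - 1):
            self.lstms.append(BiLSTM(2 * lstm_units, lstm_units, rng, dtype))
        self.lstm = self.lstms[0]
        stack = []
        d_in = 2 * lstm_units
        for i, d_out in enumerate(dense_stack):
            act = "relu" if i < len(dense_stack) - 1 else None
            stack.append(Dense(d_in, int(d_out), rng, activation=act, dtype=dtype))
            d_in = int(d_out)
        self.stack = stack
        self.layers = [self.conv, self.pre, *self.lstms, *stack]
        self.temporal_pool = temporal_pool

    # -- parameter plumbing -------------------------------------------------

    def _flat_layers(self):
        for layer in self.layers:
            if isinstance(layer, BiLSTM):
                yield from layer.sublayers
            else:
                yield layer

    def n_parameters(self) -> int:
        return sum(layer.n_parameters() for layer in self.layers)

    def parameters(self):
        """Yield (key, array) pairs for every trainable tensor."""
        for i, layer in enumerate(self._flat_layers()):
            for name, p in layer.params.items():
                yield f"{i}:{name}", p

    def gradients(self):
        for i, layer in enumerate(self._flat_layers()):
            for name, g in layer.grads.items():
                yield f"{i}:{name}", g

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        for key, p in self.parameters():
            v = values[key]
            if v.shape != p.shape:
                raise ValueError(f"shape mismatch for {key}: {v.shape} vs {p.shape}")
            p[...] = v.astype(self.dtype)

    def get_parameters(self) -> dict[str, np.ndarray]:
        return {k: p.copy() for k, p in self.parameters()}

    def zero_grad(self) -> None:
        for layer in self.layers:
            layer.zero_grad()

    # -- forward / backward -------------------------------------------------

    def forward_logits(self, x: np.ndarray) -> np.ndarray:
        """Logits for a (batch, time) intensity matrix: (batch, time, n_classes)."""
        x = np.asarray(x, dtype=self.dtype)
        if x.ndim == 1:
            x = x[None, :]
        h = self.conv.forward(x)
        self.upsample.set_target_length(h.shape[1])
        h = self.pool.forward(h)
        h = self.pre.forward(h)
        for lstm in self.lstms:
            h = lstm.forward(h)
        for layer in self.stack:
            h = layer.forward(h)
        return self.upsample.forward(h)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Row-stochastic class probabilities, shape (batch, time, n_classes)."""
        return softmax(self.forward_logits(x))

    def loss_and_backward(
        self, x: np.ndarray, labels: np.ndarray, class_weights: np.ndarray | None = None
    ) -> tuple[float, np.ndarray]:
        """Mean cross-entropy and its accumulated parameter gradients.

        Returns (loss, probabilities); gradients are left in the layers
        for the optimizer to consume.
        """
        logits = self.forward_logits(x)
        labels = np.asarray(labels)
        if labels.ndim == 1:
            labels = labels[None, :]
        if labels.min() < 0 or labels.max() >= self.n_classes:
            raise ValueError("labels outside {0..n_classes-1}")
        loss, probs, dlogits = cross_entropy_with_softmax(logits, labels, class_weights)
        grad = dlogits.astype(self.dtype)
        grad = self.upsample.backward(grad)
        for layer in reversed(self.stack):
            grad = layer.backward(grad)
        for lstm in reversed(self.lstms):
            grad = lstm.backward(grad)
        grad = self.pre.backward(grad)
        grad = self.pool.backward(grad)
        self.conv.backward(grad)
        return loss, probs
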