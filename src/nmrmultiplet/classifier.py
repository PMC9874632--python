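"""Point-wise multiplet classifier: configuration, training, prediction.

The network is an Inception-style bank of four parallel 1-D
convolutions (kernel sizes 4/16/64/256, 16 filters each, ELU) feeding a
time-distributed dense layer, a bidirectional LSTM, and a decreasing
dense stack ending in an 8-way softmax, one probability row per
spectral point.  The default hidden sizes give exactly 1,225,606
trainable weights.

Training minimizes mean per-point categorical cross-entropy with Adam.
Inference is a single full-length pass: the architecture is
length-agnostic, so arbitrarily long spectra are classified after
resampling to the training point density (5 points per Hz).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, SequenceLabeler
from .simulate import LabeledDataset

MODEL_FORMAT_VERSION = 1
TRAINING_POINTS_PER_HZ = 1024 / 204.8  # 5 points per Hz


@dataclass(frozen=True)
class NetworkConfig:
    """Structural hyperparameters of the sequence labeler."""

    conv_kernel_sizes: tuple[int, ...] = (4, 16, 64, 256)
    conv_filters_each: int = 16
    post_conv_dense_units: int = 64
    lstm_units_per_direction: int = 256
    lstm_layers: int = 1
    dense_stack_units: tuple[int, ...] = (512, 454, 136, 8)
    n_classes: int = 8
    temporal_pool: int = 1  # >1 pools time before the LSTM, upsampling the logits

    def __post_init__(self):
        stack = self.dense_stack_units
        if stack[-1] != self.n_classes:
            raise ValueError("dense stack must end at n_classes")
        if any(a <= b for a, b in zip(stack, stack[1:])):
            raise ValueError("dense stack must be strictly decreasing")
        if min(
            (self.conv_filters_each, self.post_conv_dense_units, self.lstm_units_per_direction)
            + stack
        ) < 1:
            raise ValueError("all unit counts must be positive")

    @classmethod
    def compact(cls) -> "NetworkConfig":
        """The desk-scale configuration (~0.5 M weights, temporal pool 8).

        Used by the scaled-down learning-sanity protocol; trains in
        minutes on one CPU core.
        """
        return cls(
            conv_filters_each=16,
            post_conv_dense_units=64,
            lstm_units_per_direction=192,
            dense_stack_units=(192, 96, 8),
            temporal_pool=8,
        )

    @classmethod
    def tiny(cls) -> "NetworkConfig":
        """A minimal configuration for smoke tests and quick demos."""
        return cls(
            conv_filters_each=8,
            post_conv_dense_units=32,
            lstm_units_per_direction=48,
            dense_stack_units=(64, 32, 8),
            temporal_pool=8,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = dict(d)
        for name in ("conv_kernel_sizes", "dense_stack_units"):
            d[name] = tuple(d[name])
        return cls(**d)


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization protocol; the reference protocol ran 33 epochs."""

    n_epochs: int = 33
    batch_size: int = 64
    optimizer: str = "adam"
    learning_rate: float = 1e-3
    lr_schedule: str = "constant"  # or "cosine" (decay to 2% of the base rate)
    validation_fraction: float = 0.25
    seed: int = 0
    class_weights: tuple[float, ...] | None = None
    clip_norm: float = 5.0
    normalization: str = "max-abs"  # or "max-abs-sqrt" (signed square-root compression)

    def __post_init__(self):
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if not 0.0 < self.validation_fraction < 1.0:
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.optimizer != "adam":
            raise ValueError("only the adam optimizer is implemented")
        if self.lr_schedule not in ("constant", "cosine"):
            raise ValueError("lr_schedule must be 'constant' or 'cosine'")
        if self.normalization not in ("max-abs", "max-abs-sqrt"):
            raise ValueError("normalization must be 'max-abs' or 'max-abs-sqrt'")


@dataclass
class PredictionResult:
    """Per-point softmax rows and the argmax label vector."""

    probabilities: np.ndarray  # (n_points, n_classes), rows on the simplex
    labels: np.ndarray  # (n_points,), values in {0..n_classes-1}

    def __post_init__(self):
        if self.probabilities.shape[0] != self.labels.shape[0]:
            raise ValueError("probabilities and labels disagree on point count")


@dataclass
class TrainedClassifier:
    """Network config + learned weights + normalization convention + history."""

    network: NetworkConfig
    weights: dict[str, np.ndarray]
    normalization: str = "max-abs"
    history: dict = field(default_factory=dict)

    def to_model(self) -> SequenceLabeler:
        """Materialize the network (cached; invalidated when weights are replaced)."""
        cached = getattr(self, "_model", None)
        if cached is None or getattr(self, "_model_weights", None) is not self.weights:
            model = build_network(self.network)
            model.set_parameters(self.weights)
            self._model = model
            self._model_weights = self.weights
        return self._model


def build_network(config: NetworkConfig, seed: int = 0, dtype=np.float32) -> SequenceLabeler:
    """Instantiate an untrained model from ``config``."""
    return SequenceLabeler(
        kernel_sizes=config.conv_kernel_sizes,
        conv_filters=config.conv_filters_each,
        post_conv_dense=config.post_conv_dense_units,
        lstm_units=config.lstm_units_per_direction,
        lstm_layers=config.lstm_layers,
        dense_stack=config.dense_stack_units,
        temporal_pool=config.temporal_pool,
        seed=seed,
        dtype=dtype,
    )


def count_parameters(model_or_config) -> int:
    """Total trainable scalar weights, summed over all layers."""
    if isinstance(model_or_config, NetworkConfig):
        model_or_config = build_network(model_or_config)
    return int(model_or_config.n_parameters())


def normalize_segment(intensity: np.ndarray) -> np.ndarray:
    """Scale a spectrum to unit maximum absolute intensity (all-zero passes through)."""
    x = np.asarray(intensity, dtype=float)
    if x.size == 0:
        raise ValueError("empty intensity vector")
    top = np.max(np.abs(x))
    return x if top == 0 else x / top


def apply_normalization(intensity: np.ndarray, convention: str) -> np.ndarray:
    """Apply a named input-normalization convention.

    ``max-abs`` divides by the maximum absolute intensity;
    ``max-abs-sqrt`` additionally applies a signed square root, a
    compressive display-style scaling that evens out the high dynamic
    range between strong and weak multiplets.
    """
    x = normalize_segment(intensity)
    if convention == "max-abs":
        return x
    if convention == "max-abs-sqrt":
        return np.sign(x) * np.sqrt(np.abs(x))
    raise ValueError(f"unknown normalization convention {convention!r}")


def _normalized_matrix(segments, convention: str = "max-abs") -> np.ndarray:
    return np.stack(
        [apply_normalization(s.intensity, convention) for s in segments]
    ).astype(np.float32)


def train(
    model: SequenceLabeler,
    dataset: LabeledDataset,
    tconfig: TrainingConfig,
    network_config: NetworkConfig | None = None,
    log=None,
) -> TrainedClassifier:
    """Train ``model`` on the dataset's train split, tracking the validation split.

    Segments are normalized with the configured convention, shuffled
    each epoch with a seeded RNG, and consumed in mini-batches.  Per-epoch train/validation loss
    and point-wise accuracy are recorded in the returned history.
    """
    train_ds = dataset.subset("train")
    val_ds = dataset.subset("validation")
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("dataset must provide non-empty train and validation splits")

    x_train = _normalized_matrix(train_ds.segments, tconfig.normalization)
    y_train = train_ds.label_matrix()
    x_val = _normalized_matrix(val_ds.segments, tconfig.normalization)
    y_val = val_ds.label_matrix()
    if y_train.max() >= model.n_classes or y_train.min() < 0:
        raise ValueError("labels outside the model's class set")

    weights = None
    if tconfig.class_weights is not None:
        weights = np.asarray(tconfig.class_weights, dtype=np.float32)
        if weights.shape != (model.n_classes,):
            raise ValueError("class_weights must have one entry per class")
    opt = Adam(model, learning_rate=tconfig.learning_rate, clip_norm=tconfig.clip_norm)
    rng = np.random.default_rng(tconfig.seed)
    history = {"train_loss": [], "train_accuracy": [], "val_loss": [], "val_accuracy": []}
    batches_per_epoch = int(np.ceil(len(x_train) / tconfig.batch_size))
    total_steps = batches_per_epoch * tconfig.n_epochs
    step = 0

    for epoch in range(tconfig.n_epochs):
        order = rng.permutation(len(x_train))
        losses, correct, total = [], 0, 0
        for start in range(0, len(order), tconfig.batch_size):
            if tconfig.lr_schedule == "cosine":
                frac = step / max(1, total_steps - 1)
                opt.lr = tconfig.learning_rate * (0.02 + 0.98 * 0.5 * (1 + np.cos(np.pi * frac)))
            step += 1
            idx = order[start : start + tconfig.batch_size]
            model.zero_grad()
            loss, probs = model.loss_and_backward(x_train[idx], y_train[idx], weights)
            opt.step()
            losses.append(loss * idx.size)
            correct += int((probs.argmax(-1) == y_train[idx]).sum())
            total += int(y_train[idx].size)
        vl, va = evaluate_loss(model, x_val, y_val, tconfig.batch_size)
        history["train_loss"].append(float(np.sum(losses) / len(order)))
        history["train_accuracy"].append(correct / total)
        history["val_loss"].append(vl)
        history["val_accuracy"].append(va)
        if log is not None:
            log(
                f"epoch {epoch + 1}/{tconfig.n_epochs} "
                f"loss {history['train_loss'][-1]:.4f} acc {history['train_accuracy'][-1]:.4f} "
                f"val_loss {vl:.4f} val_acc {va:.4f}"
            )

    return TrainedClassifier(
        network=network_config if network_config is not None else _infer_config(model),
        weights=model.get_parameters(),
        normalization=tconfig.normalization,
        history=history,
    )


def _infer_config(model: SequenceLabeler) -> NetworkConfig:
    return NetworkConfig(
        conv_kernel_sizes=model.kernel_sizes,
        conv_filters_each=model.conv.filters,
        post_conv_dense_units=model.pre.params["W"].shape[1],
        lstm_units_per_direction=model.lstm.fwd.units,
        lstm_layers=len(model.lstms),
        dense_stack_units=tuple(layer.params["W"].shape[1] for layer in model.stack),
        n_classes=model.n_classes,
        temporal_pool=model.temporal_pool,
    )


def evaluate_loss(model: SequenceLabeler, x: np.ndarray, y: np.ndarray, batch_size: int = 64):
    """Mean cross-entropy and point accuracy without touching gradients."""
    losses, correct, total = [], 0, 0
    for start in range(0, len(x), batch_size):
        probs = model.predict_proba(x[start : start + batch_size])
        yy = y[start : start + batch_size]
        idx = tuple(np.indices(yy.shape)) + (yy,)
        losses.append(float(-np.log(np.clip(probs[idx], 1e-12, None)).sum()))
        correct += int((probs.argmax(-1) == yy).sum())
        total += int(yy.size)
    return float(np.sum(losses) / total), correct / total


def predict(classifier: TrainedClassifier | SequenceLabeler, intensity: np.ndarray) -> PredictionResult:
    """Classify every point of one spectrum.

    The intensity is normalized with the classifier's stored convention;
    ties in the argmax resolve to the lowest class index.
    """
    if isinstance(classifier, TrainedClassifier):
        model = classifier.to_model()
        convention = classifier.normalization
    else:
        model = classifier
        convention = "max-abs"
    x = apply_normalization(np.asarray(intensity, dtype=float), convention)
    if x.size < max(model.kernel_sizes):
        raise ValueError(
            f"input has {x.size} points but the largest conv kernel is "
            f"{max(model.kernel_sizes)}; provide a longer spectrum"
        )
    probs = model.predict_proba(x[None, :])[0]
    labels = probs.argmax(axis=-1)  # np.argmax takes the first (lowest) index on ties
    return PredictionResult(probabilities=probs, labels=labels)


def resample_spectrum(
    axis_hz: np.ndarray,
    intensity: np.ndarray,
    target_points_per_hz: float = TRAINING_POINTS_PER_HZ,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly resample onto a uniform grid at the target point density.

    Returns (new axis, new intensity, back-map) where ``back_map[i]`` is
    the resampled index nearest to original point ``i``, letting
    predicted labels be reported on the original grid.
    """
    axis_hz = np.asarray(axis_hz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    d = np.diff(axis_hz)
    if len(axis_hz) < 2 or not (np.all(d > 0) or np.all(d < 0)):
        raise ValueError("axis must be strictly monotone with at least two points")
    if target_points_per_hz <= 0:
        raise ValueError("target density must be positive")
    if d[0] < 0:  # accept descending input, work ascending
        axis_hz, intensity = axis_hz[::-1], intensity[::-1]
    span = axis_hz[-1] - axis_hz[0]
    n_new = max(2, int(round(span * target_points_per_hz)) + 1)
    new_axis = np.linspace(axis_hz[0], axis_hz[-1], n_new)
    new_intensity = np.interp(new_axis, axis_hz, intensity)
    step = new_axis[1] - new_axis[0]
    back_map = np.clip(np.round((axis_hz - new_axis[0]) / step).astype(int), 0, n_new - 1)
    return new_axis, new_intensity, back_map


def majority_filter(labels: np.ndarray, window: int) -> np.ndarray:
    """Replace each label by the modal label of its centered window.

    Edge windows are truncated; when the mode ties, the original label
    is kept.  A window of 1 is the identity.  Smooths out fragmented
    single-point misclassifications inside signal regions.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")
    labels = np.asarray(labels)
    if window == 1:
        return labels.copy()
    half = window // 2
    n = len(labels)
    out = labels.copy()
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        counts = np.bincount(labels[lo:hi])
        top = counts.max()
        winners = np.flatnonzero(counts == top)
        if len(winners) == 1:
            out[i] = winners[0]
        # ties keep the original label
    return out


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------


def _config_hash(network: NetworkConfig) -> str:
    return hashlib.sha256(json.dumps(network.to_dict(), sort_keys=True).encode()).hexdigest()


def save_classifier(classifier: TrainedClassifier, path) -> None:
    """Write weights + config + normalization tag + history to one ``.npz`` archive."""
    header = {
        "format_version": MODEL_FORMAT_VERSION,
        "network": classifier.network.to_dict(),
        "config_hash": _config_hash(classifier.network),
        "normalization": classifier.normalization,
        "history": classifier.history,
    }
    arrays = {f"w::{k}": v for k, v in classifier.weights.items()}
    np.savez(path, __header__=np.frombuffer(json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_classifier(path) -> TrainedClassifier:
    """Load a model archive, refusing mismatched versions or config hashes."""
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {header.get('format_version')!r}"
            )
        network = NetworkConfig.from_dict(header["network"])
        if _config_hash(network) != header["config_hash"]:
            raise ValueError("model archive is corrupt: config hash mismatch")
        weights = {k[3:]: data[k] for k in data.files if k.startswith("w::")}
    clf = TrainedClassifier(
        network=network,
        weights=weights,
        normalization=header["normalization"],
        history=header.get("history", {}),
    )
    clf.to_model()  # raises if weight shapes do not match the config
    return clf
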