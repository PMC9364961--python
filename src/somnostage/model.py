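"""The parallel CNN-LSTM sleep-stage classifier.

The network scores one 30-s two-channel (EEG, EOG) epoch, presented as a
300 x 2 matrix (30 s at the 10 Hz model rate), with two branches over the
same input:

* an LSTM branch — two stacked 64-unit LSTM layers, the first emitting its
  full hidden sequence (300 x 64), the second reduced to its final hidden
  state (64), capturing the epoch's temporal evolution;
* a CNN branch — conv(64 filters, kernel 5) -> batch norm -> ReLU ->
  dropout -> max-pool(3), then conv(32, 5) -> batch norm -> ReLU ->
  dropout -> max-pool(3) -> flatten, capturing local waveform morphology.
  With no padding and stride 1 the temporal lengths run
  300 -> 296 -> 98 -> 94 -> 31, so the flattened CNN feature is
  31 x 32 = 992 wide.

The branch outputs are concatenated (992 + 64 = 1056) and passed through
two ReLU fully connected layers (64, 32) with dropout to a five-way softmax
over {W, N1, N2, N3, REM}; the predicted stage is the argmax.

``shape_trace`` computes the per-layer output dimensions from a
configuration without instantiating parameters, and the realized forward
pass is required to match it exactly — that contract is what pins the
architecture.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
from scipy.signal import decimate

from . import nn
from .stages import STAGE_ORDER, StageLabel
from .synth import EpochRecord

__all__ = [
    "ModelConfig",
    "ShapeTrace",
    "shape_trace",
    "StagerModel",
    "build_model",
    "predict",
    "save_checkpoint",
    "load_checkpoint",
]

CHECKPOINT_VERSION = 1


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; defaults are the canonical model."""

    input_len: int = 300
    input_channels: int = 2
    lstm_units: int = 64
    lstm_layers: int = 2
    conv_specs: tuple[tuple[int, int], ...] = ((64, 5), (32, 5))  # (filters, kernel)
    pool_size: int = 3
    fc_sizes: tuple[int, ...] = (64, 32)
    n_classes: int = 5
    dropout_conv: float = 0.20
    dropout_fc: float = 0.50
    batchnorm: bool = True
    use_attention_pool: bool = False
    #: Input scale: raw microvolt samples are divided by this constant so
    #: network activations start out order-one.
    input_scale_uv: float = 100.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "conv_specs",
                           tuple((int(f), int(k)) for f, k in self.conv_specs))
        object.__setattr__(self, "fc_sizes", tuple(int(s) for s in self.fc_sizes))
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if min(self.input_len, self.input_channels, self.lstm_units,
               self.lstm_layers, self.n_classes) < 1:
            raise ValueError("all architecture sizes must be >= 1")
        for p in (self.dropout_conv, self.dropout_fc):
            if not 0.0 <= p < 1.0:
                raise ValueError("dropout probabilities must be in [0, 1)")


@dataclass
class ShapeTrace:
    """Ordered (layer name, output shape) list implied by a configuration."""

    entries: list[tuple[str, tuple[int, ...]]]

    def shape_of(self, name: str) -> tuple[int, ...]:
        for n, s in self.entries:
            if n == name:
                return s
        raise KeyError(name)

    def __iter__(self):
        return iter(self.entries)


def shape_trace(config: ModelConfig) -> ShapeTrace:
    """Per-layer output dimensions under the architecture's composition rules.

    Convolution (valid, stride 1): L -> L - kernel + 1.  Max pooling
    (stride = pool size): L -> floor(L / pool).  Flatten: final length x
    final filters.  Concatenate: flatten + LSTM output width.  Raises
    ``ValueError`` naming the first layer whose length collapses to <= 0.
    """
    entries: list[tuple[str, tuple[int, ...]]] = [
        ("input", (config.input_len, config.input_channels))
    ]
    for i in range(1, config.lstm_layers):
        entries.append((f"lstm{i}", (config.input_len, config.lstm_units)))
    entries.append((f"lstm{config.lstm_layers}", (config.lstm_units,)))

    length = config.input_len
    filters = config.input_channels
    for i, (f, k) in enumerate(config.conv_specs, start=1):
        length = length - k + 1
        if length <= 0:
            raise ValueError(
                f"conv{i}: kernel {k} collapses temporal length to {length}"
            )
        filters = f
        entries.append((f"conv{i}", (length, filters)))
        length = length // config.pool_size
        if length <= 0:
            raise ValueError(
                f"pool{i}: pool size {config.pool_size} collapses temporal "
                f"length to {length}"
            )
        entries.append((f"pool{i}", (length, filters)))
    flat = length * filters
    entries.append(("flatten", (flat,)))
    entries.append(("concatenate", (flat + config.lstm_units,)))
    for i, size in enumerate(config.fc_sizes, start=1):
        entries.append((f"fc{i}", (size,)))
    entries.append(("softmax", (config.n_classes,)))
    return ShapeTrace(entries)


class StagerModel:
    """Trainable parameter container for the parallel CNN-LSTM network."""

    def __init__(self, config: ModelConfig, seed: int = 0) -> None:
        self.config = config
        self.trace = shape_trace(config)  # validates the configuration
        rng = np.random.default_rng(seed)

        self.lstm_layers = []
        in_dim = config.input_channels
        for li in range(config.lstm_layers):
            last = li == config.lstm_layers - 1
            self.lstm_layers.append(
                nn.LSTMLayer(
                    in_dim, config.lstm_units, rng,
                    time_major_in=li > 0,
                    # attention pooling consumes batch-major sequences
                    time_major_out=not (last and config.use_attention_pool),
                    needs_input_grad=li > 0,
                )
            )
            in_dim = config.lstm_units
        self.attention = (
            nn.AttentionPool(config.lstm_units, rng)
            if config.use_attention_pool else None
        )

        self.conv_stack: list[nn.Layer] = []
        channels = config.input_channels
        for ci, (f, k) in enumerate(config.conv_specs):
            self.conv_stack.append(
                nn.Conv1D(channels, f, k, rng, needs_input_grad=ci > 0))
            if config.batchnorm:
                self.conv_stack.append(nn.BatchNorm1D(f))
            self.conv_stack.append(nn.ReLULayer())
            self.conv_stack.append(nn.Dropout(config.dropout_conv))
            self.conv_stack.append(nn.MaxPool1D(config.pool_size))
            channels = f

        self.fc_stack: list[nn.Layer] = []
        width = self.trace.shape_of("concatenate")[0]
        for size in config.fc_sizes:
            self.fc_stack.append(nn.Dense(width, size, rng, activation="relu"))
            self.fc_stack.append(nn.Dropout(config.dropout_fc))
            width = size
        # zero-initialized output layer: an untrained model scores all five
        # stages uniformly
        self.out_layer = nn.Dense(width, config.n_classes, rng, zero_init=True)

        self.last_shapes: list[tuple[str, tuple[int, ...]]] = []

    # -- plumbing ----------------------------------------------------------

    def _all_layers(self) -> list[nn.Layer]:
        layers = list(self.lstm_layers)
        if self.attention is not None:
            layers.append(self.attention)
        layers += self.conv_stack + self.fc_stack + [self.out_layer]
        return layers

    def parameters(self) -> list[tuple[nn.Layer, str]]:
        return [(layer, name) for layer in self._all_layers()
                for name in layer.params]

    def zero_grads(self) -> None:
        for layer in self._all_layers():
            layer.zero_grads()

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, training: bool = False,
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Logits for a batch.  ``x`` is (B, input_len, channels) in uV."""
        cfg = self.config
        if x.ndim != 3 or x.shape[1:] != (cfg.input_len, cfg.input_channels):
            raise ValueError(
                f"expected input of shape (B, {cfg.input_len}, "
                f"{cfg.input_channels}), got {x.shape}"
            )
        x = (x / cfg.input_scale_uv).astype(np.float32)
        shapes = [("input", x.shape[1:])]

        h = x
        for i, layer in enumerate(self.lstm_layers, start=1):
            h = layer.forward(h, training, rng)
            if i < len(self.lstm_layers):
                # hidden sequences are carried time-major between layers
                shapes.append((f"lstm{i}", (h.shape[0], h.shape[2])))
        if self.attention is not None:
            lstm_out = self.attention.forward(h, training, rng)
        else:
            lstm_out = h[-1]  # final hidden state of the time-major sequence
        shapes.append((f"lstm{len(self.lstm_layers)}", lstm_out.shape[1:]))

        c = x
        conv_i = 0
        for layer in self.conv_stack:
            c = layer.forward(c, training, rng)
            if isinstance(layer, nn.Conv1D):
                conv_i += 1
                shapes.append((f"conv{conv_i}", c.shape[1:]))
            elif isinstance(layer, nn.MaxPool1D):
                shapes.append((f"pool{conv_i}", c.shape[1:]))
        self._conv_out_shape = c.shape
        flat = c.reshape(c.shape[0], -1)
        shapes.append(("flatten", flat.shape[1:]))

        z = np.concatenate([flat, lstm_out], axis=1)
        shapes.append(("concatenate", z.shape[1:]))
        self._concat_split = flat.shape[1]
        fc_i = 0
        for layer in self.fc_stack:
            z = layer.forward(z, training, rng)
            if isinstance(layer, nn.Dense):
                fc_i += 1
                shapes.append((f"fc{fc_i}", z.shape[1:]))
        logits = self.out_layer.forward(z, training, rng)
        shapes.append(("softmax", logits.shape[1:]))
        self.last_shapes = shapes
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.out_layer.backward(dlogits.astype(np.float32))
        for layer in reversed(self.fc_stack):
            d = layer.backward(d)
        split = self._concat_split
        dflat, dlstm_out = d[:, :split], d[:, split:]

        dc = dflat.reshape(self._conv_out_shape)
        for layer in reversed(self.conv_stack):
            dc = layer.backward(dc)

        if self.attention is not None:
            dh = self.attention.backward(dlstm_out)
        else:
            B, T = dlogits.shape[0], self.config.input_len
            dh = np.zeros((T, B, self.config.lstm_units), dtype=np.float32)
            dh[-1] = dlstm_out
        for layer in reversed(self.lstm_layers):
            dh = layer.backward(dh)

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Inference-mode class probabilities for (N, L, C) input."""
        out = []
        for start in range(0, x.shape[0], batch_size):
            logits = self.forward(x[start:start + batch_size], training=False)
            out.append(nn.softmax(logits, axis=1))
        return np.concatenate(out, axis=0)


def build_model(config: ModelConfig, seed: int = 0) -> StagerModel:
    """Instantiate a model with seed-deterministic initial parameters."""
    return StagerModel(config, seed=seed)


def epochs_to_input(records: Sequence[EpochRecord],
                    config: ModelConfig) -> np.ndarray:
    """Stack epochs into the (N, input_len, channels) model input tensor.

    Epochs sampled faster than the model rate (input_len / 30 s) are
    anti-alias decimated by the integer factor; epochs already at the model
    rate pass through.  A non-integer rate ratio or channel mismatch raises
    ``ValueError`` naming the epoch index.
    """
    target_len = config.input_len
    out = np.empty((len(records), target_len, config.input_channels))
    for idx, rec in enumerate(records):
        if rec.samples.shape[1] != config.input_channels:
            raise ValueError(
                f"epoch {idx}: has {rec.samples.shape[1]} channels, "
                f"model expects {config.input_channels}"
            )
        n = rec.samples.shape[0]
        if n == target_len:
            out[idx] = rec.samples
            continue
        if n % target_len != 0:
            raise ValueError(
                f"epoch {idx}: {n} samples not an integer multiple of the "
                f"model input length {target_len}"
            )
        q = n // target_len
        out[idx] = decimate(rec.samples, q, axis=0, ftype="fir", zero_phase=True)
    return out


def predict(
    model: StagerModel,
    epochs: Sequence[EpochRecord],
    batch_size: int = 256,
) -> tuple[list[StageLabel], np.ndarray]:
    """Score epochs: stage = argmax of the softmax probabilities.

    Returns (labels, probabilities); dropout is inactive and batch
    normalization uses running statistics, so repeated calls are identical.
    """
    x = epochs_to_input(epochs, model.config)
    probs = model.predict_proba(x, batch_size=batch_size)
    labels = [STAGE_ORDER[int(k)] for k in np.argmax(probs, axis=1)]
    return labels, probs


# -- checkpointing ---------------------------------------------------------

def save_checkpoint(model: StagerModel, path) -> None:
    """Serialize parameters + config to a single .npz archive."""
    arrays: dict[str, np.ndarray] = {}
    for li, layer in enumerate(model._all_layers()):
        for name, value in layer.params.items():
            arrays[f"layer{li:03d}/{name}"] = value
        if isinstance(layer, nn.BatchNorm1D):
            arrays[f"layer{li:03d}/running_mean"] = layer.running_mean
            arrays[f"layer{li:03d}/running_var"] = layer.running_var
    meta = json.dumps({"version": CHECKPOINT_VERSION,
                       "config": asdict(model.config)})
    arrays["__meta__"] = np.frombuffer(meta.encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path) -> StagerModel:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"unsupported checkpoint version {meta.get('version')!r}"
            )
        cfg_dict = meta["config"]
        cfg_dict["conv_specs"] = tuple(tuple(p) for p in cfg_dict["conv_specs"])
        cfg_dict["fc_sizes"] = tuple(cfg_dict["fc_sizes"])
        config = ModelConfig(**cfg_dict)
        model = StagerModel(config, seed=0)
        for li, layer in enumerate(model._all_layers()):
            for name in layer.params:
                layer.params[name] = data[f"layer{li:03d}/{name}"].copy()
            if isinstance(layer, nn.BatchNorm1D):
                layer.running_mean = data[f"layer{li:03d}/running_mean"].copy()
                layer.running_var = data[f"layer{li:03d}/running_var"].copy()
    return model
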