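"""VGG-16-style 1-D convolutional network, implemented on NumPy.

The diagnostic classifier is a 1-D adaptation of VGG-16: 13 convolutional
layers (kernel size 3, same-length padding, ReLU) arranged in five blocks of
2x64, 2x128, 3x256, 3x512 and 3x512 channels, a max-pool (size 2, stride 2)
after each block, and three fully connected layers with 50% dropout, ending
in a softmax over the tissue classes. Convolutions are evaluated as a single
matrix product per layer (im2col), which keeps CPU training practical.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["CNNConfig", "CNNModel", "build_model", "reduced_config", "TrainingError"]

_DTYPE = np.float32


class TrainingError(RuntimeError):
    """Raised when optimization diverges; carries the history so far."""

    def __init__(self, message: str, history: dict | None = None):
        super().__init__(message)
        self.history = history


@dataclass(frozen=True)
class CNNConfig:
    """Architecture and optimization settings.

    ``conv_plan`` lists (layers, channels) per block; the default plan gives
    13 convolutional layers and 5 pooling stages. ``channel_divisor`` scales
    all widths down uniformly for the reduced (desk-scale) profile without
    changing the layer count.
    """

    conv_plan: tuple[tuple[int, int], ...] = ((2, 64), (2, 128), (3, 256), (3, 512), (3, 512))
    kernel_size: int = 3
    fc_plan: tuple[int, ...] = (256, 128)
    dropout_rate: float = 0.5
    learning_rate: float = 1e-4
    batch_size: int = 128
    n_epochs: int = 50
    optimizer: str = "adam"
    channel_divisor: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout rate must lie in [0, 1)")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel size must be odd (same-length padding)")
        if self.channel_divisor < 1:
            raise ValueError("channel divisor must be >= 1")

    @property
    def n_conv_layers(self) -> int:
        return sum(n for n, _ in self.conv_plan)

    @property
    def n_pool_layers(self) -> int:
        return len(self.conv_plan)

    def block_channels(self) -> list[list[int]]:
        return [
            [max(ch // self.channel_divisor, 1)] * n for n, ch in self.conv_plan
        ]

    def fc_widths(self) -> list[int]:
        return [max(w // self.channel_divisor, 2) for w in self.fc_plan]


def reduced_config(n_epochs: int = 30, **overrides) -> CNNConfig:
    """Desk-scale profile: all widths divided by 4, shorter but brisker training.

    The smaller cohorts this profile is meant for yield few minibatches per
    epoch, so it takes a slightly larger Adam step (3e-4) than the full
    profile's 1e-4 to reach convergence within its epoch budget.
    """
    overrides.setdefault("learning_rate", 3e-4)
    return CNNConfig(channel_divisor=4, n_epochs=n_epochs, **overrides)


# ---------------------------------------------------------------------------
# layers


class _Conv1d:
    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * k))
        self.W = (rng.standard_normal((c_out, c_in * k)) * scale).astype(_DTYPE)
        self.b = np.zeros(c_out, dtype=_DTYPE)
        self.k = k
        self.c_in = c_in
        self.params = {"W": "W", "b": "b"}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        # x: (N, C, L) -> (N, C_out, L), stride 1, same padding
        n, c, length = x.shape
        pad = self.k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        cols = sliding_window_view(xp, self.k, axis=2)  # (N, C, L, k)
        cols = cols.transpose(0, 2, 1, 3).reshape(n * length, c * self.k)
        self._cols = cols
        self._shape = (n, c, length)
        out = cols @ self.W.T + self.b
        return out.reshape(n, length, -1).transpose(0, 2, 1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, length = self._shape
        d = dout.transpose(0, 2, 1).reshape(n * length, -1)
        self.dW = (d.T @ self._cols).astype(_DTYPE)
        self.db = d.sum(axis=0).astype(_DTYPE)
        dcols = (d @ self.W).reshape(n, length, c, self.k).transpose(0, 2, 1, 3)
        pad = self.k // 2
        dxp = np.zeros((n, c, length + 2 * pad), dtype=_DTYPE)
        for j in range(self.k):
            dxp[:, :, j : j + length] += dcols[:, :, :, j]
        return dxp[:, :, pad : pad + length]


class _ReLU:
    params: dict = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class _MaxPool1d:
    """Pool size 2, stride 2; an odd trailing element is dropped (floor)."""

    params: dict = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, length = x.shape
        lout = length // 2
        v = x[:, :, : lout * 2].reshape(n, c, lout, 2)
        self._arg = v.argmax(axis=3)
        self._in_len = length
        return v.max(axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, lout = dout.shape
        dx = np.zeros((n, c, self._in_len), dtype=_DTYPE)
        base = np.arange(lout) * 2
        idx = base[None, None, :] + self._arg
        np.put_along_axis(
            dx, idx.reshape(n, c, lout), dout, axis=2
        )
        return dx


class _Flatten:
    params: dict = {}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class _Dense:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / d_in)
        self.W = (rng.standard_normal((d_out, d_in)) * scale).astype(_DTYPE)
        self.b = np.zeros(d_out, dtype=_DTYPE)
        self.params = {"W": "W", "b": "b"}

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.dW = (dout.T @ self._x).astype(_DTYPE)
        self.db = dout.sum(axis=0).astype(_DTYPE)
        return dout @ self.W


class _Dropout:
    params: dict = {}

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(_DTYPE) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# model


class CNNModel:
    """The instantiated network plus everything learned during training.

    Attributes populated by :func:`ramanhisto.cnn.train`: ``history``
    (per-epoch train/val loss and accuracy), ``classes`` (label order of the
    softmax output) and the input standardization statistics.
    """

    def __init__(self, config: CNNConfig, input_length: int, n_classes: int):
        min_len = 2**config.n_pool_layers
        if input_length < max(min_len, 32):
            raise ValueError(
                f"input length {input_length} too short for {config.n_pool_layers} pooling stages"
            )
        self.config = config
        self.input_length = int(input_length)
        self.n_classes = int(n_classes)
        self.rng = np.random.default_rng(config.seed)
        self.history: dict | None = None
        self.classes: list | None = None
        self.input_mean: np.ndarray | None = None
        self.input_std: np.ndarray | None = None

        layers: list = []
        c_in, length = 1, input_length
        self.block_lengths = []
        for block in config.block_channels():
            for c_out in block:
                layers.append(_Conv1d(c_in, c_out, config.kernel_size, self.rng))
                layers.append(_ReLU())
                c_in = c_out
            layers.append(_MaxPool1d())
            length //= 2
            self.block_lengths.append(length)
        layers.append(_Flatten())
        d_in = c_in * length
        for width in config.fc_widths():
            layers.append(_Dense(d_in, width, self.rng))
            layers.append(_ReLU())
            layers.append(_Dropout(config.dropout_rate, self.rng))
            d_in = width
        layers.append(_Dense(d_in, n_classes, self.rng))
        self.layers = layers

    # -- introspection ------------------------------------------------------
    @property
    def n_conv_layers(self) -> int:
        return sum(isinstance(l, _Conv1d) for l in self.layers)

    @property
    def n_pool_layers(self) -> int:
        return sum(isinstance(l, _MaxPool1d) for l in self.layers)

    @property
    def n_fc_layers(self) -> int:
        return sum(isinstance(l, _Dense) for l in self.layers)

    def architecture_manifest(self) -> list[str]:
        """Plain-text layer listing (for checkpoints and reports)."""
        lines = []
        for l in self.layers:
            if isinstance(l, _Conv1d):
                lines.append(f"Conv1d(out={l.W.shape[0]}, k={l.k}, same-pad) + ReLU")
            elif isinstance(l, _MaxPool1d):
                lines.append("MaxPool1d(size=2, stride=2)")
            elif isinstance(l, _Dense):
                lines.append(f"Dense(out={l.W.shape[0]})")
            elif isinstance(l, _Dropout):
                lines.append(f"Dropout(rate={l.rate})")
        lines.append("Softmax")
        return lines

    # -- computation --------------------------------------------------------
    def logits(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        out = np.asarray(X, dtype=_DTYPE)[:, None, :]  # (N, 1, L)
        for layer in self.layers:
            out = layer.forward(out, train)
        return out

    def forward_proba(self, X: np.ndarray, train: bool = False) -> np.ndarray:
        return _softmax(self.logits(X, train))

    def backward(self, dlogits: np.ndarray) -> None:
        d = dlogits.astype(_DTYPE)
        for layer in reversed(self.layers):
            d = layer.backward(d)

    def parameters(self):
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def get_state(self) -> list[np.ndarray]:
        return [copy.deepcopy(getattr(l, n)) for l, n in self.parameters()]

    def set_state(self, state: list[np.ndarray]) -> None:
        for (layer, name), value in zip(self.parameters(), state):
            setattr(layer, name, value.copy())


def build_model(
    config: CNNConfig | None = None, input_length: int = 889, n_classes: int = 2
) -> CNNModel:
    """Instantiate the (untrained) network for a given spectrum length."""
    return CNNModel(config or CNNConfig(), input_length, n_classes)
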