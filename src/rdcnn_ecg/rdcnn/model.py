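"""Network assembly, feature extraction and (de)serialization.

Layer order: input -> initial 1-D convolution (stem, no batch norm) ->
alternating residual and dense blocks with optional max pooling between
blocks -> global average pooling -> fully-connected head with ReLU ->
dropout -> softmax output.  The rectified head activations are the
learned feature vector handed to the downstream classifier.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass

import numpy as np

from .blocks import DenseBlock, ResidualBlock
from .layers import (
    Conv1D,
    Dense,
    Dropout,
    GlobalAvgPool,
    MaxPool1D,
    ReLU,
    softmax,
)

_ARCHIVE_VERSION = "rdcnn-1"


class ModelConfigError(ValueError):
    """Raised for inconsistent architecture settings."""


@dataclass(frozen=True)
class RDCNNConfig:
    """Architecture hyperparameters of the residual-dense network."""

    num_res_blocks: int = 2
    num_dense_blocks: int = 2
    num_res_layers: int = 2
    num_dense_layers: int = 2
    filters: int = 63
    kernel: int = 3
    head_units: int = 64
    dropout_rate: float = 0.3
    pool_between_blocks: bool = True
    pool_size: int = 2
    pool_stride: int = 2
    n_classes: int = 5
    dense_connectivity: str = "full"  # {"full", "last-only"}

    def validate(self) -> None:
        if self.num_res_blocks < 0 or self.num_dense_blocks < 0:
            raise ModelConfigError("block counts must be >= 0")
        if self.num_res_blocks > 0 and self.num_res_layers < 1:
            raise ModelConfigError("num_res_layers must be >= 1 when using residual blocks")
        if self.num_dense_blocks > 0 and self.num_dense_layers < 1:
            raise ModelConfigError("num_dense_layers must be >= 1 when using dense blocks")
        if min(self.filters, self.kernel, self.head_units, self.n_classes) < 1:
            raise ModelConfigError("filters, kernel, head_units, n_classes must be >= 1")
        if not (0.0 <= self.dropout_rate < 1.0):
            raise ModelConfigError("dropout_rate must be in [0, 1)")
        if self.dense_connectivity not in ("full", "last-only"):
            raise ModelConfigError(
                f"unknown dense_connectivity {self.dense_connectivity!r}"
            )


class RDCNNModel:
    """Network state: ordered layers, weights, and training history."""

    def __init__(self, config: RDCNNConfig, beat_length: int, seed: int = 0) -> None:
        config.validate()
        if beat_length < 1:
            raise ModelConfigError("beat_length must be >= 1")
        self.config = config
        self.beat_length = beat_length
        self.seed = seed
        self.history: dict[str, list[float]] = {
            "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [],
        }
        rng = np.random.default_rng(seed)

        self.stem = Conv1D(1, config.filters, config.kernel, rng)
        self.trunk: list = []  # blocks and pooling layers, in order
        length = beat_length
        channels = config.filters
        kinds = _interleave(config.num_res_blocks, config.num_dense_blocks)
        for i, kind in enumerate(kinds):
            if i > 0 and config.pool_between_blocks:
                pool = MaxPool1D(config.pool_size, config.pool_stride)
                length = pool.out_length(length)
                if length < 1:
                    raise ModelConfigError(
                        "pooling reduces the temporal length below 1 sample"
                    )
                self.trunk.append(pool)
            if kind == "res":
                block = ResidualBlock(
                    channels, config.num_res_layers, config.filters, config.kernel, rng
                )
            else:
                block = DenseBlock(
                    channels,
                    config.num_dense_layers,
                    config.filters,
                    config.kernel,
                    rng,
                    config.dense_connectivity,
                )
            channels = block.out_channels
            self.trunk.append(block)
        self.gap = GlobalAvgPool()
        self.head = Dense(channels, config.head_units, rng)
        self.head_relu = ReLU()
        self.dropout = Dropout(config.dropout_rate)
        self.out = Dense(config.head_units, config.n_classes, rng)
        self.feature_dim = config.head_units
        self.trunk_channels = channels

    # ----- forward / backward -------------------------------------------

    def forward(
        self,
        beats: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Logits for a (n_beats, beat_length) batch."""
        x = self._check_input(beats)[..., None]
        x = self.stem.forward(x, training)
        for item in self.trunk:
            x = item.forward(x, training)
        z = self.gap.forward(x, training)
        h = self.head_relu.forward(self.head.forward(z, training), training)
        h = self.dropout.forward(h, training, rng)
        return self.out.forward(h, training)

    def backward(self, glogits: np.ndarray) -> None:
        g = self.out.backward(glogits)
        g = self.dropout.backward(g)
        g = self.head.backward(self.head_relu.backward(g))
        g = self.gap.backward(g)
        for item in reversed(self.trunk):
            g = item.backward(g)
        self.stem.backward(g)

    def predict_proba(self, beats: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities (softmax), dropout disabled."""
        beats = self._check_input(beats)
        chunks = [
            softmax(self.forward(beats[i : i + batch_size]))
            for i in range(0, beats.shape[0], batch_size)
        ]
        return np.vstack(chunks)

    def features(self, beats: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Rectified head activations, (n_beats, head_units), deterministic."""
        beats = self._check_input(beats)
        out = np.empty((beats.shape[0], self.feature_dim))
        for i in range(0, beats.shape[0], batch_size):
            x = beats[i : i + batch_size][..., None]
            x = self.stem.forward(x)
            for item in self.trunk:
                x = item.forward(x)
            z = self.gap.forward(x)
            out[i : i + batch_size] = self.head_relu.forward(self.head.forward(z))
        return out

    # ----- bookkeeping ---------------------------------------------------

    def named_layers(self):
        """Deterministic (name, layer) walk over every parameterized layer."""
        yield "stem", self.stem
        for i, item in enumerate(self.trunk):
            if isinstance(item, (ResidualBlock, DenseBlock)):
                prefix = f"block{i}"
                for sub, layer in item.iter_layers():
                    yield f"{prefix}.{sub}", layer
        yield "head", self.head
        yield "out", self.out

    def get_weights(self) -> dict[str, np.ndarray]:
        flat = {}
        for name, layer in self.named_layers():
            for key, val in layer.params.items():
                flat[f"{name}.{key}"] = val.copy()
            for key, val in layer.state.items():
                flat[f"{name}.{key}"] = val.copy()
        return flat

    def set_weights(self, flat: dict[str, np.ndarray]) -> None:
        for name, layer in self.named_layers():
            for key in layer.params:
                layer.params[key] = flat[f"{name}.{key}"].copy()
            for key in layer.state:
                layer.state[key] = flat[f"{name}.{key}"].copy()

    def _check_input(self, beats: np.ndarray) -> np.ndarray:
        beats = np.asarray(beats, dtype=float)
        if beats.ndim == 1:
            beats = beats[None, :]
        if beats.shape[1] != self.beat_length:
            raise ValueError(
                f"model expects beat length {self.beat_length}, "
                f"got {beats.shape[1]}"
            )
        return beats


def _interleave(n_res: int, n_dense: int) -> list[str]:
    """Alternating res/dense order, leftovers of the larger count appended."""
    kinds = []
    for i in range(max(n_res, n_dense)):
        if i < n_res:
            kinds.append("res")
        if i < n_dense:
            kinds.append("dense")
    return kinds


def build_model(config: RDCNNConfig, beat_length: int, seed: int = 0) -> RDCNNModel:
    """Assemble an untrained network with seeded weight initialization."""
    return RDCNNModel(config, beat_length, seed)


def extract_features(model: RDCNNModel, beats: np.ndarray) -> np.ndarray:
    """Learned feature matrix: rectified fully-connected head activations."""
    return model.features(beats)


def count_parameters(model: RDCNNModel) -> tuple[int, dict[str, int]]:
    """Total trainable scalar count with a per-layer breakdown."""
    breakdown = {name: layer.n_params() for name, layer in model.named_layers()}
    return int(sum(breakdown.values())), breakdown


def save_model(model: RDCNNModel, path) -> None:
    """Serialize config + weights + history to a single .npz archive."""
    meta = {
        "version": _ARCHIVE_VERSION,
        "config": asdict(model.config),
        "beat_length": model.beat_length,
        "seed": model.seed,
        "history": model.history,
    }
    arrays = {f"w::{k}": v for k, v in model.get_weights().items()}
    np.savez(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_model(path) -> RDCNNModel:
    """Rebuild a model from a :func:`save_model` archive."""
    with np.load(path) as archive:
        meta = json.loads(archive["meta"].tobytes().decode())
        if meta.get("version") != _ARCHIVE_VERSION:
            raise ValueError(f"unsupported model archive version {meta.get('version')}")
        model = RDCNNModel(
            RDCNNConfig(**meta["config"]), meta["beat_length"], meta["seed"]
        )
        model.history = meta["history"]
        weights = {
            k[len("w::"):]: archive[k] for k in archive.files if k.startswith("w::")
        }
    model.set_weights(weights)
    return model
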