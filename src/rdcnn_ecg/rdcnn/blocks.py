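"""Residual and dense blocks over 1-D feature maps.

A residual block learns a correction to its input: each of its layers is
convolution -> batch norm -> ReLU, and the block output is the last
activation plus the block input (Y = F(x) + x).  When the input channel
count differs from the branch width, the shortcut goes through a 1-tap
projection convolution so the addition is conformable.

A dense block concatenates: with full connectivity (the default) layer i
consumes the channel-concatenation of the block input and every previous
layer output, and the block output concatenates all of them, growing the
channel count to c_in + n_layers * filters.  A simplified "last-only"
variant chains the layers sequentially and concatenates only the block
input with the final activation (c_in + filters channels).
"""

from __future__ import annotations

import numpy as np

from .layers import BatchNorm1D, Conv1D, ReLU


class ResidualBlock:
    def __init__(
        self,
        c_in: int,
        n_layers: int,
        filters: int,
        kernel: int,
        rng: np.random.Generator,
    ) -> None:
        if n_layers < 1:
            raise ValueError("residual block needs at least one layer")
        self.c_in, self.n_layers = c_in, n_layers
        self.filters, self.kernel = filters, kernel
        self.layers = []
        prev = c_in
        for _ in range(n_layers):
            self.layers.append(
                (Conv1D(prev, filters, kernel, rng), BatchNorm1D(filters), ReLU())
            )
            prev = filters
        self.projection = (
            Conv1D(c_in, filters, 1, rng, bias=False) if c_in != filters else None
        )
        self.out_channels = filters

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = x
        for conv, bn, relu in self.layers:
            h = relu.forward(bn.forward(conv.forward(h, training), training), training)
        shortcut = self.projection.forward(x, training) if self.projection else x
        return h + shortcut

    def backward(self, g: np.ndarray) -> np.ndarray:
        gh = g
        for conv, bn, relu in reversed(self.layers):
            gh = conv.backward(bn.backward(relu.backward(gh)))
        gs = self.projection.backward(g) if self.projection else g
        return gh + gs

    def iter_layers(self):
        for i, (conv, bn, _) in enumerate(self.layers):
            yield f"layer{i}.conv", conv
            yield f"layer{i}.bn", bn
        if self.projection is not None:
            yield "projection", self.projection


class DenseBlock:
    def __init__(
        self,
        c_in: int,
        n_layers: int,
        filters: int,
        kernel: int,
        rng: np.random.Generator,
        connectivity: str = "full",
    ) -> None:
        if n_layers < 1:
            raise ValueError("dense block needs at least one layer")
        if connectivity not in ("full", "last-only"):
            raise ValueError(f"unknown dense connectivity {connectivity!r}")
        self.c_in, self.n_layers = c_in, n_layers
        self.filters, self.kernel = filters, kernel
        self.connectivity = connectivity
        self.layers = []
        for i in range(n_layers):
            if connectivity == "full":
                layer_in = c_in + i * filters
            else:
                layer_in = c_in if i == 0 else filters
            self.layers.append(
                (Conv1D(layer_in, filters, kernel, rng), BatchNorm1D(filters), ReLU())
            )
        self.out_channels = (
            c_in + n_layers * filters if connectivity == "full" else c_in + filters
        )

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if self.connectivity == "full":
            feats = [x]
            for conv, bn, relu in self.layers:
                inp = feats[0] if len(feats) == 1 else np.concatenate(feats, axis=2)
                y = relu.forward(
                    bn.forward(conv.forward(inp, training), training), training
                )
                feats.append(y)
            return np.concatenate(feats, axis=2)
        # last-only: sequential chain, concat block input with final activation
        h = x
        for conv, bn, relu in self.layers:
            h = relu.forward(bn.forward(conv.forward(h, training), training), training)
        return np.concatenate([x, h], axis=2)

    def backward(self, g: np.ndarray) -> np.ndarray:
        c_in, f = self.c_in, self.filters
        if self.connectivity == "full":
            # split the output gradient along the concat layout [x, y1..yn]
            gacc = [g[..., :c_in].copy()]
            for i in range(self.n_layers):
                gacc.append(g[..., c_in + i * f : c_in + (i + 1) * f].copy())
            for i in range(self.n_layers - 1, -1, -1):
                conv, bn, relu = self.layers[i]
                gin = conv.backward(bn.backward(relu.backward(gacc[i + 1])))
                gacc[0] += gin[..., :c_in]
                for j in range(i):
                    gacc[j + 1] += gin[..., c_in + j * f : c_in + (j + 1) * f]
            return gacc[0]
        gx = g[..., :c_in].copy()
        gh = g[..., c_in:]
        for conv, bn, relu in reversed(self.layers):
            gh = conv.backward(bn.backward(relu.backward(gh)))
        return gx + gh

    def iter_layers(self):
        for i, (conv, bn, _) in enumerate(self.layers):
            yield f"layer{i}.conv", conv
            yield f"layer{i}.bn", bn


def residual_block_forward(
    x: np.ndarray, block: ResidualBlock, training: bool = False
) -> np.ndarray:
    """Run a residual block on a (batch, length, channels) feature map."""
    return block.forward(np.asarray(x, dtype=float), training)


def dense_block_forward(
    x: np.ndarray, block: DenseBlock, training: bool = False
) -> np.ndarray:
    """Run a dense block on a (batch, length, channels) feature map."""
    return block.forward(np.asarray(x, dtype=float), training)
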