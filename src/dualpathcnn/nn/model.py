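"""Blocks and the materialized network for dual-path architecture specs."""

from __future__ import annotations

from typing import Iterable, Optional

import numpy as np

from ..archspec import ArchitectureSpec, ModuleSpec, ShapeTriple
from .layers import (
    F32,
    BatchNorm,
    Conv2d,
    GlobalAvgPool,
    Linear,
    MaxPool3x3s2,
    ReLU,
    softmax,
)


class ConvBNReLU:
    """Convolution -> batch normalization -> ReLU, the universal conv unit."""

    def __init__(self, c_in, c_out, kernel, stride, padding, rng):
        self.conv = Conv2d(c_in, c_out, kernel, stride, padding, rng)
        self.bn = BatchNorm(c_out)
        self.relu = ReLU()

    def forward(self, x, train=True):
        return self.relu.forward(self.bn.forward(self.conv.forward(x, train), train), train)

    def backward(self, dy):
        return self.conv.backward(self.bn.backward(self.relu.backward(dy)))

    def params(self):
        return self.conv.params() + self.bn.params()

    def sublayers(self):
        return [("conv", self.conv), ("bn", self.bn)]


class NormalDualBlock:
    """Parallel 1x1 and 3x3 stride-1 branches, concatenated along channels."""

    def __init__(self, c_in, f1, f3, rng):
        self.f1 = f1
        self.one = ConvBNReLU(c_in, f1, 1, 1, 0, rng)
        self.three = ConvBNReLU(c_in, f3, 3, 1, 1, rng)

    def forward(self, x, train=True):
        return np.concatenate(
            [self.one.forward(x, train), self.three.forward(x, train)], axis=-1
        )

    def backward(self, dy):
        return self.one.backward(dy[..., :self.f1]) + self.three.backward(dy[..., self.f1:])

    def params(self):
        return self.one.params() + self.three.params()

    def sublayers(self):
        return [(f"one.{n}", l) for n, l in self.one.sublayers()] + \
               [(f"three.{n}", l) for n, l in self.three.sublayers()]


class ReductionDualBlock:
    """Stride-2 3x3 conv branch next to a stride-2 3x3 max-pool branch.

    The pool branch passes all input channels through, so output channels are
    conv filters + input channels.
    """

    def __init__(self, c_in, filters, rng):
        self.filters = filters
        self.conv = ConvBNReLU(c_in, filters, 3, 2, 1, rng)
        self.pool = MaxPool3x3s2()

    def forward(self, x, train=True):
        return np.concatenate(
            [self.conv.forward(x, train), self.pool.forward(x, train)], axis=-1
        )

    def backward(self, dy):
        return self.conv.backward(dy[..., :self.filters]) + \
            self.pool.backward(dy[..., self.filters:])

    def params(self):
        return self.conv.params()

    def sublayers(self):
        return [(f"conv.{n}", l) for n, l in self.conv.sublayers()]


def _scaled(filters: int, width_multiplier: float) -> int:
    return max(1, int(round(filters * width_multiplier)))


class Network:
    """A trainable network materialized from an :class:`ArchitectureSpec`.

    ``width_multiplier`` scales every filter count (shape-faithfully: the
    module chain and strides are untouched) so the same architecture can be
    exercised at desk scale.  All randomness flows from ``seed``.
    """

    def __init__(self, spec: ArchitectureSpec, n_classes: Optional[int] = None,
                 width_multiplier: float = 1.0, seed: int = 0):
        self.spec = spec
        self.width_multiplier = float(width_multiplier)
        self.n_classes = int(n_classes if n_classes is not None else spec.n_classes)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)

        self.blocks: list = []       # one entry per body module (stem + duals)
        self.block_kinds: list[str] = []
        c = spec.input_shape.channels
        for m in spec.modules:
            if m.kind == "simple_conv":
                k = m.branches[0]
                f = _scaled(k.filters, width_multiplier)
                self.blocks.append(ConvBNReLU(c, f, k.kernel_width, k.stride, k.padding, rng))
                c = f
            elif m.kind == "normal_dual":
                one, three = m.branches
                f1 = _scaled(one.filters, width_multiplier)
                f3 = _scaled(three.filters, width_multiplier)
                self.blocks.append(NormalDualBlock(c, f1, f3, rng))
                c = f1 + f3
            elif m.kind == "reduction_dual":
                f = _scaled(m.branches[0].filters, width_multiplier)
                self.blocks.append(ReductionDualBlock(c, f, rng))
                c = f + c
            else:
                break
            self.block_kinds.append(m.kind)
        self.feature_dim = c
        self.gap = GlobalAvgPool()
        self.fc = Linear(c, self.n_classes, rng)
        self.last_shapes: list[ShapeTriple] = []

    # -- passes ------------------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        s = self.spec.input_shape
        if x.ndim != 4 or x.shape[1] != s.height or x.shape[2] != s.width \
                or x.shape[3] != s.channels:
            raise ValueError(
                f"expected input of shape (n, {s.height}, {s.width}, {s.channels}), "
                f"got {x.shape}"
            )
        return np.ascontiguousarray(x, dtype=F32)

    def forward(self, x: np.ndarray, train: bool = True,
                record_shapes: bool = False) -> np.ndarray:
        """Run to the logits; softmax is applied by the caller or the loss."""
        x = self._check_input(x)
        shapes = []
        for blk in self.blocks:
            x = blk.forward(x, train)
            if record_shapes:
                shapes.append(ShapeTriple(x.shape[2], x.shape[1], x.shape[3]))
        feats = self.gap.forward(x, train)
        logits = self.fc.forward(feats, train)
        if record_shapes:
            c = feats.shape[1]
            shapes.append(ShapeTriple(1, 1, c))               # global_pool
            shapes.append(ShapeTriple(1, 1, c))               # flatten
            shapes.append(ShapeTriple(1, 1, logits.shape[1]))  # fully_connected
            shapes.append(ShapeTriple(1, 1, logits.shape[1]))  # softmax
            self.last_shapes = shapes
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        dx = self.gap.backward(self.fc.backward(dlogits))
        for blk in reversed(self.blocks):
            dx = blk.backward(dx)

    def features(self, x: np.ndarray) -> np.ndarray:
        """Pooled feature vectors (input of the fully connected layer), eval mode."""
        x = self._check_input(x)
        for blk in self.blocks:
            x = blk.forward(x, train=False)
        return self.gap.forward(x, train=False)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    # -- parameters --------------------------------------------------------

    def params(self):
        out = []
        for blk in self.blocks:
            out.extend(blk.params())
        out.extend(self.fc.params())
        return out

    def named_layers(self):
        for i, blk in enumerate(self.blocks):
            for name, layer in blk.sublayers():
                yield f"block{i}.{name}", layer
        yield "fc", self.fc

    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, layer in self.named_layers():
            if isinstance(layer, (Conv2d, Linear)):
                state[f"{name}.W"] = layer.W
                state[f"{name}.b"] = layer.b
            elif isinstance(layer, BatchNorm):
                state[f"{name}.gamma"] = layer.gamma
                state[f"{name}.beta"] = layer.beta
                state[f"{name}.running_mean"] = layer.running_mean
                state[f"{name}.running_var"] = layer.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self.named_layers():
            if isinstance(layer, (Conv2d, Linear)):
                layer.W[:] = state[f"{name}.W"]
                layer.b[:] = state[f"{name}.b"]
            elif isinstance(layer, BatchNorm):
                layer.gamma[:] = state[f"{name}.gamma"]
                layer.beta[:] = state[f"{name}.beta"]
                layer.running_mean[:] = state[f"{name}.running_mean"]
                layer.running_var[:] = state[f"{name}.running_var"]


class SGDOptimizer:
    """SGD with classical momentum and decoupled-from-BN weight decay.

    Weight decay applies only to convolution and fully connected weights
    (``decay`` flag on the parameter), never to biases or batch-norm scales.
    """

    def __init__(self, network: Network, momentum: float = 0.9,
                 weight_decay: float = 0.0005):
        self.network = network
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p) for p, _, _ in network.params()]

    def step(self, lr: float) -> None:
        for v, (p, g, decay) in zip(self._velocity, self.network.params()):
            grad = g + self.weight_decay * p if decay else g
            v *= self.momentum
            v -= lr * grad
            p += v
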