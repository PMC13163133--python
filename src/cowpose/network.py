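"""The lightweight pose-tensor classifier and its complexity accounting.

Architecture (pinned): three convolutional blocks — 3x3 convolution without
bias (padding 1), batch normalization, ReLU, 2x2 max-pooling — with 64, 128
and 256 output channels, followed by global average pooling and a two-layer
fully connected head ``256 -> fc_hidden -> 3`` (both layers with bias).
Global average pooling makes the network size-agnostic: any input of at
least 8 x 8 yields a length-3 logit vector. With the default
``fc_hidden = 128`` the model has 429,315 trainable parameters
(~0.43 M, ~1.64 MiB at FP32).

The forward *and* backward passes are implemented directly on numpy arrays
(im2col convolutions running on BLAS matmul), so the whole training stack is
dependency-light and bit-deterministic for a fixed seed. Layers follow the
conventional formulation; gradient correctness is pinned by
finite-difference tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np


@dataclass(frozen=True)
class ModelSpec:
    in_channels: int = 46
    block_channels: tuple[int, ...] = (64, 128, 256)
    fc_hidden: int = 128
    n_classes: int = 3
    kernel_size: int = 3  # the implementation is specialized to 3x3

    def __post_init__(self) -> None:
        if self.kernel_size != 3:
            raise ValueError("only 3x3 kernels are supported")
        if self.n_classes != 3:
            raise ValueError("the behavior task has exactly 3 classes")


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("name", "data", "grad")

    def __init__(self, name: str, data: np.ndarray):
        self.name = name
        self.data = data
        self.grad = np.zeros_like(data)


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N, C, H, W) -> (N*H*W, C*9) patch matrix for a padded 3x3 window."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3) -> (N*H*W, C*9)
    return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * 9)


def _conv3x3(x: np.ndarray, wmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Same-padding 3x3 convolution; returns (output, patch matrix)."""
    n, _, h, w = x.shape
    cols = _im2col(x)
    out = cols @ wmat.T  # (N*H*W, cout)
    cout = wmat.shape[0]
    return out.reshape(n, h, w, cout).transpose(0, 3, 1, 2), cols


class Conv3x3:
    """3x3 convolution, stride 1, padding 1, no bias (He initialization)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / (cin * 9))
        w = (rng.standard_normal((cout, cin * 9)) * scale).astype(dtype)
        self.weight = Param(f"{name}.weight", w)
        self.cin, self.cout = cin, cout

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out, cols = _conv3x3(x, self.weight.data)
        self._cols = cols if train else None
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, cout, h, w = g.shape
        g2 = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * w, cout)
        self.weight.grad += g2.T @ self._cols
        # dx is the 'full' correlation of g with the 180-degree-rotated,
        # channel-transposed kernel — expressible as the same conv primitive.
        w4 = self.weight.data.reshape(cout, self.cin, 3, 3)
        wrot = w4[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(self.cin, cout * 9)
        dx, _ = _conv3x3(g, wrot)
        self._cols = None
        return dx

    def params(self) -> list[Param]:
        return [self.weight]


class BatchNorm2d:
    def __init__(self, channels: int, name: str, dtype=np.float32,
                 momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Param(f"{name}.gamma", np.ones(channels, dtype=dtype))
        self.beta = Param(f"{name}.beta", np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) / std[None, :, None, None]
        if train:
            self._xhat, self._std = xhat, std
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, g: np.ndarray) -> np.ndarray:
        xhat, std = self._xhat, self._std
        axes = (0, 2, 3)
        self.gamma.grad += (g * xhat).sum(axis=axes)
        self.beta.grad += g.sum(axis=axes)
        m = g.shape[0] * g.shape[2] * g.shape[3]
        gh = g * self.gamma.data[None, :, None, None]
        dx = (
            gh
            - gh.mean(axis=axes, keepdims=True)
            - xhat * (gh * xhat).mean(axis=axes, keepdims=True)
        ) / std[None, :, None, None]
        self._xhat = self._std = None
        return dx

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        out = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        dx = g * self._mask
        self._mask = None
        return dx

    def params(self) -> list[Param]:
        return []


class MaxPool2:
    """2x2 max pooling, stride 2; odd trailing rows/columns are dropped."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h // 2, w // 2
        xt = x[:, :, : h2 * 2, : w2 * 2]
        r = xt.reshape(n, c, h2, 2, w2, 2)
        out = r.max(axis=(3, 5))
        if train:
            self._shape = x.shape
            self._mask = r == out[:, :, :, None, :, None]
        return out

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        h2, w2 = h // 2, w // 2
        dx = np.zeros(self._shape, dtype=g.dtype)
        # Ties (common after ReLU zeros) share the gradient equally.
        counts = self._mask.sum(axis=(3, 5), keepdims=True)
        spread = self._mask * (g[:, :, :, None, :, None] / counts)
        dx[:, :, : h2 * 2, : w2 * 2] = spread.reshape(n, c, h2 * 2, w2 * 2).astype(g.dtype)
        self._shape = self._mask = None
        return dx

    def params(self) -> list[Param]:
        return []


class GlobalAvgPool:
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._hw = x.shape[2] * x.shape[3]
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, g: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dx = np.broadcast_to(g[:, :, None, None] / self._hw, self._shape).astype(g.dtype)
        self._shape = None
        return dx.copy()

    def params(self) -> list[Param]:
        return []


class Dense:
    def __init__(self, cin: int, cout: int, rng: np.random.Generator, name: str,
                 dtype=np.float32):
        scale = np.sqrt(2.0 / cin)
        self.weight = Param(f"{name}.weight", (rng.standard_normal((cout, cin)) * scale).astype(dtype))
        self.bias = Param(f"{name}.bias", np.zeros(cout, dtype=dtype))

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if train:
            self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, g: np.ndarray) -> np.ndarray:
        self.weight.grad += g.T @ self._x
        self.bias.grad += g.sum(axis=0)
        dx = g @ self.weight.data
        self._x = None
        return dx

    def params(self) -> list[Param]:
        return [self.weight, self.bias]


class BehaviorNet:
    """The lightweight three-block convolutional behavior classifier."""

    def __init__(self, spec: ModelSpec = ModelSpec(), seed: int = 0, dtype=np.float32):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.layers: list = []
        cin = spec.in_channels
        for b, cout in enumerate(spec.block_channels):
            self.layers += [
                Conv3x3(cin, cout, rng, f"block{b}.conv", dtype),
                BatchNorm2d(cout, f"block{b}.bn", dtype),
                ReLU(),
                MaxPool2(),
            ]
            cin = cout
        self.layers.append(GlobalAvgPool())
        self.layers.append(Dense(cin, spec.fc_hidden, rng, "fc1", dtype))
        self.layers.append(ReLU())
        self.layers.append(Dense(spec.fc_hidden, spec.n_classes, rng, "fc2", dtype))

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """Logits for a batch ``(N, C, H, W)``; eval mode uses running BN stats."""
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        g = dlogits
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0

    # -- parameters and state ----------------------------------------------
    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def _bn_layers(self) -> Iterator[BatchNorm2d]:
        return (l for l in self.layers if isinstance(l, BatchNorm2d))

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {p.name: p.data.copy() for p in self.parameters()}
        for i, bn in enumerate(self._bn_layers()):
            state[f"bn{i}.running_mean"] = bn.running_mean.copy()
            state[f"bn{i}.running_var"] = bn.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.parameters():
            p.data[...] = state[p.name]
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean[...] = state[f"bn{i}.running_mean"]
            bn.running_var[...] = state[f"bn{i}.running_var"]


def build_model(spec: ModelSpec = ModelSpec(), seed: int = 0) -> BehaviorNet:
    """Deterministically-initialized classifier (same seed, same weights)."""
    return BehaviorNet(spec, seed)


def count_parameters(model: BehaviorNet) -> tuple[int, int]:
    """Total trainable scalars and the FP32 footprint in bytes (4 per scalar)."""
    n = sum(p.data.size for p in model.parameters())
    return n, 4 * n


def predict_logits(model: BehaviorNet, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Eval-mode logits over a dataset, computed in batches."""
    outs = [model.forward(x[i : i + batch_size]) for i in range(0, len(x), batch_size)]
    return np.concatenate(outs, axis=0)


def save_checkpoint(path, model: BehaviorNet, extra: dict | None = None) -> None:
    """Persist spec + seed + weights (+ optional JSON-serializable extras)."""
    import json

    meta = {
        "spec": {
            "in_channels": model.spec.in_channels,
            "block_channels": list(model.spec.block_channels),
            "fc_hidden": model.spec.fc_hidden,
            "n_classes": model.spec.n_classes,
            "kernel_size": model.spec.kernel_size,
        },
        "seed": model.seed,
        "extra": extra or {},
    }
    state = model.state_dict()
    np.savez(path, __meta__=json.dumps(meta), **state)


def load_checkpoint(path) -> BehaviorNet:
    import json

    with np.load(path, allow_pickle=False) as fh:
        meta = json.loads(str(fh["__meta__"]))
        state = {k: fh[k] for k in fh.files if k != "__meta__"}
    spec_d = meta["spec"]
    spec = ModelSpec(
        in_channels=spec_d["in_channels"],
        block_channels=tuple(spec_d["block_channels"]),
        fc_hidden=spec_d["fc_hidden"],
        n_classes=spec_d["n_classes"],
        kernel_size=spec_d["kernel_size"],
    )
    model = BehaviorNet(spec, seed=meta["seed"])
    model.load_state_dict(state)
    return model
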