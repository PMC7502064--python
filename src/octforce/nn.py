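"""Minimal 1D convolutional network core with reverse-mode gradients.

Implements exactly the pieces the force-regression models need — 1D
convolution (im2col + BLAS), batch normalization, ReLU, max/global-average
pooling, a linear head, residual basic blocks, the ResNet-style assemblies and
an Adam optimizer — in numpy, with hand-written backward passes.  Layers cache
their forward activations, so a network instance supports one forward/backward
pair at a time.  All randomness flows through an explicit
``numpy.random.Generator``; identical seeds give bit-identical parameters.

Networks default to float32 (BLAS throughput); float64 is available for
gradient checking.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "MaxPool1d",
    "GlobalAvgPool1d",
    "Linear",
    "BasicBlock",
    "ResNet1D",
    "Adam",
    "mse_and_grad",
]

_NEG_LARGE = -1e30  # pool padding value; avoids inf*0 in gradients


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("data", "grad")

    def __init__(self, data: np.ndarray) -> None:
        self.data = data
        self.grad = np.zeros_like(data)


class Conv1d:
    """1D convolution (cross-correlation), no bias — batch norm follows it."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        *,
        rng: np.random.Generator,
        dtype=np.float32,
    ) -> None:
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU nets
        w = rng.normal(0.0, scale, size=(out_channels, fan_in)).astype(dtype)
        self.weight = Param(w)

    def params(self) -> list[Param]:
        return [self.weight]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, length = x.shape
        p, k, s = self.padding, self.kernel_size, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p))) if p else x
        win = sliding_window_view(xp, k, axis=2)[:, :, :: s, :]  # (B,C,L_out,K)
        l_out = win.shape[2]
        cols = np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(b, l_out, c * k)
        y = cols @ self.weight.data.T  # (B, L_out, C_out)
        self._cache = (cols, b, c, length, l_out)
        return np.ascontiguousarray(y.transpose(0, 2, 1))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        cols, b, c, length, l_out = self._cache
        p, k, s = self.padding, self.kernel_size, self.stride
        g = np.ascontiguousarray(gy.transpose(0, 2, 1))  # (B, L_out, C_out)
        g2 = g.reshape(-1, g.shape[2])
        self.weight.grad += g2.T @ cols.reshape(g2.shape[0], -1)
        gcols = g @ self.weight.data  # (B, L_out, C*K)
        gwin = gcols.reshape(b, l_out, c, k).transpose(0, 2, 1, 3)  # (B,C,L_out,K)
        lp = length + 2 * p
        gxp = np.zeros((b, c, lp), dtype=gy.dtype)
        for j in range(k):
            gxp[:, :, j : j + s * l_out : s] += gwin[:, :, :, j]
        return gxp[:, :, p : lp - p] if p else gxp


class BatchNorm1d:
    """Per-channel batch normalization over (batch, length)."""

    def __init__(self, channels: int, *, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32) -> None:
        self.gamma = Param(np.ones(channels, dtype=dtype))
        self.beta = Param(np.zeros(channels, dtype=dtype))
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)
        self.momentum = momentum
        self.eps = eps

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * invstd[None, :, None]
        self._cache = (xhat, invstd, x.shape[0] * x.shape[2], train)
        return self.gamma.data[None, :, None] * xhat + self.beta.data[None, :, None]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        xhat, invstd, n, train = self._cache
        self.gamma.grad += (gy * xhat).sum(axis=(0, 2))
        self.beta.grad += gy.sum(axis=(0, 2))
        gxhat = gy * self.gamma.data[None, :, None]
        if not train:
            return gxhat * invstd[None, :, None]
        s1 = gxhat.sum(axis=(0, 2), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(0, 2), keepdims=True)
        return (invstd[None, :, None] / n) * (n * gxhat - s1 - xhat * s2)


class ReLU:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy * self._mask


class MaxPool1d:
    def __init__(self, kernel_size: int = 3, stride: int = 2, padding: int = 1) -> None:
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        p, k, s = self.padding, self.kernel_size, self.stride
        xp = np.pad(x, ((0, 0), (0, 0), (p, p)), constant_values=_NEG_LARGE) if p else x
        win = sliding_window_view(xp, k, axis=2)[:, :, :: s, :]
        self._argmax = win.argmax(axis=3)  # first max wins: deterministic
        self._shape = (x.shape, win.shape[2])
        return win.max(axis=3)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        (b, c, length), l_out = self._shape
        p, k, s = self.padding, self.kernel_size, self.stride
        lp = length + 2 * p
        gxp = np.zeros((b, c, lp), dtype=gy.dtype)
        for j in range(k):
            gxp[:, :, j : j + s * l_out : s] += gy * (self._argmax == j)
        return gxp[:, :, p : lp - p] if p else gxp


class GlobalAvgPool1d:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._length = x.shape[2]
        return x.mean(axis=2)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.repeat(gy[:, :, None], self._length, axis=2) / self._length


class Linear:
    def __init__(self, in_features: int, out_features: int, *,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        scale = np.sqrt(1.0 / in_features)
        self.weight = Param(rng.normal(0.0, scale, size=(out_features, in_features)).astype(dtype))
        self.bias = Param(np.zeros(out_features, dtype=dtype))

    def params(self) -> list[Param]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.weight.grad += gy.T @ self._x
        self.bias.grad += gy.sum(axis=0)
        return gy @ self.weight.data


class BasicBlock:
    """Standard two-convolution residual block with optional projection shortcut."""

    def __init__(self, in_channels: int, out_channels: int, stride: int, *,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        self.conv1 = Conv1d(in_channels, out_channels, 3, stride, 1, rng=rng, dtype=dtype)
        self.bn1 = BatchNorm1d(out_channels, dtype=dtype)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(out_channels, out_channels, 3, 1, 1, rng=rng, dtype=dtype)
        self.bn2 = BatchNorm1d(out_channels, dtype=dtype)
        self.relu2 = ReLU()
        if stride != 1 or in_channels != out_channels:
            self.proj = Conv1d(in_channels, out_channels, 1, stride, 0, rng=rng, dtype=dtype)
            self.proj_bn = BatchNorm1d(out_channels, dtype=dtype)
        else:
            self.proj = None
            self.proj_bn = None

    def params(self) -> list[Param]:
        out = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.proj is not None:
            out += self.proj.params() + self.proj_bn.params()
        return out

    def conv_layers(self) -> int:
        return 2 + (1 if self.proj is not None else 0)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        out = self.conv1.forward(x, train)
        out = self.bn1.forward(out, train)
        out = self.relu1.forward(out, train)
        out = self.conv2.forward(out, train)
        out = self.bn2.forward(out, train)
        if self.proj is not None:
            shortcut = self.proj_bn.forward(self.proj.forward(x, train), train)
        else:
            shortcut = x
        return self.relu2.forward(out + shortcut, train)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        g = self.relu2.backward(gy)
        gx_main = self.conv1.backward(
            self.bn1.backward(self.relu1.backward(self.conv2.backward(self.bn2.backward(g))))
        )
        if self.proj is not None:
            gx_short = self.proj.backward(self.proj_bn.backward(g))
        else:
            gx_short = g
        return gx_main + gx_short


# residual-stage layout per architecture: (blocks per stage, width factor, stride)
_STAGES = {
    "resnet6": [(1, 1, 1), (1, 2, 2)],
    "resnet18": [(2, 1, 1), (2, 2, 2), (2, 4, 2), (2, 8, 2)],
    "resnet34": [(3, 1, 1), (4, 2, 2), (6, 4, 2), (3, 8, 2)],
}


class ResNet1D:
    """1D ResNet regression network: stem, residual stages, GAP, linear head.

    The 2D ResNet family adapted to 1D signals: every 2D convolution and
    pooling is replaced by its 1D counterpart with the same kernel size and
    stride along the single axis, and the classification head is replaced by
    a single-output fully connected layer.  ``resnet6`` is the small variant
    with two residual blocks and six convolutional layers in total (stem,
     2x2 block convolutions, and the 1x1 projection on the second block's
    stride-2 shortcut).
    """

    def __init__(self, architecture: str, *, width: int = 64, seed: int = 0,
                 dtype=np.float32) -> None:
        if architecture not in _STAGES:
            raise ValueError(
                f"unknown architecture {architecture!r}; expected one of {sorted(_STAGES)}"
            )
        self.architecture = architecture
        self.width = width
        self.seed = seed
        self.dtype = dtype
        rng = np.random.default_rng(seed)

        self.stem = Conv1d(1, width, 7, 2, 3, rng=rng, dtype=dtype)
        self.stem_bn = BatchNorm1d(width, dtype=dtype)
        self.stem_relu = ReLU()
        self.pool = MaxPool1d(3, 2, 1)
        self.blocks: list[BasicBlock] = []
        in_ch = width
        for n_blocks, factor, stage_stride in _STAGES[architecture]:
            out_ch = width * factor
            for i in range(n_blocks):
                stride = stage_stride if i == 0 else 1
                self.blocks.append(BasicBlock(in_ch, out_ch, stride, rng=rng, dtype=dtype))
                in_ch = out_ch
        self.gap = GlobalAvgPool1d()
        self.head = Linear(in_ch, 1, rng=rng, dtype=dtype)

    def params(self) -> list[Param]:
        out = self.stem.params() + self.stem_bn.params()
        for block in self.blocks:
            out += block.params()
        return out + self.head.params()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params()))

    def conv_layer_count(self) -> int:
        """Convolutions in the network: stem + block convs + 1x1 projections."""
        return 1 + sum(block.conv_layers() for block in self.blocks)

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Map (batch, length) inputs to (batch,) scalar predictions."""
        x = np.ascontiguousarray(x, dtype=self.dtype)[:, None, :]  # add channel axis
        h = self.stem.forward(x, train)
        h = self.stem_bn.forward(h, train)
        h = self.stem_relu.forward(h, train)
        h = self.pool.forward(h, train)
        for block in self.blocks:
            h = block.forward(h, train)
        h = self.gap.forward(h, train)
        return self.head.forward(h, train)[:, 0]

    def backward(self, gy: np.ndarray) -> None:
        """Accumulate parameter gradients from d(loss)/d(prediction)."""
        g = self.head.backward(np.asarray(gy, dtype=self.dtype)[:, None])
        g = self.gap.backward(g)
        for block in reversed(self.blocks):
            g = block.backward(g)
        g = self.pool.backward(g)
        g = self.stem_relu.backward(g)
        g = self.stem_bn.backward(g)
        self.stem.backward(g)

    # --- checkpoint support -------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        """Flat name -> array mapping of all parameters and BN running stats."""
        out: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.params()):
            out[f"param_{i}"] = p.data
        for i, bn in enumerate(self._batchnorms()):
            out[f"bn_{i}_mean"] = bn.running_mean
            out[f"bn_{i}_var"] = bn.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.data[...] = arrays[f"param_{i}"]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = arrays[f"bn_{i}_mean"]
            bn.running_var[...] = arrays[f"bn_{i}_var"]

    def _batchnorms(self) -> list[BatchNorm1d]:
        bns = [self.stem_bn]
        for block in self.blocks:
            bns += [block.bn1, block.bn2]
            if block.proj_bn is not None:
                bns.append(block.proj_bn)
        return bns


class Adam:
    """Adam optimizer over a fixed parameter list."""

    def __init__(self, params: list[Param], lr: float = 0.005,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m += (1.0 - b1) * (g - m)
            v += (1.0 - b2) * (g * g - v)
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def mse_and_grad(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Batch mean squared error and its gradient with respect to ``pred``."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.size == 0:
        raise ValueError("empty batch")
    resid = pred - target
    loss = float(np.mean(resid * resid))
    return loss, (2.0 / pred.size) * resid
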