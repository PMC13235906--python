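"""Neural-network layers on top of the autodiff engine.

Modules own :class:`~taxovision.nn.autodiff.Tensor` parameters with
``requires_grad=True``.  Freezing a module clears ``requires_grad`` so the
graph treats its parameters as constants and optimizers skip them.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: parameter discovery, train/eval mode, freezing."""

    def __init__(self):
        self.training = True

    def forward(self, x):  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x):
        return self.forward(x)

    # -- introspection --------------------------------------------------
    def children(self) -> list["Module"]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.append(v)
            elif isinstance(v, (list, tuple)):
                out.extend(m for m in v if isinstance(m, Module))
        return out

    def modules(self) -> list["Module"]:
        out = [self]
        for c in self.children():
            out.extend(c.modules())
        return out

    def own_parameters(self) -> list[Tensor]:
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor):
                out.append(v)
        return out

    def parameters(self, trainable_only: bool = False) -> list[Tensor]:
        out = []
        for m in self.modules():
            for p in m.own_parameters():
                if not trainable_only or p.requires_grad:
                    out.append(p)
        return out

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    # -- mode / freezing ------------------------------------------------
    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def freeze(self):
        for p in self.parameters():
            p.requires_grad = False
        return self

    def unfreeze(self):
        for p in self.parameters():
            p.requires_grad = True
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization ----------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        arrays = [p.data for m in self.modules() for p in m.own_parameters()]
        arrays += [m.running_mean for m in self.modules()
                   if isinstance(m, BatchNorm2d)]
        arrays += [m.running_var for m in self.modules()
                   if isinstance(m, BatchNorm2d)]
        return arrays

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        it = iter(arrays)
        for m in self.modules():
            for p in m.own_parameters():
                a = np.asarray(next(it), dtype=np.float64)
                if a.shape != p.data.shape:
                    raise ValueError("state array shape mismatch")
                p.data = a
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(next(it), dtype=np.float64)
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                m.running_var = np.asarray(next(it), dtype=np.float64)


class Dense(Module):
    """Fully connected layer, He/Glorot initialised."""

    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True,
                 init: str = "he"):
        super().__init__()
        scale = {"he": np.sqrt(2.0 / in_features),
                 "glorot": np.sqrt(2.0 / (in_features + out_features)),
                 # near-zero head init: near-uniform softmax at start while
                 # gradients still reach upstream layers
                 "head": 0.01 * np.sqrt(2.0 / (in_features + out_features)),
                 }[init]
        self.weight = Tensor(rng.normal(0.0, scale, (in_features, out_features)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x):
        out = ad.matmul(x, self.weight)
        if self.bias is not None:
            out = ad.add(out, self.bias)
        return out


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0,
                 bias: bool = True):
        super().__init__()
        fan_in = in_channels * kernel * kernel
        self.weight = Tensor(
            rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       (out_channels, in_channels, kernel, kernel)),
            requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.stride, self.padding = stride, padding

    def forward(self, x):
        return ad.conv2d(x, self.weight, self.bias,
                         stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics (NCHW)."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def forward(self, x):
        x = ad.as_tensor(x)
        if self.training:
            mean = ad.tmean(x, axis=(0, 2, 3), keepdims=True)
            centred = ad.add(x, ad.mul(mean, -1.0))
            var = ad.tmean(ad.mul(centred, centred), axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mean.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            inv = ad.pow_const(ad.add(var, self.eps), -0.5)
            norm = ad.mul(centred, inv)
        else:
            mean = self.running_mean.reshape(1, -1, 1, 1)
            inv = 1.0 / np.sqrt(self.running_var.reshape(1, -1, 1, 1) + self.eps)
            norm = ad.mul(ad.add(x, -mean), inv)
        g = ad.reshape(self.gamma, (1, -1, 1, 1))
        b = ad.reshape(self.beta, (1, -1, 1, 1))
        return ad.add(ad.mul(norm, g), b)


class ReLU(Module):
    def forward(self, x):
        return ad.relu(x)


class Sigmoid(Module):
    def forward(self, x):
        return ad.sigmoid(x)


class MaxPool2d(Module):
    def __init__(self, kernel: int = 2, stride: int | None = None,
                 padding: int = 0):
        super().__init__()
        self.kernel, self.stride, self.padding = kernel, stride, padding

    def forward(self, x):
        return ad.max_pool2d(x, self.kernel, self.stride, self.padding)


class Dropout(Module):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError(f"dropout probability must be in [0, 1), got {p}")
        self.p = p
        self.rng = rng

    def forward(self, x):
        if not self.training or self.p == 0.0:
            return ad.as_tensor(x)
        x = ad.as_tensor(x)
        mask = (self.rng.random(x.data.shape) >= self.p) / (1.0 - self.p)
        return ad.mul(x, mask)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


class SEBlock(Module):
    """Squeeze-and-Excitation channel recalibration.

    Squeeze: global average pooling collapses each channel to its mean.
    Excitation: a two-layer bottleneck (ReLU then sigmoid) learns per-channel
    weights in (0, 1).  Re-scale: the weights multiply the input maps, so the
    output shape equals the input shape.  The hidden width is
    ``channels // reduction``, floored at 1.
    """

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Dense(channels, hidden, rng)
        self.fc2 = Dense(hidden, channels, rng)

    def forward(self, x):
        x = ad.as_tensor(x)
        squeezed = ad.global_avg_pool2d(x)              # (N, C)
        w = ad.sigmoid(self.fc2(ad.relu(self.fc1(squeezed))))
        w4 = ad.reshape(w, (w.shape[0], w.shape[1], 1, 1))
        return ad.mul(x, w4)


class Adam:
    """Adam optimizer over a fixed parameter list; skips frozen tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = {id(p): np.zeros_like(p.data) for p in self.params}
        self.v = {id(p): np.zeros_like(p.data) for p in self.params}
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p in self.params:
            if not p.requires_grad or p.grad is None:
                continue
            k = id(p)
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
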