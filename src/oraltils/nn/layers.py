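"""Layer/module system on top of the autodiff tensors.

Modules register parameters and sub-modules in attribute order, which gives
a deterministic flattened layer list — the unit used by the fine-tuning
"unfreeze the last n layers" contract.  Weights are drawn after model
construction by :func:`init_parameters` from a single seeded generator, so
identical (architecture, seed) pairs yield bit-identical models.
"""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor, concatenate

__all__ = [
    "Module", "Sequential", "Dense", "Conv2d", "DepthwiseConv2d",
    "ConvTranspose2d", "BatchNorm2d", "LayerNorm", "Dropout", "ReLU",
    "SiLU", "Sigmoid", "GlobalAvgPool2d", "MultiHeadSelfAttention",
    "TransformerBlock", "init_parameters", "count_parameters", "concatenate",
]


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self._modules[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    # -- traversal -------------------------------------------------------
    def modules(self) -> list["Module"]:
        """Depth-first module list, self included, in registration order."""
        out = [self]
        for m in self._modules.values():
            out.extend(m.modules())
        return out

    def leaf_layers(self) -> list["Module"]:
        """Flattened list of parameter-carrying leaf layers, input-to-output."""
        return [m for m in self.modules() if m._params]

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for m in self.modules():
            out.extend(m._params.values())
        return out

    def train(self) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", True)
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            object.__setattr__(m, "training", False)
        return self

    def freeze(self) -> "Module":
        for p in self.parameters():
            p.trainable = False
        return self

    def unfreeze(self) -> "Module":
        for p in self.parameters():
            p.trainable = True
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        """All learnable arrays plus normalization buffers, for checkpoints."""
        arrs = [p.data for p in self.parameters()]
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                arrs.extend([m.running_mean, m.running_var])
        return arrs

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        """Assign arrays saved by :meth:`state_arrays` (same architecture)."""
        params = self.parameters()
        bns = [m for m in self.modules() if isinstance(m, BatchNorm2d)]
        expected = len(params) + 2 * len(bns)
        if len(arrays) != expected:
            raise ValueError(f"checkpoint holds {len(arrays)} arrays, model expects {expected}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float32)
        tail = arrays[len(params):]
        for m, rm, rv in zip(bns, tail[0::2], tail[1::2]):
            m.running_mean = rm.astype(np.float32)
            m.running_var = rv.astype(np.float32)

    def save_npz(self, path) -> None:
        arrays = self.state_arrays()
        np.savez_compressed(path, **{f"a{i:05d}": a for i, a in enumerate(arrays)})

    def load_npz(self, path) -> None:
        with np.load(path) as data:
            self.load_state_arrays([data[k] for k in sorted(data.files)])

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, bias: bool = True):
        super().__init__()
        self.weight = Parameter((n_in, n_out), init="he", fan_in=n_in)
        self.bias = Parameter((n_out,), init="zeros") if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int, stride: int = 1,
                 padding: int = 0, bias: bool = True):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = Parameter((c_out, c_in, k, k), init="he", fan_in=c_in * k * k)
        self.bias = Parameter((c_out,), init="zeros") if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)


class DepthwiseConv2d(Module):
    def __init__(self, ch: int, k: int, stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        self.stride, self.padding = stride, padding
        self.weight = Parameter((ch, k, k), init="he", fan_in=k * k)
        self.bias = Parameter((ch,), init="zeros") if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.depthwise_conv2d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose2d(Module):
    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 2,
                 padding: int = 1, output_padding: int = 1, bias: bool = True):
        super().__init__()
        self.stride, self.padding, self.output_padding = stride, padding, output_padding
        self.weight = Parameter((c_in, c_out, k, k), init="he", fan_in=c_in * k * k)
        self.bias = Parameter((c_out,), init="zeros") if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return F.conv_transpose2d(x, self.weight, self.bias, self.stride,
                                  self.padding, self.output_padding)


class BatchNorm2d(Module):
    def __init__(self, ch: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter((ch,), init="ones")
        self.beta = Parameter((ch,), init="zeros")
        self.running_mean = np.zeros(ch, np.float32)
        self.running_var = np.ones(ch, np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean += self.momentum * (mu.data.ravel() - self.running_mean)
            self.running_var += self.momentum * (var.data.ravel() - self.running_var)
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xhat = (x - mu) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter((dim,), init="ones")
        self.beta = Parameter((dim,), init="zeros")

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float = 0.5):
        super().__init__()
        self.p = p
        self.rng = np.random.default_rng(0)  # reseeded by init_parameters

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class SiLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.silu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class GlobalAvgPool2d(Module):
    def __init__(self, keepdims: bool = True):
        super().__init__()
        self.keepdims = keepdims

    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3), keepdims=self.keepdims)


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.heads = heads
        self.dh = dim // heads
        self.qkv = Dense(dim, 3 * dim)
        self.proj = Dense(dim, dim)

    def forward(self, x: Tensor) -> Tensor:
        b, l, d = x.shape
        qkv = self.qkv(x).reshape(b, l, 3, self.heads, self.dh).transpose(2, 0, 3, 1, 4)
        q = _take_first_axis(qkv, 0)  # (B, heads, L, dh)
        k = _take_first_axis(qkv, 1)
        v = _take_first_axis(qkv, 2)
        att = (q @ k.transpose(0, 1, 3, 2)) * (self.dh**-0.5)
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(b, l, d)
        return self.proj(out)


def _take_first_axis(x: Tensor, idx: int) -> Tensor:
    """Select ``x[idx]`` along axis 0 with gradient routing."""
    out_data = x.data[idx]

    def backward(g):
        if x.requires_grad:
            full = np.zeros_like(x.data)
            full[idx] = g
            x._accumulate(full)

    return Tensor._make(out_data, (x,), backward)


class TransformerBlock(Module):
    def __init__(self, dim: int, heads: int, mlp_ratio: float = 2.0):
        super().__init__()
        hidden = int(dim * mlp_ratio)
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, heads)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Dense(dim, hidden)
        self.fc2 = Dense(hidden, dim)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(self.fc1(self.norm2(x)).silu())


def init_parameters(model: Module, seed: int) -> Module:
    """Deterministically draw all weights of ``model`` from one seed."""
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    for p in model.parameters():
        if p.init == "he":
            std = float(np.sqrt(2.0 / max(p.fan_in or 1, 1)))
            p.data = rng.normal(0.0, std, p.shape).astype(np.float32)
        elif p.init == "ones":
            p.data = np.ones(p.shape, np.float32)
        elif p.init == "zeros":
            p.data = np.zeros(p.shape, np.float32)
        else:  # pragma: no cover - defensive
            raise ValueError(f"unknown init {p.init!r}")
    drop_seeds = ss.spawn(1)[0]
    drops = [m for m in model.modules() if isinstance(m, Dropout)]
    for m, child in zip(drops, drop_seeds.spawn(max(len(drops), 1))):
        m.rng = np.random.default_rng(child)
    return model


def count_parameters(model: Module, trainable_only: bool = False) -> int:
    return sum(
        p.data.size for p in model.parameters() if (p.trainable or not trainable_only)
    )
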