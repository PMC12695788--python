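"""Layer/module abstractions over the autodiff core."""

from __future__ import annotations

import math

import numpy as np

from . import functional as F
from .autograd import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_parameters", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._parameters[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # -- traversal ----------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._parameters.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def num_params(self) -> int:
        """Number of trainable scalars, each parameter counted exactly once."""
        seen, total = set(), 0
        for p in self.parameters():
            if id(p) not in seen:
                seen.add(id(p))
                total += p.size
        return total

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialization ---------------------------------------------------
    def state_dict(self, prefix: str = "", out=None):
        out = {} if out is None else out
        for name, p in self._parameters.items():
            out[prefix + name] = p.data.copy()
        for name, buf in getattr(self, "_buffers", {}).items():
            out[prefix + name] = buf.copy()
        for name, m in self._modules.items():
            m.state_dict(prefix + name + ".", out)
        return out

    def load_state_dict(self, state: dict, prefix: str = ""):
        for name, p in self._parameters.items():
            key = prefix + name
            if p.data.shape != state[key].shape:
                raise ValueError(f"shape mismatch for {key}")
            p.data = np.asarray(state[key], dtype=p.data.dtype)
        for name in getattr(self, "_buffers", {}):
            self._buffers[name] = np.asarray(state[prefix + name])
        for name, m in self._modules.items():
            m.load_state_dict(state, prefix + name + ".")

    def register_buffer(self, name: str, value: np.ndarray):
        if not hasattr(self, "_buffers"):
            object.__setattr__(self, "_buffers", {})
        self._buffers[name] = value


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        self._modules[str(len(self._list))] = m
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        self._list = list(mods)
        for i, m in enumerate(mods):
            self._modules[str(i)] = m

    def __iter__(self):
        return iter(self._list)

    def __getitem__(self, i):
        return self._list[i]

    def forward(self, x):
        for m in self._list:
            x = m(x)
        return x


_INIT_RNG = np.random.default_rng(0)


def set_seed(seed: int):
    """Seed parameter initialization (and return the generator)."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)
    return _INIT_RNG


def _kaiming(shape, fan_in):
    bound = math.sqrt(1.0 / fan_in)
    return _INIT_RNG.uniform(-bound, bound, size=shape)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, padding=0, bias=True, groups=1):
        super().__init__()
        kh, kw = (kernel, kernel) if isinstance(kernel, int) else kernel
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel = (kh, kw)
        self.stride, self.padding, self.groups = stride, padding, groups
        if groups not in (1, in_ch):
            raise ValueError("only groups=1 or depthwise (groups=in_ch) supported")
        cin_g = in_ch // groups
        fan_in = cin_g * kh * kw
        self.weight = Parameter(_kaiming((out_ch, cin_g, kh, kw), fan_in))
        self.bias = Parameter(np.zeros(out_ch)) if bias else None

    def forward(self, x):
        if self.groups == 1:
            return F.conv2d(x, self.weight, self.bias, self.stride, self.padding)
        if self.groups == self.in_ch and self.out_ch == self.in_ch and self.stride == 1:
            return F.depthwise_conv2d(x, self.weight, self.bias)
        raise NotImplementedError("unsupported grouped convolution configuration")


class Linear(Module):
    def __init__(self, in_f, out_f, bias=True):
        super().__init__()
        self.in_f, self.out_f = in_f, out_f
        self.weight = Parameter(_kaiming((out_f, in_f), in_f))
        self.bias = Parameter(np.zeros(out_f)) if bias else None

    def forward(self, x):
        return F.linear(x, self.weight, self.bias)


class Embedding(Module):
    def __init__(self, n, dim):
        super().__init__()
        self.weight = Parameter(_INIT_RNG.normal(0, 0.02, (n, dim)))

    def forward(self, idx):
        return self.weight[np.asarray(idx)]


class BatchNorm2d(Module):
    """Batch statistics while training, running statistics in eval mode."""

    def __init__(self, ch, eps=1e-5, momentum=0.1):
        super().__init__()
        self.ch, self.eps, self.momentum = ch, eps, momentum
        self.weight = Parameter(np.ones(ch))
        self.bias = Parameter(np.zeros(ch))
        self.register_buffer("running_mean", np.zeros(ch))
        self.register_buffer("running_var", np.ones(ch))

    def forward(self, x):
        g = self.weight.reshape(1, self.ch, 1, 1)
        b = self.bias.reshape(1, self.ch, 1, 1)
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mu.data.reshape(-1)
            )
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * var.data.reshape(-1)
            )
            return g * (x - mu) / ((var + self.eps) ** 0.5) + b
        rm = self._buffers["running_mean"].reshape(1, self.ch, 1, 1)
        rv = self._buffers["running_var"].reshape(1, self.ch, 1, 1)
        scale = self.weight.reshape(1, self.ch, 1, 1) / np.sqrt(rv + self.eps)
        return x * scale + (b - Tensor(rm) * scale)


class LayerNorm(Module):
    def __init__(self, dim, eps=1e-5):
        super().__init__()
        self.dim, self.eps = dim, eps
        self.weight = Parameter(np.ones(dim))
        self.bias = Parameter(np.zeros(dim))

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return self.weight * (x - mu) / ((var + self.eps) ** 0.5) + self.bias


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class GELU(Module):
    def forward(self, x):
        return x.gelu()


class Identity(Module):
    def forward(self, x):
        return x


class ConvNormAct(Module):
    """Conv -> BatchNorm -> activation, the workhorse block of the detector."""

    def __init__(self, in_ch, out_ch, kernel=1, stride=1, padding=None, act="silu"):
        super().__init__()
        if padding is None:
            k = kernel if isinstance(kernel, int) else max(kernel)
            padding = k // 2
        self.conv = Conv2d(in_ch, out_ch, kernel, stride, padding, bias=False)
        self.norm = BatchNorm2d(out_ch)
        self.act = {"silu": SiLU, "relu": ReLU, "gelu": GELU, None: Identity, "none": Identity}[
            act
        ]()

    def forward(self, x):
        return self.act(self.norm(self.conv(x)))


class MultiheadAttention(Module):
    def __init__(self, dim, heads):
        super().__init__()
        if dim % heads:
            raise ValueError("dim must be divisible by heads")
        self.dim, self.heads, self.hd = dim, heads, dim // heads
        self.qkv = Linear(dim, 3 * dim)
        self.out = Linear(dim, dim)

    def forward(self, q, k=None, v=None):
        """q, k, v: (B, L, dim). Self-attention when k/v omitted."""
        k = q if k is None else k
        v = k if v is None else v
        B, Lq, D = q.shape
        Lk = k.shape[1]
        wq, wk, wv = (self.qkv.weight[i * D : (i + 1) * D] for i in range(3))
        bq, bk, bv = (self.qkv.bias[i * D : (i + 1) * D] for i in range(3))
        qh = F.linear(q, wq, bq).reshape(B, Lq, self.heads, self.hd).transpose(0, 2, 1, 3)
        kh = F.linear(k, wk, bk).reshape(B, Lk, self.heads, self.hd).transpose(0, 2, 1, 3)
        vh = F.linear(v, wv, bv).reshape(B, Lk, self.heads, self.hd).transpose(0, 2, 1, 3)
        att = F.matmul(qh, kh.transpose(0, 1, 3, 2)) * (1.0 / math.sqrt(self.hd))
        att = att.softmax(axis=-1)
        out = F.matmul(att, vh).transpose(0, 2, 1, 3).reshape(B, Lq, D)
        return self.out(out)


class MLP(Module):
    """Stack of linear layers with ReLU between (DETR-style prediction head)."""

    def __init__(self, in_f, hidden, out_f, layers):
        super().__init__()
        dims = [in_f] + [hidden] * (layers - 1) + [out_f]
        self.layers = ModuleList([Linear(a, b) for a, b in zip(dims[:-1], dims[1:])])

    def forward(self, x):
        for i, layer in enumerate(self.layers):
            x = layer(x)
            if i < len(self.layers) - 1:
                x = x.relu()
        return x
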