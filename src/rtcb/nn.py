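"""Minimal reverse-mode autodiff over NumPy arrays, with the layer set a
small convolutional classifier needs: 2-D convolution, batch normalisation,
max/global pooling, linear layers, ReLU/sigmoid gates and a fused
softmax-cross-entropy loss, plus SGD with momentum.

All arithmetic is float32. Convolutions are lowered to GEMM via im2col;
their input gradients are folded back with strided accumulation. Every op
is deterministic given its inputs, so fixed seeds give bit-reproducible
training on a given BLAS.
"""

from __future__ import annotations

import json
from typing import Callable, Iterable, Iterator, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Module",
    "Parameter",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "MaxPool2d",
    "GlobalAvgPool2d",
    "ReLU",
    "Sequential",
    "SGD",
    "no_grad",
    "set_grad_enabled",
    "concat",
    "sigmoid",
    "relu",
    "softmax",
    "cross_entropy",
    "conv2d",
    "he_normal",
]

_GRAD_ENABLED = True


class set_grad_enabled:
    """Context manager toggling graph construction (used for eval passes)."""

    def __init__(self, mode: bool) -> None:
        self.mode = mode

    def __enter__(self):
        global _GRAD_ENABLED
        self.prev = _GRAD_ENABLED
        _GRAD_ENABLED = self.mode
        return self

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self.prev
        return False


def no_grad() -> "set_grad_enabled":
    return set_grad_enabled(False)


def _as_f32(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype != np.float32:
        a = a.astype(np.float32)
    return a


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A NumPy array plus the backward closure that produced it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_f32(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple["Tensor", ...] = ()

    # -- graph plumbing ----------------------------------------------------
    @staticmethod
    def _make(data, parents: Sequence["Tensor"], backward) -> "Tensor":
        req = _GRAD_ENABLED and any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS: graphs are deep (ResNet + loss)
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))
        self.grad = _as_f32(grad)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()
                node._backward = None  # free closures as we go
                node._parents = ()

    # -- shape helpers -----------------------------------------------------
    @property
    def shape(self) -> tuple:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def reshape(self, *shape) -> "Tensor":
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out = Tensor._make(self.data.reshape(shape), (self,), None)
        if out.requires_grad:
            def _bwd():
                self._accum(out.grad.reshape(old))
            out._backward = _bwd
        return out

    def permute(self, *axes) -> "Tensor":
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out = Tensor._make(np.ascontiguousarray(self.data.transpose(axes)), (self,), None)
        if out.requires_grad:
            def _bwd():
                self._accum(out.grad.transpose(inv))
            out._backward = _bwd
        return out

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor._make(self.data + other.data, (self, other), None)
        if out.requires_grad:
            def _bwd():
                if self.requires_grad:
                    self._accum(_unbroadcast(out.grad, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(out.grad, other.data.shape))
            out._backward = _bwd
        return out

    __radd__ = __add__

    def __mul__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor._make(self.data * other.data, (self, other), None)
        if out.requires_grad:
            def _bwd():
                if self.requires_grad:
                    self._accum(_unbroadcast(out.grad * other.data, self.data.shape))
                if other.requires_grad:
                    other._accum(_unbroadcast(out.grad * self.data, other.data.shape))
            out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * np.float32(-1.0)

    def __sub__(self, other) -> "Tensor":
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __truediv__(self, other):
        if isinstance(other, (int, float, np.floating)):
            return self * np.float32(1.0 / other)
        raise TypeError("tensor division only by scalars")

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor._make(self.data @ other.data, (self, other), None)
        if out.requires_grad:
            def _bwd():
                if self.requires_grad:
                    self._accum(out.grad @ other.data.T)
                if other.requires_grad:
                    other._accum(self.data.T @ out.grad)
            out._backward = _bwd
        return out

    # -- reductions --------------------------------------------------------
    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        out_data = self.data.mean(axis=axis, keepdims=keepdims, dtype=np.float32)
        out = Tensor._make(out_data, (self,), None)
        if out.requires_grad:
            n = self.data.size if axis is None else np.prod(
                [self.data.shape[a] for a in np.atleast_1d(axis)])
            def _bwd():
                g = out.grad
                if not keepdims and axis is not None:
                    g = np.expand_dims(g, axis)
                elif axis is None and not keepdims:
                    g = np.asarray(g).reshape((1,) * self.data.ndim)
                self._accum(np.broadcast_to(g, self.data.shape) / np.float32(n))
            out._backward = _bwd
        return out

    def max(self, axis: int, keepdims: bool = False) -> "Tensor":
        out_data = self.data.max(axis=axis, keepdims=keepdims)
        out = Tensor._make(out_data, (self,), None)
        if out.requires_grad:
            def _bwd():
                g = out.grad
                o = out_data
                if not keepdims:
                    g = np.expand_dims(g, axis)
                    o = np.expand_dims(o, axis)
                mask = (self.data == o)
                # split ties evenly so the gradient stays well-defined
                counts = mask.sum(axis=axis, keepdims=True)
                self._accum(mask * (g / counts))
            out._backward = _bwd
        return out


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out = Tensor._make(np.concatenate(datas, axis=axis), tuple(tensors), None)
    if out.requires_grad:
        sizes = [d.shape[axis] for d in datas]
        splits = np.cumsum(sizes)[:-1]
        def _bwd():
            parts = np.split(out.grad, splits, axis=axis)
            for t, g in zip(tensors, parts):
                if t.requires_grad:
                    t._accum(g)
        out._backward = _bwd
    return out


def relu(x: Tensor) -> Tensor:
    out = Tensor._make(np.maximum(x.data, 0.0), (x,), None)
    if out.requires_grad:
        def _bwd():
            x._accum(out.grad * (x.data > 0))
        out._backward = _bwd
    return out


def _stable_sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    e = np.exp(z[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = _stable_sigmoid(x.data)
    out = Tensor._make(s, (x,), None)
    if out.requires_grad:
        def _bwd():
            x._accum(out.grad * s * (1.0 - s))
        out._backward = _bwd
    return out


def softmax(logits: np.ndarray) -> np.ndarray:
    """Row-wise softmax of a plain (N, K) array (inference helper)."""
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean softmax cross-entropy; fused forward/backward for stability."""
    n = logits.data.shape[0]
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    loss = -logp[np.arange(n), labels].mean(dtype=np.float32)
    out = Tensor._make(np.float32(loss), (logits,), None)
    if out.requires_grad:
        def _bwd():
            p = np.exp(logp)
            p[np.arange(n), labels] -= 1.0
            logits._accum(out.grad * p / np.float32(n))
        out._backward = _bwd
    return out


# ---------------------------------------------------------------------------
# convolution and pooling primitives
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, pad: int):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - kh) // stride + 1
    wo = (x.shape[3] - kw) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    win = win[:, :, ::stride, ::stride]                      # n,c,ho,wo,kh,kw
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(n * ho * wo, c * kh * kw), (n, c, ho, wo, x.shape[2], x.shape[3])


def _col2im(gcols: np.ndarray, geom, kh: int, kw: int, stride: int, pad: int) -> np.ndarray:
    n, c, ho, wo, hp, wp = geom
    g = gcols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 1, 2, 4, 5)
    gx = np.zeros((n, c, hp, wp), dtype=np.float32)
    for i in range(kh):
        for j in range(kw):
            gx[:, :, i:i + ho * stride:stride, j:j + wo * stride:stride] += g[:, :, :, :, i, j]
    if pad:
        gx = gx[:, :, pad:hp - pad, pad:wp - pad]
    return gx


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """Cross-correlation of (N,Cin,H,W) with (Cout,Cin,kh,kw) kernels."""
    cout, cin, kh, kw = weight.data.shape
    if x.data.shape[1] != cin:
        raise ValueError(
            f"conv2d: input has {x.data.shape[1]} channels, kernel expects {cin}")
    cols, geom = _im2col(x.data, kh, kw, stride, pad)
    n, _, ho, wo, _, _ = geom
    wmat = weight.data.reshape(cout, cin * kh * kw)
    out_data = cols @ wmat.T
    if bias is not None:
        out_data += bias.data
    out_data = out_data.reshape(n, ho, wo, cout).transpose(0, 3, 1, 2)
    parents = (x, weight) if bias is None else (x, weight, bias)
    out = Tensor._make(np.ascontiguousarray(out_data), parents, None)
    if out.requires_grad:
        def _bwd():
            gout = out.grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, cout)
            if weight.requires_grad:
                weight._accum((gout.T @ cols).reshape(weight.data.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(gout.sum(axis=0))
            if x.requires_grad:
                gcols = gout @ wmat
                x._accum(_col2im(gcols, geom, kh, kw, stride, pad))
        out._backward = _bwd
    return out


def max_pool2d(x: Tensor, kernel: int = 3, stride: int = 2, pad: int = 1) -> Tensor:
    n, c, h, w = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                constant_values=-np.inf)
    hp, wp = xp.shape[2], xp.shape[3]
    ho = (hp - kernel) // stride + 1
    wo = (wp - kernel) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (kernel, kernel), axis=(2, 3))
    win = win[:, :, ::stride, ::stride].reshape(n, c, ho, wo, kernel * kernel)
    idx = win.argmax(axis=-1)
    out_data = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]
    out = Tensor._make(out_data, (x,), None)
    if out.requires_grad:
        def _bwd():
            di, dj = np.divmod(idx, kernel)
            oh = np.arange(ho)[None, None, :, None]
            ow = np.arange(wo)[None, None, None, :]
            hi = oh * stride + di
            wi = ow * stride + dj
            nn_, cc = np.meshgrid(np.arange(n), np.arange(c), indexing="ij")
            flat = ((nn_[..., None, None] * c + cc[..., None, None]) * hp + hi) * wp + wi
            gx = np.zeros(n * c * hp * wp, dtype=np.float32)
            np.add.at(gx, flat.ravel(), out.grad.ravel())
            gx = gx.reshape(n, c, hp, wp)
            if pad:
                gx = gx[:, :, pad:hp - pad, pad:wp - pad]
            x._accum(gx)
        out._backward = _bwd
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(np.float32)


class Module:
    """Tiny module system: attribute discovery, train/eval mode, state dict."""

    def __init__(self) -> None:
        self.training = True
        self.last_output_shape: tuple | None = None

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        out = self.forward(x)
        self.last_output_shape = out.data.shape
        return out

    def children(self) -> Iterator["Module"]:
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield item

    def named_modules(self, prefix: str = "") -> Iterator[tuple[str, "Module"]]:
        yield prefix or "root", self
        for k, v in self.__dict__.items():
            items: list[tuple[str, Module]] = []
            if isinstance(v, Module):
                items = [(k, v)]
            elif isinstance(v, (list, tuple)):
                items = [(f"{k}.{i}", m) for i, m in enumerate(v) if isinstance(m, Module)]
            for name, mod in items:
                full = f"{prefix}.{name}" if prefix else name
                yield from mod.named_modules(full)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for k, v in self.__dict__.items():
            full = f"{prefix}.{k}" if prefix else k
            if isinstance(v, Parameter):
                yield full, v
            elif isinstance(v, Module):
                yield from v.named_parameters(full)
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for c in self.children():
            c.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # state (parameters + batch-norm running statistics)
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        for name, mod in self.named_modules():
            if isinstance(mod, BatchNorm2d):
                state[f"{name}.running_mean"] = mod.running_mean
                state[f"{name}.running_var"] = mod.running_var
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for name, p in params.items():
            p.data = _as_f32(state[name]).reshape(p.data.shape)
        for name, mod in self.named_modules():
            if isinstance(mod, BatchNorm2d):
                mod.running_mean = _as_f32(state[f"{name}.running_mean"])
                mod.running_var = _as_f32(state[f"{name}.running_var"])


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 pad: int = 0, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.pad = kernel, stride, pad
        rng = rng or np.random.default_rng(0)
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in))
        self.bias = Parameter(np.zeros(out_ch, dtype=np.float32)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(he_normal(rng, (in_features, out_features), in_features))
        self.bias = Parameter(np.zeros(out_features, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        return x.matmul(self.weight) + self.bias


class BatchNorm2d(Module):
    """Per-channel batch normalisation with running statistics (momentum 0.1)."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.channels = channels
        self.eps = np.float32(eps)
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mean = x.data.mean(axis=(0, 2, 3), dtype=np.float32)
            var = x.data.var(axis=(0, 2, 3), dtype=np.float32)
            m = np.float32(self.momentum)
            self.running_mean = (1 - m) * self.running_mean + m * mean
            self.running_var = (1 - m) * self.running_var + m * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x.data - mean[None, :, None, None]) * inv_std[None, :, None, None]
        out_data = self.gamma.data[None, :, None, None] * xhat + \
            self.beta.data[None, :, None, None]
        out = Tensor._make(out_data, (x, self.gamma, self.beta), None)
        if out.requires_grad:
            training = self.training
            gamma = self.gamma
            beta = self.beta
            def _bwd():
                gy = out.grad
                if gamma.requires_grad:
                    gamma._accum((gy * xhat).sum(axis=(0, 2, 3)))
                if beta.requires_grad:
                    beta._accum(gy.sum(axis=(0, 2, 3)))
                if x.requires_grad:
                    gscale = (gamma.data * inv_std)[None, :, None, None]
                    if training:
                        mean_gy = gy.mean(axis=(0, 2, 3), keepdims=True, dtype=np.float32)
                        mean_gyx = (gy * xhat).mean(axis=(0, 2, 3), keepdims=True,
                                                    dtype=np.float32)
                        x._accum(gscale * (gy - mean_gy - xhat * mean_gyx))
                    else:
                        x._accum(gscale * gy)
            out._backward = _bwd
        return out


class MaxPool2d(Module):
    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        super().__init__()
        self.kernel, self.stride, self.pad = kernel, stride, pad

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel, self.stride, self.pad)


class GlobalAvgPool2d(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.mean(axis=(2, 3))


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class SGD:
    """Momentum SGD with decoupled-from-nothing classic weight decay."""

    def __init__(self, params: Iterable[Parameter], lr: float,
                 momentum: float = 0.9, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._vel = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        lr = np.float32(self.lr)
        mu = np.float32(self.momentum)
        wd = np.float32(self.weight_decay)
        for p, v in zip(self.params, self._vel):
            if p.grad is None:
                continue
            g = p.grad
            if wd:
                g = g + wd * p.data
            v *= mu
            v += g
            p.data -= lr * v


def _ckpt_paths(path: str) -> tuple[str, str]:
    base = path[:-4] if path.endswith(".npz") else path
    return base + ".npz", base + ".json"


def save_state(path: str, model: Module, meta: dict | None = None) -> None:
    """Serialize a model's state dict to `<base>.npz` with a `<base>.json`
    sidecar holding arbitrary metadata."""
    npz_path, json_path = _ckpt_paths(str(path))
    np.savez(npz_path, **model.state_dict())
    if meta is not None:
        with open(json_path, "w") as fh:
            json.dump(meta, fh, indent=2)


def load_state(path: str, model: Module) -> None:
    npz_path, _ = _ckpt_paths(str(path))
    with np.load(npz_path) as npz:
        model.load_state_dict(dict(npz.items()))
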