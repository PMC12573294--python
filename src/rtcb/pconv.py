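"""Partial convolution (PConv) and exact parameter/FLOP accounting.

A partial convolution applies a dense k x k convolution to only the first
c_p of c channels and passes the remaining c - c_p channels through
untouched (bit-identical). Its multiply-accumulate cost on an h x w output
is  S = h * w * k^2 * c_p^2,  so at the default ratio c_p = c/4 a PConv
layer costs 1/16 of the dense convolution it replaces.

The profiler walks a model and reports per-layer parameter and MAC counts;
unknown parameterised layers raise rather than silently contributing zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor


class UnsupportedLayerError(TypeError):
    """Raised when the profiler meets a parameterised layer it cannot count."""


@dataclass(frozen=True)
class PConvSpec:
    """Geometry of a partial convolution: c channels in and out, the first
    c_p convolved densely, the rest passed through."""

    channels: int
    partial_count: int
    kernel: int = 3
    stride: int = 1

    def __post_init__(self):
        if not (1 <= self.partial_count <= self.channels):
            raise ValueError("need 1 <= partial_count <= channels")
        if self.kernel % 2 == 0 or self.kernel < 1:
            raise ValueError("kernel must be odd and positive")
        if self.stride < 1:
            raise ValueError("stride must be positive")

    @property
    def partial_ratio(self) -> float:
        return self.partial_count / self.channels


def pconv_flops(h: int, w: int, k: int, c_p: int) -> int:
    """Multiply-accumulate count of a partial convolution: h*w*k^2*c_p^2."""
    for name, v in (("h", h), ("w", w), ("k", k), ("c_p", c_p)):
        if int(v) != v or v <= 0:
            raise ValueError(f"{name} must be a positive integer, got {v!r}")
    return int(h) * int(w) * int(k) ** 2 * int(c_p) ** 2


class PartialConv2d(nn.Module):
    """Dense convolution on the first c_p channels, identity on the rest.

    Stride is fixed at 1 with same-padding: identity passthrough is not
    defined under spatial subsampling, so strided positions keep dense
    convolutions in the backbone.
    """

    def __init__(self, spec: PConvSpec, rng: np.random.Generator | None = None):
        super().__init__()
        if spec.stride != 1:
            raise ValueError("PartialConv2d requires stride 1 (identity passthrough)")
        self.spec = spec
        self.conv = nn.Conv2d(spec.partial_count, spec.partial_count, spec.kernel,
                              stride=1, pad=(spec.kernel - 1) // 2, bias=False,
                              rng=rng or np.random.default_rng(0))

    def forward(self, x: Tensor) -> Tensor:
        c, cp = self.spec.channels, self.spec.partial_count
        if x.shape[1] != c:
            raise ValueError(f"expected {c} channels, got {x.shape[1]}")
        head = _channel_slice(x, 0, cp)
        out_head = self.conv(head)
        if cp == c:
            return out_head
        tail = _channel_slice(x, cp, c)
        return nn.concat([out_head, tail], axis=1)


def _channel_slice(x: Tensor, lo: int, hi: int) -> Tensor:
    out = Tensor._make(np.ascontiguousarray(x.data[:, lo:hi]), (x,), None)
    if out.requires_grad:
        def _bwd():
            g = np.zeros_like(x.data)
            g[:, lo:hi] = out.grad
            x._accum(g)
        out._backward = _bwd
    return out


# ---------------------------------------------------------------------------
# complexity profiling
# ---------------------------------------------------------------------------

@dataclass
class LayerCost:
    name: str
    kind: str
    params: int
    flops: int


@dataclass
class ComplexityReport:
    """Per-layer parameter and MAC bookkeeping; totals are the column sums."""

    per_layer: list[LayerCost] = field(default_factory=list)

    @property
    def total_params(self) -> int:
        return sum(e.params for e in self.per_layer)

    @property
    def total_flops(self) -> int:
        return sum(e.flops for e in self.per_layer)

    def to_dict(self) -> dict:
        return {
            "layers": [vars(e) for e in self.per_layer],
            "total_params": self.total_params,
            "total_flops": self.total_flops,
        }

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


_STATELESS = (nn.ReLU, nn.MaxPool2d, nn.GlobalAvgPool2d)


def _count_params(mod: nn.Module) -> int:
    return sum(p.data.size for _, p in mod.named_parameters())


def profile(model: nn.Module, input_size: tuple[int, int] | None = None,
            in_channels: int = 3) -> ComplexityReport:
    """Count parameters and forward MACs for every layer of a model.

    Runs one dummy forward pass (eval mode, no gradients) to record output
    shapes, then tabulates: dense convs at h_out*w_out*k^2*c_in*c_out,
    partial convs at the closed form h_out*w_out*k^2*c_p^2, linear layers
    at in*out. Batch-norm contributes its affine parameters and zero MACs.
    The report is a pure function of the architecture, not of the weights.
    """
    if input_size is None:
        input_size = getattr(model, "input_size", (224, 224))
    was_training = model.training
    model.eval()
    with nn.no_grad():
        model(Tensor(np.zeros((1, in_channels) + tuple(input_size), dtype=np.float32)))
    if was_training:
        model.train()

    report = ComplexityReport()
    skip_below: list[str] = []
    for name, mod in model.named_modules():
        if any(name.startswith(p + ".") for p in skip_below):
            continue
        if isinstance(mod, PartialConv2d):
            skip_below.append(name)  # its inner conv is folded into Eq. 10
            _, _, h, w = mod.last_output_shape
            report.per_layer.append(LayerCost(
                name, "pconv", _count_params(mod),
                pconv_flops(h, w, mod.spec.kernel, mod.spec.partial_count)))
        elif isinstance(mod, nn.Conv2d):
            _, cout, h, w = mod.last_output_shape
            flops = h * w * mod.kernel ** 2 * mod.in_ch * cout
            report.per_layer.append(LayerCost(name, "conv", _count_params(mod), flops))
        elif isinstance(mod, nn.Linear):
            report.per_layer.append(LayerCost(
                name, "linear", _count_params(mod),
                mod.in_features * mod.out_features))
        elif isinstance(mod, nn.BatchNorm2d):
            report.per_layer.append(LayerCost(name, "batchnorm", 2 * mod.channels, 0))
        elif isinstance(mod, _STATELESS):
            continue
        else:
            own = [v for v in mod.__dict__.values() if isinstance(v, nn.Parameter)]
            if own:
                raise UnsupportedLayerError(
                    f"profiler cannot count layer {name!r} of type "
                    f"{type(mod).__name__} carrying direct parameters")
            # pure container: its children are visited by the walk
    return report
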