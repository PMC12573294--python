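"""Channel/spatial attention blocks: Z-pool, three-branch triplet attention,
and the convolutional block attention module (CBAM).

All blocks are shape-preserving transforms of channel-first (N, C, H, W)
feature maps. Triplet attention couples the channel axis with each spatial
axis in turn: two branches permute the tensor so that a spatial axis takes
the channel position, compress with Z-pool (per-position max and mean over
the leading axis), convolve the 2-channel map with a single k x k kernel,
sigmoid-gate the permuted input, and permute back; the third branch gates
in the original orientation. The three gated maps are averaged.

CBAM applies a per-channel gate built from global average/max pooled
descriptors passed through a shared bottleneck MLP, then a per-position
gate from a k x k convolution over the channel-pooled 2-channel map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor


@dataclass(frozen=True)
class TripletConfig:
    """Branch convolution geometry for triplet attention.

    kernel_size must be odd so same-padding preserves spatial dims;
    7 is the customary receptive field for attention-gate convolutions.
    """

    kernel_size: int = 7

    def __post_init__(self):
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd and >= 3")

    @property
    def padding(self) -> int:
        return (self.kernel_size - 1) // 2


@dataclass(frozen=True)
class CBAMConfig:
    """CBAM hyper-parameters: channel-MLP reduction ratio and the spatial
    gate's kernel size. The bottleneck width is clamped to >= 1 for layers
    narrower than `reduction`."""

    reduction: int = 16
    spatial_kernel: int = 7

    def __post_init__(self):
        if self.reduction < 1:
            raise ValueError("reduction must be positive")
        if self.spatial_kernel % 2 == 0:
            raise ValueError("spatial_kernel must be odd")


def z_pool(m: Tensor) -> Tensor:
    """Compress the channel axis to 2 channels: [per-position max, mean].

    Channel 0 is the elementwise maximum over input channels, channel 1 the
    mean, so channel 0 >= channel 1 everywhere.
    """
    if m.ndim != 4 or m.shape[1] < 1 or 0 in m.shape:
        raise ValueError(f"z_pool expects a non-empty 4-D map, got shape {m.shape}")
    return nn.concat([m.max(axis=1, keepdims=True),
                      m.mean(axis=1, keepdims=True)], axis=1)


_ROTATIONS = {
    # ccw about H exchanges the C and W axes; ccw about W exchanges C and H.
    # Both are transpositions, hence self-inverse: cw applies the same
    # permutation and exactly undoes ccw.
    ("H", "ccw"): (0, 3, 2, 1),
    ("H", "cw"): (0, 3, 2, 1),
    ("W", "ccw"): (0, 2, 1, 3),
    ("W", "cw"): (0, 2, 1, 3),
}


def rotate(x: Tensor, axis: str, direction: str = "ccw") -> Tensor:
    """90-degree rotation of a feature map about a spatial axis, realised as
    a pure axis permutation (no values change, only the layout)."""
    key = (axis, direction)
    if key not in _ROTATIONS:
        raise ValueError(f"unknown rotation axis={axis!r} direction={direction!r}")
    return x.permute(_ROTATIONS[key])


class TripletAttention(nn.Module):
    """Three-branch cross-dimension attention; output = mean of the three
    gated maps, same shape as the input."""

    def __init__(self, cfg: TripletConfig = TripletConfig(),
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        k, p = cfg.kernel_size, cfg.padding
        rng = rng or np.random.default_rng(0)
        # each branch convolves the 2-channel Z-pool map down to 1 gate channel
        self.branch_h = nn.Conv2d(2, 1, k, pad=p, rng=rng)
        self.branch_w = nn.Conv2d(2, 1, k, pad=p, rng=rng)
        self.branch_c = nn.Conv2d(2, 1, k, pad=p, rng=rng)
        for conv in (self.branch_h, self.branch_w, self.branch_c):
            if conv.weight.data.shape[:2] != (1, 2):
                raise ValueError("triplet branch conv must map 2 channels -> 1")

    @staticmethod
    def _gated(x: Tensor, conv: nn.Conv2d) -> Tensor:
        return x * nn.sigmoid(conv(z_pool(x)))

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4:
            raise ValueError("triplet attention expects (N, C, H, W)")
        xh = rotate(x, "H", "ccw")                      # couple C with W
        yh = rotate(self._gated(xh, self.branch_h), "H", "cw")
        xw = rotate(x, "W", "ccw")                      # couple C with H
        yw = rotate(self._gated(xw, self.branch_w), "W", "cw")
        yc = self._gated(x, self.branch_c)              # plain orientation
        return (yh + yw + yc) / 3.0


class ChannelGate(nn.Module):
    """Per-channel sigmoid gate from GAP/GMP descriptors through a shared
    two-layer bottleneck MLP: sigma(MLP(gap) + MLP(gmp))."""

    def __init__(self, channels: int, cfg: CBAMConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.channels = channels
        hidden = max(1, channels // cfg.reduction)
        rng = rng or np.random.default_rng(0)
        self.fc1 = nn.Linear(channels, hidden, rng=rng)
        self.fc2 = nn.Linear(hidden, channels, rng=rng)

    def _mlp(self, v: Tensor) -> Tensor:
        return self.fc2(nn.relu(self.fc1(v)))

    def forward(self, f: Tensor) -> Tensor:
        gap = f.mean(axis=(2, 3))                       # (N, C)
        gmp = f.max(axis=3).max(axis=2)                 # (N, C)
        gate = nn.sigmoid(self._mlp(gap) + self._mlp(gmp))
        n, c = gate.shape
        return gate.reshape(n, c, 1, 1)


class SpatialGate(nn.Module):
    """Per-position sigmoid gate: k x k convolution over the 2-channel
    [channel-max, channel-mean] map with same-padding."""

    def __init__(self, cfg: CBAMConfig, rng: np.random.Generator | None = None):
        super().__init__()
        k = cfg.spatial_kernel
        self.conv = nn.Conv2d(2, 1, k, pad=(k - 1) // 2,
                              rng=rng or np.random.default_rng(0))

    def forward(self, f: Tensor) -> Tensor:
        return nn.sigmoid(self.conv(z_pool(f)))


class CBAM(nn.Module):
    """Sequential channel-then-spatial attention: F' = F * channel_gate(F),
    output = F' * spatial_gate(F'). Shape preserving."""

    def __init__(self, channels: int, cfg: CBAMConfig = CBAMConfig(),
                 rng: np.random.Generator | None = None,
                 identity_bypass: bool = False):
        super().__init__()
        self.cfg = cfg
        rng = rng or np.random.default_rng(0)
        self.channel_gate = ChannelGate(channels, cfg, rng=rng)
        self.spatial_gate = SpatialGate(cfg, rng=rng)
        # test hook: treat both gates as exactly 1 (the sigmoid's open limit)
        self.identity_bypass = identity_bypass

    def forward(self, f: Tensor) -> Tensor:
        if self.identity_bypass:
            return f
        f2 = f * self.channel_gate(f)
        return f2 * self.spatial_gate(f2)
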