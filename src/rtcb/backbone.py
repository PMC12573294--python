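"""ResNet18 variants with attention and partial-convolution placements.

The modified network (the "rtcb" variant) follows three edits to a standard
ResNet18 skeleton (7x7/2 stem conv -> BN -> ReLU -> 3x3/2 max-pool -> four
stages of two basic blocks -> global average pool -> linear head):

* a triplet-attention block directly after the stem activation, before the
  max-pool, where the feature map still carries raw texture/contour detail;
* a CBAM block on each basic block's second-conv output (after its BN),
  before the residual addition, so the attention-refined features are fused
  with the identity path;
* partial convolutions replacing the stride-1 3x3 convolutions inside the
  basic blocks (identity passthrough is undefined under stride, so the
  stride-2 convolutions opening stages 2-4 stay dense).

Every edit is independently toggleable, giving the six-variant ablation
grid. The stem 7x7 convolution is never replaced.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .attention import CBAM, CBAMConfig, TripletAttention, TripletConfig
from .nn import Tensor
from .pconv import PartialConv2d, PConvSpec


@dataclass(frozen=True)
class PConvPolicy:
    """Which block convolutions become partial, and at what ratio.

    replace="all" converts every stride-1 3x3 block conv; "second_only"
    converts only each block's second conv. partial_ratio is c_p / c.
    """

    enabled: bool = False
    partial_ratio: float = 0.25
    replace: str = "all"

    def __post_init__(self):
        if not 0 < self.partial_ratio <= 1:
            raise ValueError("partial_ratio must lie in (0, 1]")
        if self.replace not in ("all", "second_only"):
            raise ValueError("replace must be 'all' or 'second_only'")

    def partial_count(self, channels: int) -> int:
        return max(1, int(round(channels * self.partial_ratio)))


VARIANTS: dict[str, dict[str, bool]] = {
    "resnet18": dict(triplet=False, cbam=False, pconv=False),
    "resnet18_triplet": dict(triplet=True, cbam=False, pconv=False),
    "resnet18_cbam": dict(triplet=False, cbam=True, pconv=False),
    "resnet18_cbam_pconv": dict(triplet=False, cbam=True, pconv=True),
    "resnet18_cbam_triplet": dict(triplet=True, cbam=True, pconv=False),
    "rtcb": dict(triplet=True, cbam=True, pconv=True),
}


@dataclass(frozen=True)
class VariantSpec:
    name: str = "rtcb"
    num_classes: int = 5
    input_size: tuple[int, int] = (224, 224)
    triplet_cfg: TripletConfig = field(default_factory=TripletConfig)
    cbam_cfg: CBAMConfig = field(default_factory=CBAMConfig)
    pconv_policy: PConvPolicy = field(default_factory=PConvPolicy)

    def __post_init__(self):
        if self.name not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.name!r}; choose from {sorted(VARIANTS)}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")

    @property
    def flags(self) -> dict[str, bool]:
        flags = dict(VARIANTS[self.name])
        if flags["pconv"]:
            flags["pconv"] = self.pconv_policy.enabled or True
        return flags

    def to_dict(self) -> dict:
        d = asdict(self)
        d["input_size"] = list(self.input_size)
        return d

    @staticmethod
    def from_dict(d: dict) -> "VariantSpec":
        return VariantSpec(
            name=d["name"],
            num_classes=d["num_classes"],
            input_size=tuple(d["input_size"]),
            triplet_cfg=TripletConfig(**d["triplet_cfg"]),
            cbam_cfg=CBAMConfig(**d["cbam_cfg"]),
            pconv_policy=PConvPolicy(**d["pconv_policy"]),
        )


class BasicBlock(nn.Module):
    """Two-3x3-conv residual unit with optional CBAM and PConv edits."""

    def __init__(self, in_ch: int, out_ch: int, stride: int,
                 use_cbam: bool, cbam_cfg: CBAMConfig,
                 pconv: PConvPolicy, rng: np.random.Generator):
        super().__init__()
        def block_conv(cin, cout, s, position):
            eligible = (
                pconv.enabled and s == 1 and cin == cout
                and (pconv.replace == "all" or position == "second")
            )
            if eligible:
                return PartialConv2d(
                    PConvSpec(cout, pconv.partial_count(cout), kernel=3), rng=rng)
            return nn.Conv2d(cin, cout, 3, stride=s, pad=1, bias=False, rng=rng)

        self.conv1 = block_conv(in_ch, out_ch, stride, "first")
        self.bn1 = nn.BatchNorm2d(out_ch)
        self.conv2 = block_conv(out_ch, out_ch, 1, "second")
        self.bn2 = nn.BatchNorm2d(out_ch)
        self.cbam = CBAM(out_ch, cbam_cfg, rng=rng) if use_cbam else None
        if stride != 1 or in_ch != out_ch:
            self.down_conv = nn.Conv2d(in_ch, out_ch, 1, stride=stride,
                                       bias=False, rng=rng)
            self.down_bn = nn.BatchNorm2d(out_ch)
        else:
            self.down_conv = None
            self.down_bn = None

    def forward(self, x: Tensor) -> Tensor:
        y = nn.relu(self.bn1(self.conv1(x)))
        y = self.bn2(self.conv2(y))
        if self.cbam is not None:
            y = self.cbam(y)
        shortcut = x if self.down_conv is None else self.down_bn(self.down_conv(x))
        return nn.relu(y + shortcut)


_STAGE_CHANNELS = (64, 128, 256, 512)


class ResNet(nn.Module):
    def __init__(self, spec: VariantSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.input_size = tuple(spec.input_size)
        flags = spec.flags
        self.stem_conv = nn.Conv2d(3, 64, 7, stride=2, pad=3, bias=False, rng=rng)
        self.stem_bn = nn.BatchNorm2d(64)
        self.triplet = TripletAttention(spec.triplet_cfg, rng=rng) \
            if flags["triplet"] else None
        self.maxpool = nn.MaxPool2d(3, 2, 1)
        pconv = spec.pconv_policy if flags["pconv"] else PConvPolicy(enabled=False)
        if flags["pconv"] and not pconv.enabled:
            pconv = PConvPolicy(enabled=True, partial_ratio=pconv.partial_ratio,
                                replace=pconv.replace)
        blocks: list[BasicBlock] = []
        in_ch = 64
        for si, out_ch in enumerate(_STAGE_CHANNELS):
            for bi in range(2):
                stride = 2 if (si > 0 and bi == 0) else 1
                blocks.append(BasicBlock(in_ch, out_ch, stride, flags["cbam"],
                                         spec.cbam_cfg, pconv, rng))
                in_ch = out_ch
        self.blocks = blocks
        self.gap = nn.GlobalAvgPool2d()
        self.fc = nn.Linear(512, spec.num_classes, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got shape {x.shape}")
        y = nn.relu(self.stem_bn(self.stem_conv(x)))
        if self.triplet is not None:
            y = self.triplet(y)
        y = self.maxpool(y)
        for block in self.blocks:
            y = block(y)
        return self.fc(self.gap(y))


def build_variant(spec: VariantSpec | str, seed: int = 0) -> ResNet:
    """Build a deterministic, freshly initialised variant.

    Convolution and linear weights are He-normal draws from a generator
    seeded with `seed`; batch-norm affines start at identity and gate
    biases at zero, so an untrained model's attention gates sit near 0.5.
    """
    if isinstance(spec, str):
        spec = VariantSpec(name=spec)
    return ResNet(spec, np.random.default_rng(seed))


def predict(model: ResNet, images: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Class probabilities (softmax over logits) and argmax labels.

    `images` must already be resized/normalised to the model's input
    contract. Ties break toward the lowest class index.
    """
    images = np.asarray(images, dtype=np.float32)
    if images.ndim != 4 or images.shape[1] != 3:
        raise ValueError(f"expected (N, 3, H, W) images, got {images.shape}")
    was_training = model.training
    model.eval()
    with nn.no_grad():
        logits = model(Tensor(images)).data
    if was_training:
        model.train()
    probs = nn.softmax(logits)
    return probs, probs.argmax(axis=1)


def placement_audit(model: ResNet) -> dict[str, int]:
    """Count attention/PConv insertions for structural verification."""
    counts = {"triplet": 0, "cbam": 0, "pconv": 0}
    for _, mod in model.named_modules():
        if isinstance(mod, TripletAttention):
            counts["triplet"] += 1
        elif isinstance(mod, CBAM):
            counts["cbam"] += 1
        elif isinstance(mod, PartialConv2d):
            counts["pconv"] += 1
    return counts


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(model: ResNet, path: str | Path, *, epoch: int | None = None,
                    seed: int | None = None, extra: dict | None = None) -> None:
    """Single-file NPZ of all learnable state plus a JSON sidecar with the
    variant spec, epoch and seed, sufficient to rebuild the model exactly."""
    path = str(path)
    meta = {"spec": model.spec.to_dict(), "epoch": epoch, "seed": seed}
    if extra:
        meta.update(extra)
    nn.save_state(path, model, meta=meta)


def load_checkpoint(path: str | Path) -> tuple[ResNet, dict]:
    path = str(path)
    base = path[:-4] if path.endswith(".npz") else path
    with open(base + ".json") as fh:
        meta = json.load(fh)
    model = build_variant(VariantSpec.from_dict(meta["spec"]))
    nn.load_state(path, model)
    model.eval()
    return model, meta
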