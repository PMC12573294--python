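"""Portable model export for deployment-style inference.

`export_model` flattens a trained backbone into a framework-neutral
register program — a JSON list of primitive instructions (conv, batchnorm,
relu, sigmoid, pooling, slice/concat, linear, ...) plus an NPZ of weight
arrays — the same role an ONNX graph plays for a mobile runtime.
`run_exported` is a self-contained inference interpreter for that program:
it shares no code with the training graph (convolutions are evaluated by
einsum contraction over sliding windows rather than im2col GEMM, and batch
norm is frozen to its running statistics), so export-vs-native parity is a
genuine two-implementation check.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import nn
from .attention import CBAM, TripletAttention, _ROTATIONS
from .backbone import BasicBlock, ResNet, VariantSpec
from .pconv import PartialConv2d


class ExportError(RuntimeError):
    """Raised when a model contains a layer the exporter cannot serialize."""


class _Emitter:
    def __init__(self) -> None:
        self.instrs: list[dict] = []
        self.weights: dict[str, np.ndarray] = {}
        self._n = 0

    def reg(self) -> str:
        self._n += 1
        return f"r{self._n}"

    def emit(self, op: str, ins: list[str], attrs: dict | None = None,
             **arrays: np.ndarray | None) -> str:
        out = self.reg()
        idx = len(self.instrs)
        wkeys = {}
        for k, a in arrays.items():
            if a is None:
                continue
            key = f"i{idx}_{k}"
            self.weights[key] = np.asarray(a, dtype=np.float32)
            wkeys[k] = key
        self.instrs.append({"op": op, "in": ins, "out": out,
                            "attrs": attrs or {}, "weights": wkeys})
        return out

    # -- module lowering ---------------------------------------------------
    def conv(self, x: str, conv: nn.Conv2d) -> str:
        return self.emit("conv", [x],
                         {"stride": conv.stride, "pad": conv.pad},
                         weight=conv.weight.data,
                         bias=None if conv.bias is None else conv.bias.data)

    def bn(self, x: str, bn: nn.BatchNorm2d) -> str:
        return self.emit("batchnorm", [x], {"eps": float(bn.eps)},
                         gamma=bn.gamma.data, beta=bn.beta.data,
                         mean=bn.running_mean, var=bn.running_var)

    def linear(self, x: str, fc: nn.Linear) -> str:
        return self.emit("linear", [x], weight=fc.weight.data, bias=fc.bias.data)

    def triplet(self, x: str, block: TripletAttention) -> str:
        gated = []
        for axis, conv in (("H", block.branch_h), ("W", block.branch_w),
                           (None, block.branch_c)):
            t = x if axis is None else \
                self.emit("permute", [x], {"axes": list(_ROTATIONS[(axis, "ccw")])})
            z = self.emit("zpool", [t])
            s = self.emit("sigmoid", [self.conv(z, conv)])
            m = self.emit("mul", [t, s])
            gated.append(m if axis is None else
                         self.emit("permute", [m],
                                   {"axes": list(_ROTATIONS[(axis, "cw")])}))
        acc = self.emit("add", [gated[0], gated[1]])
        acc = self.emit("add", [acc, gated[2]])
        return self.emit("scale", [acc], {"factor": 1.0 / 3.0})

    def cbam(self, x: str, block: CBAM) -> str:
        cg = block.channel_gate
        branches = []
        for pool in ("global_avg", "global_max"):
            v = self.emit(pool, [x])
            v = self.linear(self.emit("relu", [self.linear(v, cg.fc1)]), cg.fc2)
            branches.append(v)
        gate = self.emit("sigmoid", [self.emit("add", branches)])
        f2 = self.emit("mul", [x, self.emit("unsqueeze2", [gate])])
        sp = self.emit("sigmoid", [self.conv(self.emit("zpool", [f2]),
                                             block.spatial_gate.conv)])
        return self.emit("mul", [f2, sp])

    def block_conv(self, x: str, conv) -> str:
        if isinstance(conv, PartialConv2d):
            c, cp = conv.spec.channels, conv.spec.partial_count
            head = self.emit("slice", [x], {"lo": 0, "hi": cp})
            head = self.conv(head, conv.conv)
            if cp == c:
                return head
            tail = self.emit("slice", [x], {"lo": cp, "hi": c})
            return self.emit("concat", [head, tail])
        if isinstance(conv, nn.Conv2d):
            return self.conv(x, conv)
        raise ExportError(f"unsupported convolution layer {type(conv).__name__}")

    def basic_block(self, x: str, block: BasicBlock) -> str:
        y = self.emit("relu", [self.bn(self.block_conv(x, block.conv1), block.bn1)])
        y = self.bn(self.block_conv(y, block.conv2), block.bn2)
        if block.cbam is not None:
            y = self.cbam(y, block.cbam)
        shortcut = x
        if block.down_conv is not None:
            shortcut = self.bn(self.conv(x, block.down_conv), block.down_bn)
        return self.emit("relu", [self.emit("add", [y, shortcut])])


def export_model(model: ResNet, path: str | Path) -> tuple[str, str]:
    """Export to `<base>.json` (program) + `<base>.npz` (weights).

    The exported graph has fixed input shape (1, 3, *input_size) recorded
    in its header; the interpreter accepts any batch size.
    """
    if not isinstance(model, ResNet):
        raise ExportError(f"can only export backbone models, got {type(model).__name__}")
    em = _Emitter()
    x = "input"
    y = em.emit("relu", [em.bn(em.conv(x, model.stem_conv), model.stem_bn)])
    if model.triplet is not None:
        y = em.triplet(y, model.triplet)
    y = em.emit("maxpool", [y], {"kernel": 3, "stride": 2, "pad": 1})
    for block in model.blocks:
        y = em.basic_block(y, block)
    y = em.linear(em.emit("global_avg", [y]), model.fc)

    base = str(path)
    if base.endswith(".json") or base.endswith(".npz"):
        base = base[:-5] if base.endswith(".json") else base[:-4]
    graph = {
        "format": "rtcb-inference-graph/1",
        "input": "input",
        "input_shape": [1, 3, *model.input_size],
        "output": y,
        "spec": model.spec.to_dict(),
        "instructions": em.instrs,
    }
    with open(base + ".json", "w") as fh:
        json.dump(graph, fh)
    np.savez(base + ".npz", **em.weights)
    return base + ".json", base + ".npz"


# ---------------------------------------------------------------------------
# independent interpreter
# ---------------------------------------------------------------------------

def _windows(x: np.ndarray, k: int, stride: int, pad: int,
             fill: float = 0.0) -> np.ndarray:
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)),
                constant_values=fill)
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def _run_instr(instr: dict, regs: dict, w: dict) -> np.ndarray:
    op = instr["op"]
    a = instr["attrs"]
    ins = [regs[name] for name in instr["in"]]
    wt = {k: w[key] for k, key in instr["weights"].items()}
    if op == "conv":
        x, kernel = ins[0], wt["weight"]
        win = _windows(x, kernel.shape[2], a["stride"], a["pad"])
        out = np.einsum("nchwij,ocij->nohw", win, kernel, optimize=True)
        if "bias" in wt:
            out += wt["bias"][None, :, None, None]
        return out.astype(np.float32)
    if op == "batchnorm":
        x = ins[0]
        scale = wt["gamma"] / np.sqrt(wt["var"] + np.float32(a["eps"]))
        shift = wt["beta"] - wt["mean"] * scale
        return x * scale[None, :, None, None] + shift[None, :, None, None]
    if op == "linear":
        return ins[0] @ wt["weight"] + wt["bias"]
    if op == "relu":
        return np.maximum(ins[0], 0.0)
    if op == "sigmoid":
        z = ins[0]
        out = np.empty_like(z)
        pos = z >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
        e = np.exp(z[~pos])
        out[~pos] = e / (1.0 + e)
        return out
    if op == "maxpool":
        win = _windows(ins[0], a["kernel"], a["stride"], a["pad"], fill=-np.inf)
        return win.max(axis=(4, 5))
    if op == "global_avg":
        return ins[0].mean(axis=(2, 3), dtype=np.float32)
    if op == "global_max":
        return ins[0].max(axis=(2, 3))
    if op == "zpool":
        x = ins[0]
        return np.concatenate([x.max(axis=1, keepdims=True),
                               x.mean(axis=1, keepdims=True, dtype=np.float32)], axis=1)
    if op == "permute":
        return np.ascontiguousarray(ins[0].transpose(a["axes"]))
    if op == "add":
        return ins[0] + ins[1]
    if op == "mul":
        return ins[0] * ins[1]
    if op == "scale":
        return ins[0] * np.float32(a["factor"])
    if op == "slice":
        return ins[0][:, a["lo"]:a["hi"]]
    if op == "concat":
        return np.concatenate(ins, axis=1)
    if op == "unsqueeze2":
        return ins[0][:, :, None, None]
    raise ExportError(f"unknown instruction {op!r}")


def run_exported(path: str | Path, x: np.ndarray) -> np.ndarray:
    """Evaluate an exported graph on a batch of images; returns logits."""
    base = str(path)
    if base.endswith(".json") or base.endswith(".npz"):
        base = base[:-5] if base.endswith(".json") else base[:-4]
    with open(base + ".json") as fh:
        graph = json.load(fh)
    with np.load(base + ".npz") as npz:
        weights = dict(npz.items())
    x = np.asarray(x, dtype=np.float32)
    expected = graph["input_shape"]
    if x.ndim != 4 or list(x.shape[1:]) != expected[1:]:
        raise ValueError(f"input shape {x.shape} does not match exported "
                         f"graph contract (N, {expected[1]}, {expected[2]}, "
                         f"{expected[3]})")
    regs: dict[str, np.ndarray] = {graph["input"]: x}
    for instr in graph["instructions"]:
        regs[instr["out"]] = _run_instr(instr, regs, weights)
    return regs[graph["output"]]


def export_parity(model: ResNet, path: str | Path, n: int = 16,
                  seed: int = 0) -> float:
    """Max |native - exported| logit difference over n random inputs."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, 3, *model.input_size)).astype(np.float32)
    was_training = model.training
    model.eval()
    with nn.no_grad():
        native = model(nn.Tensor(x)).data
    if was_training:
        model.train()
    exported = run_exported(path, x)
    return float(np.abs(native - exported).max())
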