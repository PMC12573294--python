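# rtcb

Garlic leaf diseases — botrytis, rust, blight and purple spot — are a major
yield risk, and field diagnosis by eye is slow and error-prone. `rtcb`
implements a lightweight convolutional classifier for five-way garlic leaf
diagnosis (four diseases plus healthy), built as a modified ResNet18 that
trades a small amount of dense computation for attention:

* **Triplet attention** after the stem convolution. Three branches couple
  the channel axis with each spatial axis: two branches permute the
  (N, C, H, W) map so a spatial axis takes the channel position, compress
  with **Z-pool** (per-position channel max ⊕ channel mean), convolve the
  2-channel map with one k×k kernel, and sigmoid-gate the permuted input;
  the third gates in the original orientation. The output is the mean of
  the three gated maps, X′ = (X\*_H + X\*_W + X\*)/3.
* **CBAM** inside every residual block, after the second 3×3 convolution's
  batch norm and before the shortcut addition: a channel gate
  σ(MLP(F_GAP) + MLP(F_GMP)) with a shared bottleneck MLP (reduction r),
  then a spatial gate σ(W_k ∗ [max_c F; mean_c F]).
* **Partial convolution (PConv)** replacing every stride-1 3×3 block
  convolution: a dense convolution over only the first c_p of c channels,
  identity on the rest. Its multiply–accumulate cost is
  S = h·w·k²·c_p², exactly 1/16 of the dense cost at the default
  c_p = c/4.

The real garlic dataset behind this line of work is private, so the package
ships a deterministic synthetic leaf generator with class-specific lesion
phenotypes and a controllable difficulty dial, making the whole pipeline —
splitting, augmentation, training, evaluation, profiling, export — testable
end to end. The network stack (reverse-mode autodiff, convolution, batch
norm, pooling, SGD) is implemented in NumPy inside the package; there is no
deep-learning framework dependency.

## Worked example

```python
import numpy as np
from rtcb import (VariantSpec, build_variant, generate_arrays,
                  largest_remainder_quotas, profile, TrainConfig, train)

# 5 classes x 100 synthetic 96x96 leaves, fully colour-separable preset
images, labels = generate_arrays(100, seed=1, image_size=96,
                                 difficulty="separable")

# per-class 3:1:1 split (largest remainder, ties to the later split)
rng = np.random.default_rng(1)
tr, va = [], []
for c in range(5):
    idx = np.where(labels == c)[0]; rng.shuffle(idx)
    q = largest_remainder_quotas(len(idx), (3, 1, 1))   # -> [60, 20, 20]
    tr += list(idx[:q[0]]); va += list(idx[q[0]:q[0] + q[1]])
tr, va = np.array(tr), np.array(va)

model = build_variant(VariantSpec(name="rtcb", input_size=(96, 96)), seed=1)
print(profile(model).total_params)        # 2421886
history, meta = train(model, images[tr], labels[tr], images[va], labels[va],
                      TrainConfig(epochs=10, batch_size=32, seed=1))
print(round(meta["best_val_acc"], 2))     # 0.94
```

The profiler output is the parameter count of the full model (2.42 M,
versus 11 179 077 for the plain ResNet18 with a 5-class head — the attention
blocks add little and PConv removes most of the block-conv weight). The
final line is the best validation accuracy of the 10-epoch scaled-down run:
0.94, i.e. 94 of the 100 held-out synthetic leaves classified correctly.

The same pipeline is scriptable from the shell:

```bash
rtcb generate --set data.n_per_class=100
rtcb split
rtcb train --out runs
rtcb eval  --checkpoint runs/checkpoint --out runs/eval
rtcb profile --out runs
rtcb export --checkpoint runs/checkpoint --out runs
```

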