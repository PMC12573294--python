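# Methods

## Model

The classifier is a ResNet18 skeleton (7×7/2 stem conv → BN → ReLU → 3×3/2
max-pool → four stages of two basic blocks at 64/128/256/512 channels →
global average pool → linear head) with three structural edits, each
independently toggleable so the six-variant ablation grid (`resnet18`,
`+triplet`, `+cbam`, `+cbam+pconv`, `+cbam+triplet`, `rtcb`) can be built
from one spec.

**Triplet attention** sits after the stem activation and before the
max-pool, where the feature map still carries raw texture and contour
information. The "rotations" of the two cross-dimension branches are
implemented as pure axis permutations (counter-clockwise about H swaps the
C and W axes; about W swaps C and H), which are self-inverse; the branch
then Z-pools over the leading axis, convolves the 2-channel map with a
single k×k kernel (2 → 1 channels), sigmoid-gates the permuted input, and
permutes back. The three gated maps are averaged. No separate recurrent
unit follows the block: the averaged map feeds the next backbone stage,
whose own convolution plays that role.

**CBAM** is applied to each basic block's second-conv output after its
batch norm and before the residual addition — the standard CBAM-ResNet
recipe — so the attention-refined features are fused with the identity
path and the block keeps its identity-mapping property. The channel gate
is the shared-bottleneck-MLP form σ(MLP(gap) + MLP(gmp)); the spatial gate
convolves the channel-pooled 2-channel map. We read the single-kernel
fusion sometimes written for this block as the channel-gate formula and
keep the conventional two-stage structure; this is a deliberate reading,
documented here rather than hidden.

**Partial convolution** replaces block convolutions only where the stride
is 1 and input/output channel counts match, because identity passthrough
of the untouched channels is undefined under spatial subsampling: the
stride-2 convolutions opening stages 2–4 stay dense, as does the stem.
With the default `replace="all"` policy this converts 13 of the 16 block
convolutions (all 8 second convs plus the 5 stride-1 first convs); a
`second_only` policy (8 layers) is available because the narrative around
this design is ambiguous about the replacement set. The convolved slice is
the *first* c_p channels (the alternative "last" slice is symmetric).

Gates contain no batch norm (conv/MLP + sigmoid only). Weights are
He-normal with zero-initialised biases, so a freshly built model's gates
sit at 0.5 — which gives the closed forms used in tests: zero-weight
triplet attention returns X/2 and zero-weight CBAM returns F/4.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| triplet/CBAM gate kernel k | 7 (padding 3) | the customary receptive field for attention-gate convolutions; configurable |
| CBAM reduction r | 16, clamped so the bottleneck ≥ 1 | standard bottleneck ratio; clamping keeps narrow layers valid |
| PConv partial ratio c_p/c | 1/4 | the ratio at which the partial/dense cost fraction is exactly (1/4)² = 1/16 |
| optimiser | SGD, momentum 0.9, weight decay 5e-4 | conventional ResNet recipe; the optimiser itself is not specified by the protocol this follows |
| learning rate | cosine, lr_max 0.02 → lr_min 1e-5 | 0.02 and 0.001 are the two probed fixed rates; cosine annealing between a high start and a near-zero floor bounds both |
| batch size | 32 | unstated upstream; standard for this model size |
| epochs | 100 (10 in the scaled-down runs) | the full protocol trains 100 epochs with no early stopping |
| BN eps / momentum | 1e-5 / 0.1 | framework-conventional values |

## Data splitting

Splitting is stratified: each class is shuffled and partitioned 3:1:1
independently. Integer quotas are floors of n·r_i/Σr with leftovers
assigned by largest fractional remainder, ties broken toward the later
split (test receives before val). This policy reproduces four of the five
published per-class train/val/test rows exactly (botrytis 1177/392/392,
rust 1124/374/375 — the tie case, blight 975/325/325, healthy
1108/369/369). The published purple row, 1055/358/358 of 1771, is not a
3:1:1 partition of its total under any rounding rule (1055/1771 ≈ 59.6 %);
the procedure yields 1063/354/354 and the discrepancy is documented rather
than chased.

## Synthetic data: what it does and does not show

The generator draws an elongated green blade at a random tilt on a soil
background (optionally cluttered with blurred colour blobs) and composites
class-specific lesions: large irregular soft-edged gray-brown patches
(botrytis), many small round orange pustules (rust), brown necrosis
advancing from the tip with a ragged margin (blight), elongated
purple-centred spots with a pale halo (purple), or nothing (healthy). All
randomness flows from one integer seed through `numpy` generators, so
identical specs give bit-identical images on any platform.

Lesion palettes are deliberately disjoint in colour space: with
`color_jitter=0` and a plain background (the "separable" preset) a
nearest-centroid classifier on mean lesion colour scores 100 %, and
raising jitter/clutter degrades it monotonically (measured ≈ 0.98 at
"moderate", ≈ 0.85 at "hard"). This makes the scaled-down training check
meaningful — the network must actually learn the colour/shape phenotypes —
but it bounds what a pass demonstrates: the synthetic classes lack the
texture detail, lighting variation, occlusion and intra-class morphology
of field photographs, so results here demonstrate pipeline correctness and
model capacity, not field accuracy.

## Training at desk scale

The regression run trains the full `rtcb` variant on 5×100 synthetic
96×96 images (per-class 3:1:1 split → 300 train / 100 val), 10 epochs,
batch 32, the default SGD/cosine settings, one fixed seed. These sizes are
the package's chosen desk-scale study conditions; at them the run reaches
0.94 best validation accuracy in a few minutes on one CPU. The scaled run
trains without photometric augmentation: the separable preset contains no
lighting variation to robustify against, and at 10 epochs augmentation
only measures schedule length, not capacity (with the default augmentation
on, the same run reaches 0.86 and is still improving at epoch 10 —
consistent with augmentation acting as regularisation). Full-length runs
on real data should keep augmentation on.

## Profiling conventions

FLOPs are multiply–accumulate counts: dense convolutions at
h_out·w_out·k²·c_in·c_out, partial convolutions at the closed form
h_out·w_out·k²·c_p², linear layers at in·out. Batch-norm layers contribute
their 2c affine parameters and zero MACs; activations and pools are free.
Unknown parameterised layers raise rather than silently contributing zero.
Under these conventions the plain ResNet18 with a 5-class head counts
11 179 077 parameters (the standard 11 689 512 minus the 1000-class head
plus the 5-class head), and the full model counts 2 421 886. Published
figures quoted under other conventions (e.g. counting each MAC as two
FLOPs, or different replacement sets) are not reproduced by this
bookkeeping and are not targeted.

## Export

Models export to a framework-neutral inference graph: a JSON program of
primitive instructions plus an NPZ of weights, executed by a
self-contained interpreter that shares no code with the training graph
(einsum-contracted convolutions instead of im2col GEMM, batch norm frozen
to running statistics). The parity contract — max |native − exported|
logit difference ≤ 1e-4 over 16 random inputs — is therefore a genuine
two-implementation check; measured parity is ~1e-5 for every variant.

## Numerical choices

* All arithmetic is float32; oracle-equivalence tests use 1e-5 absolute
  tolerance against float64 loop references.
* Sigmoid is computed in the numerically stable split form; softmax and
  cross-entropy subtract the row max before exponentiating.
* The max-reduction gradient splits ties evenly among maximising entries;
  argmax prediction ties break toward the lowest class index.
* Batch-norm backward uses the standard whitened-gradient formula in
  training mode and the frozen-affine form in eval mode.
* Undefined evaluation metrics (zero denominators, e.g. precision of a
  never-predicted class) are NaN-flagged, excluded from macro averages,
  and warned about — never silently zero. Reported percentages round
  half-up to two decimals.

## Known limitations

* The synthetic phenotypes are colour/shape caricatures; no claim is made
  about transfer to field imagery.
* Training is CPU-bound NumPy; it is intended for desk-scale runs and
  correctness work, not for full 100-epoch runs on thousands of images.
* The exported graph fixes the spatial input size recorded at export time.
* Bit-reproducibility holds for a fixed BLAS; different BLAS builds may
  differ in the last float32 ulp (all tests use tolerances wide enough for
  this except the same-process determinism checks).
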