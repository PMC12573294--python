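"""Deterministic synthetic garlic-leaf image generator.

The real survey data behind this package (field photographs of garlic
leaves with botrytis, rust, blight, purple spot, or no disease) is not
publicly available, so every downstream stage — splitting, augmentation,
training, evaluation, export — is exercised on procedurally drawn leaves
instead. Each image is an elongated green blade on a plain or cluttered
background, overlaid with class-specific lesions:

* botrytis — a few large irregular gray-brown patches with soft edges;
* rust — many small round orange pustules;
* blight — brown necrosis advancing from the leaf tip;
* purple — elongated purple-centred spots with a pale halo;
* healthy — no lesions at all.

The five classes occupy disjoint regions of lesion-colour space when
colour jitter is off, so a nearest-centroid classifier on mean lesion
colour separates them perfectly ("separable" preset); raising jitter and
background clutter makes the task progressively harder. Identical specs
(including the seed) give bit-identical images on any platform.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

CLASS_NAMES = ("botrytis", "rust", "blight", "purple", "healthy")

#: difficulty presets: (color_jitter, background)
PRESETS = {
    "separable": (0.0, "plain"),
    "moderate": (0.03, "cluttered"),
    "hard": (0.08, "cluttered"),
}


@dataclass(frozen=True)
class LeafSpec:
    class_label: str
    image_size: int = 96
    lesion_density: float = 1.0
    lesion_scale: float = 1.0
    color_jitter: float = 0.0
    background: str = "plain"
    seed: int = 0

    def __post_init__(self):
        if self.class_label not in CLASS_NAMES:
            raise ValueError(f"unknown class {self.class_label!r}")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32 pixels to contain a leaf")
        if self.background not in ("plain", "cluttered"):
            raise ValueError("background must be 'plain' or 'cluttered'")


# mean lesion colours, chosen pairwise-distant in RGB (leaf green is the
# "lesion colour" of the healthy class for separability purposes)
_LESION_COLOR = {
    "botrytis": np.array([0.50, 0.42, 0.33]),   # gray-brown
    "rust": np.array([0.85, 0.45, 0.08]),       # orange
    "blight": np.array([0.38, 0.24, 0.08]),     # dark brown
    "purple": np.array([0.48, 0.12, 0.45]),     # purple
}
_LEAF_GREEN = np.array([0.20, 0.48, 0.16])
_SOIL = np.array([0.62, 0.55, 0.45])


def _soft_disc(yy, xx, cy, cx, r, softness=0.35):
    d = np.hypot(yy - cy, xx - cx)
    return np.clip((r - d) / (softness * r + 1e-9), 0.0, 1.0)


def generate_leaf(spec: LeafSpec) -> tuple[np.ndarray, str, np.ndarray]:
    """Draw one leaf; returns (HxWx3 float image in [0,1], label, lesion mask).

    The lesion mask is a debug channel: 1 where lesion pigment was
    composited, identically 0 for the healthy class.
    """
    rng = np.random.default_rng([spec.seed, CLASS_NAMES.index(spec.class_label)])
    s = spec.image_size
    yy, xx = np.mgrid[0:s, 0:s] / (s - 1.0)

    # background
    grad = 0.15 * (yy - 0.5)
    img = np.clip(_SOIL[None, None, :] + grad[..., None]
                  + 0.02 * rng.standard_normal((s, s, 3)), 0, 1)
    if spec.background == "cluttered":
        for _ in range(rng.integers(4, 9)):
            c = rng.uniform(0.15, 0.8, size=3)
            alpha = 0.6 * _soft_disc(yy, xx, rng.uniform(0, 1), rng.uniform(0, 1),
                                     rng.uniform(0.08, 0.25), softness=0.8)
            img = img * (1 - alpha[..., None]) + c[None, None, :] * alpha[..., None]

    # blade: a long tapered strip at a random tilt through the image centre
    theta = rng.uniform(-0.45, 0.45)
    cy0, cx0 = 0.5 + rng.uniform(-0.05, 0.05), 0.5 + rng.uniform(-0.05, 0.05)
    u = (yy - cy0) * np.cos(theta) + (xx - cx0) * np.sin(theta)   # along blade
    v = -(yy - cy0) * np.sin(theta) + (xx - cx0) * np.cos(theta)  # across blade
    half_len = 0.46
    wmax = rng.uniform(0.075, 0.11)
    width = wmax * np.clip(1 - (u / half_len) ** 2, 0, None)
    blade = np.clip((width - np.abs(v)) * s * 1.5, 0, 1)  # anti-aliased edge

    leaf_col = _LEAF_GREEN + rng.normal(0, 0.015, size=3)
    leaf = leaf_col[None, None, :] * np.ones((s, s, 3))
    leaf += 0.07 * np.clip(1 - np.abs(v) / (width + 1e-9), 0, 1)[..., None] \
        * np.array([0.3, 1.0, 0.3])[None, None, :] * 0.25   # pale mid-vein
    leaf += 0.015 * rng.standard_normal((s, s, 3))
    img = img * (1 - blade[..., None]) + leaf * blade[..., None]

    # lesions
    alpha = np.zeros((s, s))
    color = np.zeros((s, s, 3))

    def paint(a, col):
        nonlocal alpha, color
        a = a * (blade > 0.5)
        color = np.where((a > alpha)[..., None], col[None, None, :], color)
        alpha = np.maximum(alpha, a)

    label = spec.class_label
    dens, scale = spec.lesion_density, spec.lesion_scale
    if label == "botrytis":
        n = 1 + rng.poisson(2.0 * dens)
        ang = np.arctan2(yy - 0.5, xx - 0.5)
        for _ in range(n):
            cu = rng.uniform(-0.3, 0.3)
            cy = cy0 + cu * np.cos(theta) + rng.normal(0, 0.01)
            cx = cx0 + cu * np.sin(theta) + rng.normal(0, 0.01)
            r0 = 0.07 * scale * rng.uniform(0.7, 1.4)
            wob = 1 + 0.25 * np.sin(ang * rng.integers(3, 6) + rng.uniform(0, 6.28))
            d = np.hypot(yy - cy, xx - cx)
            paint(np.clip((r0 * wob - d) / (0.5 * r0), 0, 1) * 0.9,
                  _LESION_COLOR[label] + rng.normal(0, 0.02, 3))
    elif label == "rust":
        n = 6 + rng.poisson(22.0 * dens)
        for _ in range(n):
            cu, cv = rng.uniform(-0.42, 0.42), rng.uniform(-wmax, wmax)
            cy = cy0 + cu * np.cos(theta) - cv * np.sin(theta)
            cx = cx0 + cu * np.sin(theta) + cv * np.cos(theta)
            r0 = 0.012 * scale * rng.uniform(0.7, 1.5)
            paint(_soft_disc(yy, xx, cy, cx, r0, softness=0.5),
                  _LESION_COLOR[label] + rng.normal(0, 0.03, 3))
    elif label == "blight":
        tip = rng.choice([-1.0, 1.0])
        front = 0.46 - rng.uniform(0.12, 0.30) * scale
        prog = 1.0 / (1.0 + np.exp(-(tip * u - front) / 0.03))
        prog *= 1 + 0.15 * np.sin(v * s * 0.7)  # ragged margin
        paint(np.clip(prog, 0, 1) * 0.95, _LESION_COLOR[label])
    elif label == "purple":
        n = 2 + rng.poisson(5.0 * dens)
        for _ in range(n):
            cu, cv = rng.uniform(-0.38, 0.38), rng.uniform(-0.6, 0.6) * wmax
            du, dv = u - cu, v - cv
            a_len = 0.055 * scale * rng.uniform(0.8, 1.3)   # elongated along blade
            a_wid = 0.016 * scale * rng.uniform(0.8, 1.3)
            d = np.sqrt((du / a_len) ** 2 + (dv / a_wid) ** 2)
            halo = np.clip((1.6 - d) / 0.8, 0, 1) * 0.5
            core = np.clip((1.0 - d) / 0.4, 0, 1)
            paint(halo, _LESION_COLOR[label] * 0.5 + np.array([0.35, 0.3, 0.33]))
            paint(core, _LESION_COLOR[label] + rng.normal(0, 0.02, 3))

    img = img * (1 - alpha[..., None]) + color * alpha[..., None]
    if spec.color_jitter > 0:
        img = img + rng.normal(0, spec.color_jitter, size=3)[None, None, :]
    mask = (alpha > 0.5).astype(np.float32)
    return np.clip(img, 0, 1).astype(np.float32), label, mask


def generate_class_images(label: str, n: int, seed: int,
                          **spec_kwargs) -> list[tuple[np.ndarray, np.ndarray]]:
    """n (image, lesion-mask) pairs for one class, seeds derived from `seed`."""
    out = []
    for i in range(n):
        spec = LeafSpec(class_label=label, seed=seed * 1000 + i, **spec_kwargs)
        img, _, mask = generate_leaf(spec)
        out.append((img, mask))
    return out


def generate_arrays(n_per_class: int, seed: int = 0, image_size: int = 96,
                    difficulty: str = "separable") -> tuple[np.ndarray, np.ndarray]:
    """In-memory dataset: (N, H, W, 3) images and integer labels, class-ordered."""
    jitter, background = PRESETS[difficulty]
    images, labels = [], []
    for ci, label in enumerate(CLASS_NAMES):
        for img, _ in generate_class_images(
                label, n_per_class, seed=seed * 10 + ci,
                image_size=image_size, color_jitter=jitter, background=background):
            images.append(img)
            labels.append(ci)
    return np.stack(images), np.array(labels, dtype=np.int64)


def generate_dataset(out_dir: str | Path, n_per_class: int, seed: int = 0,
                     image_size: int = 96,
                     difficulty: str = "separable") -> Path:
    """Write a class-per-folder PNG tree plus a `manifest.csv` with header
    path,label,split (split left empty until assigned). Returns the
    manifest path."""
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    out_dir = Path(out_dir)
    jitter, background = PRESETS[difficulty]
    rows = []
    for ci, label in enumerate(CLASS_NAMES):
        cls_dir = out_dir / label
        cls_dir.mkdir(parents=True, exist_ok=True)
        pairs = generate_class_images(label, n_per_class, seed=seed * 10 + ci,
                                      image_size=image_size,
                                      color_jitter=jitter, background=background)
        for i, (img, _) in enumerate(pairs):
            rel = Path(label) / f"{label}_{i:05d}.png"
            Image.fromarray((img * 255.0 + 0.5).astype(np.uint8)).save(out_dir / rel)
            rows.append((str(rel), label, ""))
    manifest = out_dir / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "split"])
        writer.writerows(rows)
    return manifest


def easy_spec(label: str, seed: int = 0, image_size: int = 96) -> LeafSpec:
    """Convenience: the 'separable' preset as a LeafSpec."""
    jitter, background = PRESETS["separable"]
    return LeafSpec(class_label=label, image_size=image_size,
                    color_jitter=jitter, background=background, seed=seed)
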