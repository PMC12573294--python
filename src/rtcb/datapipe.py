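"""Dataset manifests, the per-class 3:1:1 stratified split, and the
robustness augmentations (brightness, contrast, additive noise, simulated
polygonal shadows).

The split is performed independently within each class: records are
shuffled with the given seed, integer quotas are the floors of n*r_i/R,
and leftover items go to the splits with the largest fractional remainder,
ties broken toward the *later* split (test before val before train). With
ratios 3:1:1 this reproduces the published per-class train/val/test counts
for four of the five garlic classes; the fifth (purple, 1055/358/358 of
1771) is not a 3:1:1 partition of its total under any rounding rule and is
documented as an inconsistency rather than reproduced.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .synthetic_data import CLASS_NAMES

SPLITS = ("train", "val", "test")


class ManifestError(ValueError):
    pass


@dataclass(frozen=True)
class ManifestRecord:
    path: str
    label: str
    split: str = ""  # "" = unassigned


@dataclass
class DatasetManifest:
    records: list[ManifestRecord] = field(default_factory=list)
    classes: tuple[str, ...] = CLASS_NAMES

    def __post_init__(self):
        seen = set()
        for r in self.records:
            if r.label not in self.classes:
                raise ManifestError(f"unknown label {r.label!r} in manifest")
            if r.split not in ("",) + SPLITS:
                raise ManifestError(f"unknown split {r.split!r} in manifest")
            if r.path in seen:
                raise ManifestError(f"duplicate path {r.path!r} in manifest")
            seen.add(r.path)

    def __len__(self) -> int:
        return len(self.records)

    def by_split(self, split: str) -> list[ManifestRecord]:
        return [r for r in self.records if r.split == split]

    def class_counts(self, split: str | None = None) -> dict[str, int]:
        counts = {c: 0 for c in self.classes}
        for r in self.records:
            if split is None or r.split == split:
                counts[r.label] += 1
        return counts


def read_manifest(path: str | Path,
                  classes: tuple[str, ...] = CLASS_NAMES) -> DatasetManifest:
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["path", "label", "split"]:
            raise ManifestError(f"{path}: expected header path,label,split, "
                                f"got {header}")
        for lineno, row in enumerate(reader, start=2):
            if len(row) != 3:
                raise ManifestError(f"{path}:{lineno}: expected 3 fields, "
                                    f"got {len(row)}")
            p, label, split = row
            if label not in classes:
                raise ManifestError(f"{path}:{lineno}: unknown label {label!r}")
            if split not in ("",) + SPLITS:
                raise ManifestError(f"{path}:{lineno}: unknown split {split!r}")
            records.append(ManifestRecord(p, label, split))
    return DatasetManifest(records, classes)


def write_manifest(manifest: DatasetManifest, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "split"])
        for r in manifest.records:
            writer.writerow([r.path, r.label, r.split])


def largest_remainder_quotas(n: int, ratios: tuple[int, ...]) -> list[int]:
    """Apportion n items to len(ratios) bins by largest fractional
    remainder, ties broken toward the later bin."""
    total = sum(ratios)
    exact = [n * r / total for r in ratios]
    quotas = [int(q) for q in exact]
    leftover = n - sum(quotas)
    order = sorted(range(len(ratios)),
                   key=lambda i: (exact[i] - quotas[i], i), reverse=True)
    for i in order[:leftover]:
        quotas[i] += 1
    return quotas


def stratified_split(manifest: DatasetManifest,
                     ratios: tuple[int, int, int] = (3, 1, 1),
                     seed: int = 0) -> DatasetManifest:
    """Assign train/val/test within each class independently (stratified)."""
    if any(r <= 0 for r in ratios):
        raise ValueError("ratios must be positive")
    if any(r.split for r in manifest.records):
        raise ManifestError("manifest already carries split assignments")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for label in manifest.classes:
        idx = [i for i, r in enumerate(manifest.records) if r.label == label]
        if not idx:
            continue
        if len(idx) < len(ratios):
            raise ManifestError(
                f"class {label!r} has {len(idx)} records, fewer than "
                f"{len(ratios)} splits")
        perm = rng.permutation(len(idx))
        quotas = largest_remainder_quotas(len(idx), ratios)
        cursor = 0
        for split, q in zip(SPLITS, quotas):
            for j in perm[cursor:cursor + q]:
                assignment[manifest.records[idx[j]].path] = split
            cursor += q
    new_records = [replace(r, split=assignment.get(r.path, r.split))
                   for r in manifest.records]
    return DatasetManifest(new_records, manifest.classes)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AugmentConfig:
    """Photometric robustness augmentations; each op fires independently
    with probability `prob`. Factors multiply, noise adds, shadows darken
    inside random convex polygons; results are clamped to [0, 1]."""

    brightness_range: tuple[float, float] = (0.7, 1.3)
    contrast_range: tuple[float, float] = (0.7, 1.3)
    noise_std: float = 0.02
    shadow_max_polygons: int = 2
    shadow_opacity: tuple[float, float] = (0.3, 0.7)
    prob: float = 0.5

    def __post_init__(self):
        for name, (lo, hi) in (("brightness_range", self.brightness_range),
                               ("contrast_range", self.contrast_range),
                               ("shadow_opacity", self.shadow_opacity)):
            if not (0 <= lo <= hi):
                raise ValueError(f"invalid {name}: ({lo}, {hi})")
        if self.noise_std < 0 or not 0 <= self.prob <= 1:
            raise ValueError("noise_std must be >= 0 and prob in [0, 1]")


def _convex_polygon_mask(size: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    h, w = size
    k = int(rng.integers(3, 7))
    pts = np.column_stack([rng.uniform(0, w, k), rng.uniform(0, h, k)])
    centre = pts.mean(axis=0)
    order = np.argsort(np.arctan2(pts[:, 1] - centre[1], pts[:, 0] - centre[0]))
    poly = [tuple(p) for p in pts[order]]
    im = Image.new("L", (w, h), 0)
    ImageDraw.Draw(im).polygon(poly, fill=255)
    return np.asarray(im, dtype=np.float32) / 255.0


def augment(image: np.ndarray, cfg: AugmentConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Apply the configured photometric ops to an HxWx3 image in [0, 1]."""
    img = np.asarray(image, dtype=np.float32)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("augment expects pixel values in [0, 1]")
    out = img.copy()
    if rng.random() < cfg.prob:  # brightness
        out = out * rng.uniform(*cfg.brightness_range)
    if rng.random() < cfg.prob:  # contrast about the image mean
        m = out.mean()
        out = m + (out - m) * rng.uniform(*cfg.contrast_range)
    if rng.random() < cfg.prob and cfg.noise_std > 0:
        out = out + rng.normal(0, cfg.noise_std, size=out.shape)
    if rng.random() < cfg.prob and cfg.shadow_max_polygons > 0:
        n = int(rng.integers(1, cfg.shadow_max_polygons + 1))
        for _ in range(n):
            mask = _convex_polygon_mask(out.shape[:2], rng)
            opacity = rng.uniform(*cfg.shadow_opacity)
            out = out * (1 - opacity * mask[..., None])
    return np.clip(out, 0.0, 1.0).astype(np.float32)


def load_split_arrays(manifest: DatasetManifest, root: str | Path,
                      split: str) -> tuple[np.ndarray, np.ndarray]:
    """Load one split's images as (N, H, W, 3) floats in [0,1] plus integer
    labels in manifest class order."""
    records = manifest.by_split(split)
    if not records:
        raise ManifestError(f"split {split!r} is empty")
    images, labels = [], []
    for r in records:
        with Image.open(Path(root) / r.path) as im:
            images.append(np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0)
        labels.append(manifest.classes.index(r.label))
    return np.stack(images), np.array(labels, dtype=np.int64)
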