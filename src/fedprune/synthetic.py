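"""Synthetic day-age-style image data: generation, rebalancing, splitting.

Real day-age datasets collected in rearing houses are heavily imbalanced —
some ages contribute thousands of images, others a few hundred, and whole
spans of days can be missing entirely.  This module generates labelled RGB
(or grayscale) images with exactly that statistical structure, plus the
standard rebalancing augmentations (geometric, color, multi-sample mixing),
a stratified 7:3 train/test split, and ratio-based client partitioning for
federated experiments.

The visual signal is a bright disc whose radius grows strictly monotonically
with the day-age label (morphology scales with age), with positional jitter
and Gaussian pixel noise, so the classification task is learnable but not
trivial.

``DAY_AGE_COUNTS`` reproduces the per-day image counts of the day-age dataset
this simulator emulates: 78 present classes between day 1 and day 100, counts
from 249 to 3176, and missing days (32-34, 51-67, 76, 91).  Absent classes
are dropped from the label space via contiguous re-indexing (see
:func:`stack`), with the label map retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

__all__ = [
    "ClassSpec",
    "ImageSample",
    "AugmentationConfig",
    "SplitSpec",
    "DAY_AGE_COUNTS",
    "day_age_class_specs",
    "uniform_class_specs",
    "generate_dataset",
    "rebalance",
    "split_train_test",
    "partition_clients",
    "stack",
    "load_image_directory",
]

GEOMETRIC_OPS = ("flip", "rotate", "crop", "deform", "scale")
COLOR_OPS = ("noise", "blur", "color_shift", "erase", "fill")
MULTI_SAMPLE_MODES = ("none", "sample_pairing", "smote_like")

#: Per-day image counts of the emulated day-age dataset; missing days omitted.
DAY_AGE_COUNTS: Dict[int, int] = {
    1: 286, 2: 268, 3: 249, 4: 273, 5: 251, 6: 275, 7: 269, 8: 263,
    9: 278, 10: 266, 11: 266, 12: 250, 13: 260, 14: 3176, 15: 3164,
    16: 3150, 17: 3171, 18: 3140, 19: 3133, 20: 3140, 21: 3120, 22: 3117,
    23: 3080, 24: 3050, 25: 3070, 26: 3066, 27: 3052, 28: 3040, 29: 3050,
    30: 3024, 31: 2928, 35: 2916, 36: 2903, 37: 2933, 38: 2929, 39: 2932,
    40: 2921, 41: 2922, 42: 2966, 43: 2928, 44: 2923, 45: 2961, 46: 2926,
    47: 2925, 48: 2913, 49: 2922, 50: 3020, 68: 765, 69: 741, 70: 630,
    71: 622, 72: 619, 73: 646, 74: 629, 75: 628, 77: 612, 78: 648,
    79: 723, 80: 612, 81: 635, 82: 648, 83: 644, 84: 639, 85: 644,
    86: 648, 87: 647, 88: 675, 89: 633, 90: 649, 92: 648, 93: 647,
    94: 638, 95: 622, 96: 652, 97: 653, 98: 650, 99: 641, 100: 652,
}


@dataclass(frozen=True)
class ClassSpec:
    """One day-age class: label in [1, 100], image count, presence flag."""

    label: int
    count: int
    present: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.label <= 100:
            raise ValueError("label must be a day-age in [1, 100]")
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.present != (self.count > 0):
            raise ValueError("present flag must equal (count > 0)")


@dataclass
class ImageSample:
    """An H×W×C image with values in [0, 1] and its integer day-age label."""

    pixels: np.ndarray
    label: int

    def __post_init__(self) -> None:
        p = self.pixels
        if p.ndim != 3 or p.shape[0] < 8 or p.shape[1] < 8 or p.shape[2] not in (1, 3):
            raise ValueError("pixels must be H×W×C with H,W >= 8 and C in {1,3}")
        if not np.all(np.isfinite(p)) or p.min() < 0 or p.max() > 1:
            raise ValueError("pixel values must be finite and in [0, 1]")


@dataclass
class AugmentationConfig:
    """Which augmentation families rebalancing may draw from."""

    geometric: frozenset = frozenset({"flip", "rotate"})
    color: frozenset = frozenset({"noise"})
    multi_sample: str = "none"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.geometric = frozenset(self.geometric)
        self.color = frozenset(self.color)
        if not self.geometric <= set(GEOMETRIC_OPS):
            raise ValueError(f"unknown geometric ops {self.geometric - set(GEOMETRIC_OPS)}")
        if not self.color <= set(COLOR_OPS):
            raise ValueError(f"unknown color ops {self.color - set(COLOR_OPS)}")
        if self.multi_sample not in MULTI_SAMPLE_MODES:
            raise ValueError(f"unknown multi_sample mode {self.multi_sample!r}")
        if not (self.geometric or self.color or self.multi_sample != "none"):
            raise ValueError("at least one augmentation family must be enabled")


@dataclass
class SplitSpec:
    """Stratified split fractions and per-client allocation ratios."""

    train_fraction: float = 0.7
    client_ratios: Sequence[float] = (1.0,)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if len(self.client_ratios) == 0 or min(self.client_ratios) <= 0:
            raise ValueError("client_ratios must be positive")


def day_age_class_specs(scale: float = 1.0) -> List[ClassSpec]:
    """The emulated dataset's class distribution, optionally scaled down.

    ``scale`` multiplies every per-day count (minimum 1 image per present
    day) so desk-scale runs can keep the imbalance shape without the volume.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    specs = []
    for day in range(1, 101):
        count = DAY_AGE_COUNTS.get(day, 0)
        count = max(1, int(round(count * scale))) if count else 0
        specs.append(ClassSpec(label=day, count=count, present=count > 0))
    return specs


def uniform_class_specs(n_classes: int = 10, count: int = 200) -> List[ClassSpec]:
    """Evenly spaced, equally sized day-age classes (the benchmark setting)."""
    labels = np.linspace(10, 100, n_classes).round().astype(int)
    return [ClassSpec(label=int(l), count=count) for l in labels]


def _disc_image(rng: np.random.Generator, label: int, h: int, w: int, c: int,
                noise_sigma: float) -> np.ndarray:
    """A noisy bright disc whose radius is strictly monotone in the label."""
    r_min, r_max = 2.0, 0.38 * min(h, w)
    radius = r_min + (r_max - r_min) * label / 100.0
    jitter = min(2.0, 0.06 * min(h, w))
    cy = h / 2.0 + rng.uniform(-jitter, jitter)
    cx = w / 2.0 + rng.uniform(-jitter, jitter)
    yy, xx = np.mgrid[0:h, 0:w]
    disc = ((yy - cy) ** 2 + (xx - cx) ** 2) <= radius ** 2
    img = np.full((h, w), 0.15)
    img[disc] = 0.85
    img = img[:, :, None] + rng.normal(0.0, noise_sigma, size=(h, w, c))
    return np.clip(img, 0.0, 1.0)


def generate_dataset(
    class_specs: Sequence[ClassSpec],
    image_size: Tuple[int, int, int] = (32, 32, 3),
    rng_seed: int = 0,
    noise_sigma: float = 0.1,
) -> List[ImageSample]:
    """Generate exactly ``count`` images per present class, deterministically.

    Identical ``(class_specs, image_size, rng_seed)`` give bit-identical
    pixels.  Raises if every class is absent.
    """
    if not class_specs:
        raise ValueError("empty dataset spec")
    labels = [cs.label for cs in class_specs]
    if len(set(labels)) != len(labels):
        raise ValueError("class labels must be unique")
    present = [cs for cs in class_specs if cs.present]
    if not present:
        raise ValueError("empty dataset spec: all classes absent")
    h, w, c = image_size
    samples: List[ImageSample] = []
    for cs in sorted(present, key=lambda s: s.label):
        rng = np.random.default_rng(np.random.SeedSequence((rng_seed, cs.label)))
        for _ in range(cs.count):
            samples.append(ImageSample(_disc_image(rng, cs.label, h, w, c, noise_sigma), cs.label))
    return samples


# --------------------------------------------------------------- augmentation


def _augment_geometric(img: np.ndarray, op: str, rng: np.random.Generator) -> np.ndarray:
    if op == "flip":
        axis = int(rng.integers(0, 2))
        return np.flip(img, axis=axis).copy()
    if op == "rotate":
        angle = float(rng.uniform(-25.0, 25.0))
        out = ndimage.rotate(img, angle, axes=(0, 1), reshape=False, order=1,
                             mode="nearest")
        return np.clip(out, 0.0, 1.0)
    if op == "crop":
        h, w, _ = img.shape
        m = max(1, h // 8)
        top, left = int(rng.integers(0, m + 1)), int(rng.integers(0, m + 1))
        cropped = img[top : h - (m - top), left : w - (m - left), :]
        zoom = (h / cropped.shape[0], w / cropped.shape[1], 1.0)
        out = ndimage.zoom(cropped, zoom, order=1)
        return np.clip(out[:h, :w, :], 0.0, 1.0)
    if op == "deform":
        shift = (float(rng.uniform(-2, 2)), float(rng.uniform(-2, 2)), 0.0)
        return np.clip(ndimage.shift(img, shift, order=1, mode="nearest"), 0.0, 1.0)
    if op == "scale":
        factor = float(rng.uniform(0.85, 1.15))
        h, w, _ = img.shape
        out = ndimage.zoom(img, (factor, factor, 1.0), order=1)
        if factor >= 1.0:
            oh = (out.shape[0] - h) // 2
            ow = (out.shape[1] - w) // 2
            out = out[oh : oh + h, ow : ow + w, :]
        else:
            pad_h, pad_w = h - out.shape[0], w - out.shape[1]
            out = np.pad(out, ((pad_h // 2, pad_h - pad_h // 2),
                               (pad_w // 2, pad_w - pad_w // 2), (0, 0)),
                         mode="edge")
        return np.clip(out[:h, :w, :], 0.0, 1.0)
    raise ValueError(op)


def _augment_color(img: np.ndarray, op: str, rng: np.random.Generator) -> np.ndarray:
    if op == "noise":
        return np.clip(img + rng.normal(0, 0.03, img.shape), 0.0, 1.0)
    if op == "blur":
        return np.clip(ndimage.gaussian_filter(img, sigma=(0.8, 0.8, 0.0)), 0.0, 1.0)
    if op == "color_shift":
        shift = rng.uniform(-0.08, 0.08, size=(1, 1, img.shape[2]))
        return np.clip(img + shift, 0.0, 1.0)
    if op == "erase":
        h, w, _ = img.shape
        eh, ew = max(1, h // 6), max(1, w // 6)
        top = int(rng.integers(0, h - eh + 1))
        left = int(rng.integers(0, w - ew + 1))
        out = img.copy()
        out[top : top + eh, left : left + ew, :] = 0.0
        return out
    if op == "fill":
        h, w, _ = img.shape
        eh, ew = max(1, h // 6), max(1, w // 6)
        top = int(rng.integers(0, h - eh + 1))
        left = int(rng.integers(0, w - ew + 1))
        out = img.copy()
        out[top : top + eh, left : left + ew, :] = float(rng.uniform(0, 1))
        return out
    raise ValueError(op)


def _mix(a: np.ndarray, b: np.ndarray, mode: str, rng: np.random.Generator) -> np.ndarray:
    if mode == "sample_pairing":
        return (a + b) / 2.0  # pixelwise average of the two parent images
    lam = float(rng.uniform(0.2, 0.8))  # smote_like: convex combination
    return lam * a + (1.0 - lam) * b


def rebalance(
    samples: Sequence[ImageSample],
    target_count: int,
    config: AugmentationConfig,
) -> List[ImageSample]:
    """Augment every class up to exactly ``target_count`` samples.

    Originals are retained unmodified; synthesized samples are single-image
    geometric/color augmentations or two-sample mixes of originals from the
    same class.  A class with a single sample cannot be mixed: multi-sample
    requests fall back to single-sample augmentation with a warning.
    """
    by_class: Dict[int, List[ImageSample]] = {}
    for s in samples:
        by_class.setdefault(s.label, []).append(s)
    for label, group in by_class.items():
        if not group:
            raise ValueError(f"cannot augment empty class {label}")
    if target_count < max(len(g) for g in by_class.values()):
        raise ValueError("target_count must be >= the largest class count")
    rng = np.random.default_rng(config.rng_seed)
    out: List[ImageSample] = list(samples)
    single_ops = [("geo", op) for op in sorted(config.geometric)]
    single_ops += [("col", op) for op in sorted(config.color)]
    for label in sorted(by_class):
        group = by_class[label]
        deficit = target_count - len(group)
        for _ in range(deficit):
            use_mix = config.multi_sample != "none"
            if use_mix and len(group) < 2:
                warnings.warn(
                    f"class {label} has a single sample; falling back to "
                    "single-sample augmentation", stacklevel=2)
                use_mix = False
            if use_mix and (not single_ops or rng.random() < 0.5):
                i, j = rng.choice(len(group), size=2, replace=False)
                pix = _mix(group[i].pixels, group[j].pixels, config.multi_sample, rng)
            else:
                if not single_ops:
                    raise ValueError("no single-sample augmentation enabled")
                kind, op = single_ops[int(rng.integers(0, len(single_ops)))]
                src = group[int(rng.integers(0, len(group)))].pixels
                pix = (_augment_geometric if kind == "geo" else _augment_color)(src, op, rng)
            out.append(ImageSample(pix, label))
    return out


# ---------------------------------------------------------------- partitioning


def split_train_test(
    samples: Sequence[ImageSample],
    split: SplitSpec,
) -> Tuple[List[ImageSample], List[ImageSample]]:
    """Per-class stratified split; the flooring remainder goes to train."""
    by_class: Dict[int, List[int]] = {}
    for i, s in enumerate(samples):
        by_class.setdefault(s.label, []).append(i)
    for label, idxs in by_class.items():
        if len(idxs) < 2:
            raise ValueError(f"stratified split impossible: class {label} has 1 sample")
    rng = np.random.default_rng(split.rng_seed)
    train_idx: List[int] = []
    test_idx: List[int] = []
    for label in sorted(by_class):
        idxs = np.array(by_class[label])
        rng.shuffle(idxs)
        n_test = int(np.floor((1.0 - split.train_fraction) * len(idxs)))
        test_idx.extend(idxs[:n_test])
        train_idx.extend(idxs[n_test:])
    return [samples[i] for i in sorted(train_idx)], [samples[i] for i in sorted(test_idx)]


def partition_clients(
    train: Sequence[ImageSample],
    split: SplitSpec,
) -> List[List[ImageSample]]:
    """Disjointly cover the training set across clients, per class, by ratio.

    Client k receives a ``ratio_k / Σ ratios`` share of every class; the
    flooring remainders are assigned randomly (seeded) with probability
    proportional to each client's fractional entitlement.
    """
    ratios = np.asarray(split.client_ratios, dtype=float)
    n_clients = len(ratios)
    if n_clients > len(train):
        raise ValueError("more clients than training samples")
    shares = ratios / ratios.sum()
    rng = np.random.default_rng(np.random.SeedSequence((split.rng_seed, 1)))
    by_class: Dict[int, List[int]] = {}
    for i, s in enumerate(train):
        by_class.setdefault(s.label, []).append(i)
    parts: List[List[int]] = [[] for _ in range(n_clients)]
    for label in sorted(by_class):
        idxs = np.array(by_class[label])
        rng.shuffle(idxs)
        exact = shares * len(idxs)
        base = np.floor(exact).astype(int)
        rem = len(idxs) - base.sum()
        if rem:
            frac = exact - base
            p = frac / frac.sum() if frac.sum() > 0 else np.full(n_clients, 1.0 / n_clients)
            extra = rng.choice(n_clients, size=rem, replace=False, p=p) if rem <= n_clients \
                else rng.choice(n_clients, size=rem, replace=True, p=p)
            for k in extra:
                base[k] += 1
        pos = 0
        for k in range(n_clients):
            parts[k].extend(idxs[pos : pos + base[k]])
            pos += base[k]
    return [[train[i] for i in sorted(part)] for part in parts]


def load_image_directory(path) -> List[ImageSample]:
    """Load a ``class_<label>/img_<k>.png`` directory tree (8-bit PNGs).

    The inverse of the CLI's dataset export; also accepts real images laid
    out in the same directory-of-class-folders structure.
    """
    from pathlib import Path

    from PIL import Image

    root = Path(path)
    samples: List[ImageSample] = []
    for cls_dir in sorted(root.glob("class_*")):
        label = int(cls_dir.name.split("_", 1)[1])
        for img_path in sorted(cls_dir.glob("*.png")):
            arr = np.asarray(Image.open(img_path), dtype=np.float64) / 255.0
            if arr.ndim == 2:
                arr = arr[:, :, None]
            samples.append(ImageSample(arr, label))
    if not samples:
        raise ValueError(f"no class_*/ PNG images found under {root}")
    return samples


def stack(
    samples: Sequence[ImageSample],
    label_map: Optional[Dict[int, int]] = None,
) -> Tuple[np.ndarray, np.ndarray, Dict[int, int]]:
    """Samples → (X, y, label_map) with contiguous class indices.

    Absent day-ages simply never appear; the returned map records
    ``original day-age label -> contiguous class index``.  Pass the map of a
    reference set (e.g. the full training set) when stacking a subset, so a
    client shard that happens to miss a class keeps consistent indices.
    """
    if label_map is None:
        labels = sorted({s.label for s in samples})
        label_map = {lab: i for i, lab in enumerate(labels)}
    X = np.stack([s.pixels for s in samples]).astype(np.float64)
    y = np.array([label_map[s.label] for s in samples], dtype=int)
    return X, y, label_map
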