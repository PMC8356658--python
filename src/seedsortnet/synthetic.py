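"""Deterministic two-class synthetic seed images.

Emulates the structure of an industrial line-scan seed-sorting dataset:
100×100-pixel RGB images of single objects on a dark background.  The
"normal" class (label 1) is one centered, textured ellipse in seed-like hues
(randomized axis ratio, orientation, stripe texture).  The "abnormal" class
(label 0) is one of three defect archetypes with matched brightness
statistics: several smaller objects in one frame, an irregular polygon
(stone/leaf analog), or a broken ellipse.  Additive Gaussian pixel noise is
applied last and the result is clipped to [0, 1].

Everything is a pure function of :class:`SyntheticSpec` (including its seed),
so the same spec always produces byte-identical data.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

__all__ = [
    "SyntheticSpec",
    "LabeledImageSet",
    "generate_dataset",
    "augment_x4",
    "train_test_split",
    "save_dataset",
    "load_dataset",
    "to_input_batch",
]


@dataclass(frozen=True)
class SyntheticSpec:
    n_per_class: int = 100
    image_size: int = 100
    noise_sd: float = 0.02
    clutter_rate: float = 1.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_per_class < 1:
            raise ValueError("n_per_class must be >= 1")
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not 0.0 <= self.clutter_rate <= 1.0:
            raise ValueError("clutter_rate must be in [0, 1]")


@dataclass
class LabeledImageSet:
    images: np.ndarray          # (N, H, W, 3) float32 in [0, 1]
    labels: np.ndarray          # (N,) int, normal=1 / abnormal=0
    provenance: SyntheticSpec | None = None

    def __post_init__(self):
        if len(self.images) != len(self.labels):
            raise ValueError("images and labels must have equal length")

    def __len__(self) -> int:
        return len(self.labels)


def _ellipse_mask(size: int, cx: float, cy: float, a: float, b: float,
                  theta: float) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    x = xx - cx
    y = yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (x * ct + y * st) / a
    v = (-x * st + y * ct) / b
    return u * u + v * v <= 1.0


def _seed_color(rng: np.random.Generator) -> np.ndarray:
    # seed-like tones: tan through brown
    h = rng.uniform(0.55, 0.95)
    base = np.array([0.75, 0.55, 0.30]) * h
    return base + rng.uniform(-0.05, 0.05, size=3)


def _paint(canvas: np.ndarray, mask: np.ndarray, color: np.ndarray,
           rng: np.random.Generator, stripes: bool, theta: float) -> None:
    size = canvas.shape[0]
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    shade = np.ones((size, size))
    if stripes:
        freq = rng.uniform(0.25, 0.7)
        phase = rng.uniform(0, 2 * np.pi)
        axis = xx * np.cos(theta) + yy * np.sin(theta)
        shade += 0.25 * np.sin(freq * axis + phase)
    tex = shade[..., None] * color[None, None, :]
    canvas[mask] = tex[mask]


def _normal_image(size: int, rng: np.random.Generator) -> np.ndarray:
    img = np.full((size, size, 3), 0.06, dtype=np.float64)
    cx = size / 2 + rng.uniform(-0.04, 0.04) * size
    cy = size / 2 + rng.uniform(-0.04, 0.04) * size
    a = rng.uniform(0.26, 0.36) * size
    b = a * rng.uniform(0.45, 0.75)
    theta = rng.uniform(0, np.pi)
    mask = _ellipse_mask(size, cx, cy, a, b, theta)
    _paint(img, mask, _seed_color(rng), rng, stripes=True, theta=theta)
    return img


def _scatter_objects(img, size, rng, n_obj, radius_range=(0.07, 0.13)):
    """Place n_obj non-overlapping ellipses (rejection sampling on centers)."""
    placed = []
    for _ in range(n_obj):
        for _attempt in range(40):
            cx = rng.uniform(0.15, 0.85) * size
            cy = rng.uniform(0.15, 0.85) * size
            a = rng.uniform(*radius_range) * size
            if all(np.hypot(cx - px, cy - py) > a + pa + 0.04 * size
                   for px, py, pa in placed):
                break
        placed.append((cx, cy, a))
        b = a * rng.uniform(0.5, 0.9)
        theta = rng.uniform(0, np.pi)
        mask = _ellipse_mask(size, cx, cy, a, b, theta)
        _paint(img, mask, _seed_color(rng), rng,
               stripes=bool(rng.random() < 0.5), theta=theta)


def _abnormal_image(size: int, rng: np.random.Generator,
                    clutter_rate: float) -> np.ndarray:
    img = np.full((size, size, 3), 0.06, dtype=np.float64)
    kind = rng.integers(0, 3) if rng.random() < clutter_rate else 0
    if kind == 0:                      # several seeds in one frame
        _scatter_objects(img, size, rng, int(rng.integers(2, 5)))
    elif kind == 1:                    # irregular polygon (stone / leaf analog)
        n_v = int(rng.integers(5, 9))
        ang = np.sort(rng.uniform(0, 2 * np.pi, size=n_v))
        rad = rng.uniform(0.15, 0.38, size=n_v) * size
        cx = size / 2 + rng.uniform(-0.08, 0.08) * size
        cy = size / 2 + rng.uniform(-0.08, 0.08) * size
        vx = cx + rad * np.cos(ang)
        vy = cy + rad * np.sin(ang)
        yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
        mask = np.zeros((size, size), dtype=bool)
        inside = np.zeros((size, size), dtype=bool)
        j = n_v - 1
        for i in range(n_v):
            cond = ((vy[i] > yy) != (vy[j] > yy)) & (
                xx < (vx[j] - vx[i]) * (yy - vy[i]) / (vy[j] - vy[i] + 1e-12) + vx[i])
            inside ^= cond
            j = i
        mask |= inside
        _paint(img, mask, _seed_color(rng) * rng.uniform(0.7, 1.1), rng,
               stripes=False, theta=0.0)
        _scatter_debris(img, size, rng, mask)
    else:                              # broken ellipse
        cx = size / 2 + rng.uniform(-0.05, 0.05) * size
        cy = size / 2 + rng.uniform(-0.05, 0.05) * size
        a = rng.uniform(0.26, 0.36) * size
        b = a * rng.uniform(0.45, 0.75)
        theta = rng.uniform(0, np.pi)
        mask = _ellipse_mask(size, cx, cy, a, b, theta)
        # crack: remove a band through the middle
        yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
        crack_theta = theta + rng.uniform(-0.5, 0.5) + np.pi / 2
        d = (xx - cx) * np.cos(crack_theta) + (yy - cy) * np.sin(crack_theta)
        width = rng.uniform(0.05, 0.09) * size
        mask &= np.abs(d) > width
        _paint(img, mask, _seed_color(rng), rng, stripes=True, theta=theta)
        _scatter_debris(img, size, rng, mask)
    return img


def _scatter_debris(img, size, rng, occupied) -> None:
    """Add 1-2 small impurity fragments clear of the main object."""
    n = int(rng.integers(1, 3))
    for _ in range(n):
        for _attempt in range(40):
            cx = rng.uniform(0.08, 0.92) * size
            cy = rng.uniform(0.08, 0.92) * size
            a = rng.uniform(0.035, 0.06) * size
            m = _ellipse_mask(size, cx, cy, a, a * rng.uniform(0.6, 1.0),
                              rng.uniform(0, np.pi))
            grown = _ellipse_mask(size, cx, cy, a + 0.05 * size,
                                  a + 0.05 * size, 0.0)
            if not (grown & occupied).any():
                _paint(img, m, _seed_color(rng) * rng.uniform(0.6, 1.0), rng,
                       stripes=False, theta=0.0)
                occupied = occupied | m
                break


def generate_dataset(spec: SyntheticSpec) -> LabeledImageSet:
    """Balanced two-class image set, fully determined by the spec."""
    rng = np.random.default_rng(spec.rng_seed)
    images = np.empty((2 * spec.n_per_class, spec.image_size, spec.image_size, 3),
                      dtype=np.float32)
    labels = np.empty(2 * spec.n_per_class, dtype=np.int64)
    for i in range(spec.n_per_class):
        images[2 * i] = _normal_image(spec.image_size, rng)
        labels[2 * i] = 1
        images[2 * i + 1] = _abnormal_image(spec.image_size, rng, spec.clutter_rate)
        labels[2 * i + 1] = 0
    if spec.noise_sd > 0:
        images += rng.normal(0.0, spec.noise_sd, size=images.shape).astype(np.float32)
    np.clip(images, 0.0, 1.0, out=images)
    return LabeledImageSet(images, labels, provenance=spec)


def augment_x4(dataset: LabeledImageSet) -> LabeledImageSet:
    """Original + horizontal flip + vertical flip + 90° rotation (labels copied)."""
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    x = dataset.images
    images = np.concatenate([
        x,
        x[:, :, ::-1],          # horizontal flip
        x[:, ::-1, :],          # vertical flip
        np.rot90(x, k=1, axes=(1, 2)),
    ])
    labels = np.tile(dataset.labels, 4)
    return LabeledImageSet(np.ascontiguousarray(images), labels,
                           provenance=dataset.provenance)


def _split_indices(labels: np.ndarray, train_fraction: float, seed: int):
    """Stratified allocation hitting round(fraction*N) overall.

    Per-class counts use the largest-remainder method so class balance is
    within one sample of proportional while the total is exact.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    classes = np.unique(labels)
    sizes = {c: int(np.sum(labels == c)) for c in classes}
    if min(sizes.values()) < 2:
        raise ValueError("every class needs at least 2 samples to split")
    total_train = int(round(train_fraction * len(labels)))
    shares = {c: train_fraction * n for c, n in sizes.items()}
    counts = {c: int(np.floor(s)) for c, s in shares.items()}
    remainder = total_train - sum(counts.values())
    for c in sorted(classes, key=lambda c: shares[c] - np.floor(shares[c]),
                    reverse=True)[:remainder]:
        counts[c] += 1
    train_idx, test_idx = [], []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        n_train = min(max(counts[c], 1), idx.size - 1)
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    return (np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx)))


def train_test_split(dataset: LabeledImageSet, train_fraction: float = 0.75,
                     seed: int = 0) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Stratified random split; partitions are disjoint and exhaustive."""
    tr, te = _split_indices(dataset.labels, train_fraction, seed)
    return (LabeledImageSet(dataset.images[tr], dataset.labels[tr], dataset.provenance),
            LabeledImageSet(dataset.images[te], dataset.labels[te], dataset.provenance))


def to_input_batch(dataset: LabeledImageSet, input_size: int | None = None) -> np.ndarray:
    """(N, H, W, 3) in [0,1] float32, resized/center-cropped to input_size."""
    x = dataset.images
    if input_size and input_size != x.shape[1]:
        resized = np.empty((len(x), input_size, input_size, 3), dtype=np.float32)
        for i, img in enumerate(x):
            pil = Image.fromarray((img * 255).astype(np.uint8))
            short = min(pil.size)
            scale = input_size / short
            pil = pil.resize((round(pil.width * scale), round(pil.height * scale)),
                             Image.BILINEAR)
            left = (pil.width - input_size) // 2
            top = (pil.height - input_size) // 2
            pil = pil.crop((left, top, left + input_size, top + input_size))
            resized[i] = np.asarray(pil, dtype=np.float32) / 255.0
        x = resized
    return np.ascontiguousarray(x, dtype=np.float32)


def save_dataset(dataset: LabeledImageSet, directory, train_fraction: float | None = None,
                 seed: int = 0) -> Path:
    """Write PNGs in ``class_0/`` / ``class_1/`` plus a CSV manifest."""
    directory = Path(directory)
    for label in (0, 1):
        (directory / f"class_{label}").mkdir(parents=True, exist_ok=True)
    split = np.array([""] * len(dataset), dtype=object)
    if train_fraction is not None:
        tr_idx, _ = _split_indices(dataset.labels, train_fraction, seed)
        split[:] = "test"
        split[tr_idx] = "train"
    manifest = directory / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "split"])
        for i, (img, label) in enumerate(zip(dataset.images, dataset.labels)):
            rel = f"class_{label}/img_{i:05d}.png"
            Image.fromarray((img * 255).astype(np.uint8)).save(directory / rel)
            writer.writerow([rel, int(label), split[i]])
    return manifest


def load_dataset(directory) -> LabeledImageSet:
    """Read a ``class_0/`` / ``class_1/`` directory (manifest optional)."""
    directory = Path(directory)
    manifest = directory / "manifest.csv"
    paths, labels = [], []
    if manifest.exists():
        with open(manifest) as fh:
            for row in csv.DictReader(fh):
                paths.append(directory / row["path"])
                labels.append(int(row["label"]))
    else:
        for label in (0, 1):
            for p in sorted((directory / f"class_{label}").glob("*.png")):
                paths.append(p)
                labels.append(label)
    if not paths:
        raise FileNotFoundError(f"no images found under {directory}")
    images = np.stack([np.asarray(Image.open(p).convert("RGB"), dtype=np.float32) / 255.0
                       for p in paths])
    return LabeledImageSet(images, np.asarray(labels, dtype=np.int64))
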