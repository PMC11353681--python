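"""Breast-ultrasound data handling: MedMNIST-style archive loading,
preprocessing (binarize, downsample, normalize, balance), and a
synthetic speckled-ultrasound generator so everything runs offline.

Label convention throughout: 1 = positive (normal/benign), 0 = negative
(malignant).  In three-class archives, class index 0 is taken to be
malignant and every other class maps to the positive label; two-class
archives are assumed to already follow the 0 = malignant convention.

The synthetic generator emulates the gross statistics of low-resolution
breast ultrasound: a mid-gray background under multiplicative speckle
(exponential intensity, i.e. squared-Rayleigh amplitude statistics),
with a darker (hypoechoic) lesion in the middle of the field.  Benign
lesions are smooth ellipses with a blurred margin; malignant lesions are
star-convex polygons with angular spicules
``r(phi) = r0 * (1 + irregularity * sin(k*phi + phi0))``, a sharper
margin, a slightly darker core and a mild posterior acoustic shadow —
classic sonographic malignancy features.  It is a phantom, not a
simulator: no anatomy, no depth-dependent attenuation, no probe
artifacts beyond the shadow.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "LabeledImageSet",
    "SynthConfig",
    "load_medmnist_archive",
    "downsample_2x",
    "normalize",
    "balanced_subset",
    "generate_synthetic",
    "split_sizes",
    "lesion_features",
    "write_image_dir",
    "read_image_dir",
]


@dataclass
class LabeledImageSet:
    """N grayscale images in [0,1] with binary labels (1 = normal/benign)."""

    images: np.ndarray
    labels: np.ndarray
    split_name: str = "train"

    def __post_init__(self):
        imgs = np.asarray(self.images, dtype=float)
        labs = np.asarray(self.labels, dtype=int).ravel()
        if imgs.ndim != 3:
            raise ValueError("images must be N x H x W")
        if len(imgs) != len(labs):
            raise ValueError("images and labels length mismatch")
        if imgs.size and (imgs.min() < 0.0 or imgs.max() > 1.0):
            raise ValueError("image values must lie in [0, 1]")
        if labs.size and not set(np.unique(labs)) <= {0, 1}:
            raise ValueError("labels must be binary")
        self.images, self.labels = imgs, labs

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class SynthConfig:
    """Generator settings; defaults mirror the BreastMNIST regime
    (28x28 frames, ~73% positive prevalence)."""

    n_images: int = 780
    class_balance: float = 0.73  # fraction of positive (normal/benign)
    image_size: int = 28
    speckle_scale: float = 0.35
    irregularity: float = 0.4  # spicule amplitude for malignant lesions
    seed: int = 0

    def __post_init__(self):
        if self.n_images <= 0 or self.image_size <= 0:
            raise ValueError("sizes must be positive")
        if not (0.0 < self.class_balance < 1.0):
            raise ValueError("class balance must lie in (0, 1)")


def split_sizes(n_total: int, ratio=(7, 1, 2)) -> tuple[int, int, int]:
    """Train/val/test sizes for an n_total-image archive at the given ratio.

    780 images at 7:1:2 gives (546, 78, 156).
    """
    total = sum(ratio)
    train = n_total * ratio[0] // total
    val = n_total * ratio[1] // total
    return train, val, n_total - train - val


def load_medmnist_archive(path) -> tuple[LabeledImageSet, LabeledImageSet, LabeledImageSet]:
    """Load a MedMNIST-layout .npz (train/val/test images + labels).

    uint8 images are scaled to [0,1]; labels are binarized with class 0
    (malignant) negative and everything else positive.  Split sizes are
    preserved exactly as shipped.
    """
    with np.load(path, allow_pickle=False) as data:
        required = ["train_images", "train_labels", "val_images",
                    "val_labels", "test_images", "test_labels"]
        missing = [k for k in required if k not in data.files]
        if missing:
            raise ValueError(f"archive missing arrays: {missing}")
        out = []
        for split in ("train", "val", "test"):
            imgs = np.asarray(data[f"{split}_images"])
            labs = np.asarray(data[f"{split}_labels"]).ravel()
            if imgs.ndim == 4:
                if imgs.shape[-1] != 1:
                    raise ValueError("only grayscale archives are supported")
                imgs = imgs[..., 0]
            if imgs.ndim != 3:
                raise ValueError("images must be N x H x W")
            if imgs.dtype == np.uint8:
                imgs = imgs.astype(float) / 255.0
            else:
                imgs = imgs.astype(float)
            binary = (labs != 0).astype(int)
            out.append(LabeledImageSet(imgs, binary, split))
    return tuple(out)


def downsample_2x(image: np.ndarray) -> np.ndarray:
    """Non-overlapping 2x2 mean pooling (28x28 -> 14x14)."""
    image = np.asarray(image, dtype=float)
    h, w = image.shape[-2:]
    if h % 2 or w % 2:
        raise ValueError(f"dimensions must be even, got {h}x{w}")
    shape = image.shape[:-2] + (h // 2, 2, w // 2, 2)
    return image.reshape(shape).mean(axis=(-3, -1))


def normalize(images: np.ndarray) -> np.ndarray:
    """Global min-max rescale to [0,1]; a constant stack maps to 0."""
    images = np.asarray(images, dtype=float)
    if images.size == 0:
        raise ValueError("empty input")
    lo, hi = images.min(), images.max()
    if hi == lo:
        return np.zeros_like(images)
    return (images - lo) / (hi - lo)


def balanced_subset(dataset: LabeledImageSet, seed: int) -> LabeledImageSet:
    """All minority-class items plus an equal-count seeded sample of the
    majority class, order shuffled by the seed."""
    labels = dataset.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    minority = classes[np.argmin(counts)]
    n_min = counts.min()
    keep = list(np.flatnonzero(labels == minority))
    majority_idx = np.flatnonzero(labels != minority)
    keep += list(rng.choice(majority_idx, size=n_min, replace=False))
    keep = np.array(keep)
    rng.shuffle(keep)
    return LabeledImageSet(dataset.images[keep], dataset.labels[keep],
                           dataset.split_name)


# ---------------------------------------------------------------------------
# Synthetic phantom generator.


def _lesion_mask(size, rng, r0, aspect, angle, irregularity):
    """Boolean mask of a (possibly spiculated) star-convex lesion."""
    cy, cx = size / 2 + rng.uniform(-2, 2), size / 2 + rng.uniform(-2, 2)
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = ca * dx + sa * dy
    v = (-sa * dx + ca * dy) / aspect
    radius = np.hypot(u, v)
    phi = np.arctan2(v, u)
    if irregularity > 0:
        k = int(rng.integers(5, 10))
        phi0 = rng.uniform(0, 2 * np.pi)
        boundary = r0 * (1.0 + irregularity * np.sin(k * phi + phi0))
    else:
        boundary = np.full_like(phi, r0)
    return radius <= boundary, (cy, cx)


def _one_image(rng, cfg: SynthConfig, label: int) -> np.ndarray:
    size = cfg.image_size
    # multiplicative speckle: exponential intensity, lightly smoothed
    speckle = rng.exponential(1.0, (size, size))
    speckle = ndimage.gaussian_filter(speckle, 0.6)
    speckle = 1.0 + cfg.speckle_scale * (speckle / speckle.mean() - 1.0)
    background = 0.55
    r0 = rng.uniform(0.18, 0.30) * size
    aspect = rng.uniform(0.6, 1.0)
    angle = rng.uniform(0, np.pi)
    if label == 1:  # benign: smooth ellipse, soft margin
        mask, _ = _lesion_mask(size, rng, r0, aspect, angle, 0.0)
        soft = ndimage.gaussian_filter(mask.astype(float), 1.2)
        lesion_level = 0.18
        img = background * (1.0 - soft) + lesion_level * soft
    else:  # malignant: spiculated, sharp margin, darker core, shadow
        mask, (cy, cx) = _lesion_mask(size, rng, r0, aspect, angle,
                                      cfg.irregularity)
        soft = ndimage.gaussian_filter(mask.astype(float), 0.4)
        lesion_level = 0.10
        img = background * (1.0 - soft) + lesion_level * soft
        # posterior acoustic shadow: darken the column band below the lesion
        cols = mask.any(axis=0)
        rows = np.flatnonzero(mask.any(axis=1))
        if rows.size:
            shadow = np.zeros((size, size))
            shadow[rows[-1]:, cols] = 1.0
            shadow = ndimage.gaussian_filter(shadow, 1.5)
            img *= 1.0 - 0.35 * shadow
    img = img * speckle
    return np.clip(img, 0.0, 1.0)


def generate_synthetic(cfg: SynthConfig) -> LabeledImageSet:
    """Deterministic phantom set: same config -> bitwise-identical arrays."""
    rng = np.random.default_rng(cfg.seed)
    n_pos = int(round(cfg.n_images * cfg.class_balance))
    n_pos = min(max(n_pos, 1), cfg.n_images - 1)
    labels = np.array([1] * n_pos + [0] * (cfg.n_images - n_pos))
    rng.shuffle(labels)
    images = np.stack([_one_image(rng, cfg, int(y)) for y in labels])
    return LabeledImageSet(images, labels, "train")


def lesion_features(images: np.ndarray) -> np.ndarray:
    """Two hand-crafted per-image features: lesion area fraction and
    radial roughness (std/mean of boundary-pixel distance to centroid)
    of the darkest connected region.  Used to show the synthetic task is
    separable by construction."""
    from skimage import filters, measure

    feats = np.empty((len(images), 2))
    for i, img in enumerate(images):
        smooth = ndimage.gaussian_filter(img, 1.0)
        mask = smooth < filters.threshold_otsu(smooth)
        lab = measure.label(mask)
        if lab.max() == 0:
            feats[i] = (0.0, 0.0)
            continue
        region = max(measure.regionprops(lab), key=lambda r: r.area)
        region_mask = lab == region.label
        area = region.area / img.size
        boundary = region_mask & ~ndimage.binary_erosion(region_mask)
        ys, xs = np.nonzero(boundary)
        cy, cx = region.centroid
        dist = np.hypot(ys - cy, xs - cx)
        rough = float(dist.std() / dist.mean()) if dist.size else 0.0
        feats[i] = (area, rough)
    return feats


# ---------------------------------------------------------------------------
# Plain-directory interchange: PNG files + labels CSV.


def write_image_dir(dataset: LabeledImageSet, directory) -> list:
    """Write PNGs plus labels.csv (filename,label); returns the filenames."""
    import imageio.v3 as iio

    os.makedirs(directory, exist_ok=True)
    names = []
    with open(os.path.join(directory, "labels.csv"), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["filename", "label"])
        for i, (img, lab) in enumerate(zip(dataset.images, dataset.labels)):
            name = f"img_{i:05d}.png"
            iio.imwrite(os.path.join(directory, name),
                        np.round(img * 255).astype(np.uint8))
            writer.writerow([name, int(lab)])
            names.append(name)
    return names


def read_image_dir(directory, split_name: str = "train") -> LabeledImageSet:
    import imageio.v3 as iio

    path = os.path.join(directory, "labels.csv")
    images, labels = [], []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            img = iio.imread(os.path.join(directory, row["filename"]))
            images.append(np.asarray(img, dtype=float) / 255.0)
            labels.append(int(row["label"]))
    return LabeledImageSet(np.stack(images), np.array(labels), split_name)
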