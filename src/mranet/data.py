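"""Dataset handling and synthetic fixtures.

Reads image/mask folders in the Kvasir-SEG convention (``root/images/*`` and
``root/masks/*`` with matching filename stems), applies the training
augmentations (random rotation, horizontal and vertical flips), preprocesses
samples to normalised network tensors, and generates synthetic endoscopy-style
fixtures: textured backgrounds with one or more smooth bright "polyp" blobs
whose boundaries are deformed and blurred, paired with their exact binary
masks. The generator emulates the qualitative challenges of real polyp data -
varying sizes, indistinct boundaries and scattered multi-blob distributions -
so the full pipeline is exercisable without downloads.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image
from scipy import ndimage

from .backbone import ConfigurationError

__all__ = [
    "SegSample",
    "SynthConfig",
    "IMAGENET_MEAN",
    "IMAGENET_STD",
    "load_seg_dataset",
    "write_samples",
    "hflip",
    "vflip",
    "rotate",
    "augment",
    "preprocess",
    "generate_synthetic",
    "SPLIT_RATIOS",
]

# Standard ImageNet channel statistics, used to normalise inputs.
IMAGENET_MEAN = np.array([0.485, 0.456, 0.406])
IMAGENET_STD = np.array([0.229, 0.224, 0.225])

# Train/val/test proportions mirroring the 880/120/196 official split sizes.
SPLIT_RATIOS = (880 / 1196, 120 / 1196, 196 / 1196)


@dataclass
class SegSample:
    """One image/mask pair with provenance."""

    image: np.ndarray  # H x W x 3 uint8
    mask: np.ndarray   # H x W uint8 in {0, 1}
    id: str
    source: str = "disk"  # "disk" | "synthetic"

    def __post_init__(self):
        if self.image.shape[:2] != self.mask.shape:
            raise ValueError(
                f"image {self.image.shape[:2]} and mask {self.mask.shape} "
                "spatial dims differ")
        if not np.all((self.mask == 0) | (self.mask == 1)):
            raise ValueError("mask values must be 0/1")


@dataclass
class SynthConfig:
    n_images: int = 8
    size: tuple[int, int] = (96, 96)
    polyps_per_image: tuple[int, int] = (1, 3)
    blob_radius_frac: tuple[float, float] = (0.08, 0.25)
    boundary_blur_px: float = 2.0
    background_texture_scale: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if self.n_images < 1:
            raise ConfigurationError("n_images must be >= 1")
        lo, hi = self.blob_radius_frac
        if not (0.0 < lo <= hi < 0.5):
            raise ConfigurationError(
                f"blob_radius_frac must satisfy 0 < lo <= hi < 0.5, "
                f"got {self.blob_radius_frac}")
        plo, phi = self.polyps_per_image
        if not (1 <= plo <= phi):
            raise ConfigurationError(
                f"polyps_per_image must be an increasing range from >= 1, "
                f"got {self.polyps_per_image}")


# ---------------------------------------------------------------------------
# disk I/O
# ---------------------------------------------------------------------------

_EXTS = (".png", ".jpg", ".jpeg")


def _scan(folder: str) -> dict[str, str]:
    out = {}
    for name in sorted(os.listdir(folder)):
        stem, ext = os.path.splitext(name)
        if ext.lower() in _EXTS:
            out[stem] = os.path.join(folder, name)
    return out


def load_seg_dataset(root_dir: str, split: str | None = None,
                     ratios: tuple[float, float, float] = SPLIT_RATIOS,
                     seed: int = 0) -> list[SegSample]:
    """Load image/mask pairs; optionally select a named split.

    Pairs are matched by filename stem and returned in lexicographic stem
    order. ``split`` of "train"/"val"/"test" selects from ``<split>.txt``
    stem lists in the root when present, otherwise from a seeded ratio split.
    """
    img_dir = os.path.join(root_dir, "images")
    mask_dir = os.path.join(root_dir, "masks")
    for d in (img_dir, mask_dir):
        if not os.path.isdir(d):
            raise FileNotFoundError(f"missing dataset folder: {d}")
    images = _scan(img_dir)
    masks = _scan(mask_dir)
    orphan_images = sorted(set(images) - set(masks))
    orphan_masks = sorted(set(masks) - set(images))
    if orphan_images or orphan_masks:
        raise ValueError(
            "unpaired files: images without masks "
            f"{orphan_images}, masks without images {orphan_masks}")
    stems = sorted(images)
    if split is not None:
        if split not in ("train", "val", "test"):
            raise ConfigurationError(f"unknown split {split!r}")
        listing = os.path.join(root_dir, f"{split}.txt")
        if os.path.isfile(listing):
            with open(listing) as fh:
                wanted = [line.strip() for line in fh if line.strip()]
            missing = sorted(set(wanted) - set(stems))
            if missing:
                raise ValueError(f"split file names unknown stems: {missing}")
            stems = sorted(wanted)
        else:
            rng = np.random.default_rng(seed)
            order = list(rng.permutation(stems))
            n = len(order)
            n_train = int(round(ratios[0] * n))
            n_val = int(round(ratios[1] * n))
            chosen = {"train": order[:n_train],
                      "val": order[n_train:n_train + n_val],
                      "test": order[n_train + n_val:]}[split]
            stems = sorted(chosen)
    samples = []
    for stem in stems:
        try:
            img = np.asarray(Image.open(images[stem]).convert("RGB"))
            raw_mask = np.asarray(Image.open(masks[stem]).convert("L"))
        except OSError as exc:
            raise OSError(f"unreadable file for stem {stem!r}: {exc}") from exc
        mask = (raw_mask >= 128).astype(np.uint8)  # near-binary masks tolerated
        samples.append(SegSample(image=img, mask=mask, id=stem, source="disk"))
    return samples


def write_samples(samples: list[SegSample], root_dir: str) -> None:
    """Write samples in the same images/ + masks/ layout (lossless PNG)."""
    img_dir = os.path.join(root_dir, "images")
    mask_dir = os.path.join(root_dir, "masks")
    os.makedirs(img_dir, exist_ok=True)
    os.makedirs(mask_dir, exist_ok=True)
    for s in samples:
        Image.fromarray(s.image).save(os.path.join(img_dir, f"{s.id}.png"))
        Image.fromarray((s.mask * 255).astype(np.uint8)).save(
            os.path.join(mask_dir, f"{s.id}.png"))


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def hflip(sample: SegSample) -> SegSample:
    return SegSample(image=sample.image[:, ::-1].copy(),
                     mask=sample.mask[:, ::-1].copy(),
                     id=sample.id, source=sample.source)


def vflip(sample: SegSample) -> SegSample:
    return SegSample(image=sample.image[::-1].copy(),
                     mask=sample.mask[::-1].copy(),
                     id=sample.id, source=sample.source)


def rotate(sample: SegSample, angle_deg: float) -> SegSample:
    """Rotate image (bilinear, reflection padding) and mask (nearest)."""
    if angle_deg == 0.0:
        return sample
    img = ndimage.rotate(sample.image.astype(np.float64), angle_deg,
                         reshape=False, order=1, mode="reflect")
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    mask = ndimage.rotate(sample.mask, angle_deg, reshape=False, order=0,
                          mode="constant", cval=0)
    return SegSample(image=img, mask=mask.astype(np.uint8),
                     id=sample.id, source=sample.source)


def augment(sample: SegSample, rng_seed: int) -> SegSample:
    """Random flips (p=0.5 each) and rotation by U(-90, 90) degrees (p=0.5).

    The same geometric transform is applied to image and mask; deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(rng_seed)
    out = sample
    if rng.random() < 0.5:
        out = hflip(out)
    if rng.random() < 0.5:
        out = vflip(out)
    if rng.random() < 0.5:
        out = rotate(out, float(rng.uniform(-90.0, 90.0)))
    return out


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(sample: SegSample, target_size: tuple[int, int],
               mean: np.ndarray = IMAGENET_MEAN,
               std: np.ndarray = IMAGENET_STD) -> tuple[np.ndarray, np.ndarray]:
    """Resize and normalise one sample to network tensors.

    Returns (image 3 x H x W float64 normalised, mask 1 x H x W float64 in
    {0, 1}). Image resizing is bilinear; the mask uses nearest-neighbour so
    it stays binary.
    """
    h, w = target_size
    if h % 32 or w % 32 or h <= 0 or w <= 0:
        raise ConfigurationError(
            f"target_size must be positive multiples of 32, got {target_size}")
    img = Image.fromarray(sample.image).resize((w, h), Image.BILINEAR)
    msk = Image.fromarray(sample.mask).resize((w, h), Image.NEAREST)
    x = np.asarray(img).astype(np.float64) / 255.0
    x = (x - mean) / std
    x = x.transpose(2, 0, 1)
    m = np.asarray(msk).astype(np.float64)[None]
    return x, m


def batch_tensors(samples: list[SegSample], target_size: tuple[int, int],
                  mean: np.ndarray = IMAGENET_MEAN,
                  std: np.ndarray = IMAGENET_STD) -> tuple[np.ndarray, np.ndarray]:
    """Stack preprocessed samples into (N,3,H,W) and (N,1,H,W) arrays."""
    pairs = [preprocess(s, target_size, mean, std) for s in samples]
    return (np.stack([p[0] for p in pairs]), np.stack([p[1] for p in pairs]))


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------

def _polyp_support(rng: np.random.Generator, h: int, w: int,
                   radius_px: float) -> np.ndarray | None:
    """Exact binary support of one deformed elliptical blob (or None if the
    sampled geometry leaves no room)."""
    margin = int(np.ceil(radius_px * 1.5)) + 1
    if 2 * margin >= min(h, w):
        margin = min(h, w) // 4
    cy = rng.uniform(margin, h - margin)
    cx = rng.uniform(margin, w - margin)
    ax = radius_px * rng.uniform(0.75, 1.25)
    ay = radius_px * rng.uniform(0.75, 1.25)
    theta0 = rng.uniform(0, 2 * np.pi)
    # smooth radial perturbation: low-order cosine series
    orders = (2, 3, 4, 5)
    amps = rng.uniform(0.0, 0.06, size=len(orders))
    phases = rng.uniform(0, 2 * np.pi, size=len(orders))
    yy, xx = np.mgrid[0:h, 0:w]
    dy = (yy - cy)
    dx = (xx - cx)
    cos_t, sin_t = np.cos(theta0), np.sin(theta0)
    u = (cos_t * dx + sin_t * dy) / ax
    v = (-sin_t * dx + cos_t * dy) / ay
    rho = np.hypot(u, v)
    ang = np.arctan2(v, u)
    bound = np.ones_like(ang)
    for k, a, ph in zip(orders, amps, phases):
        bound += a * np.cos(k * ang + ph)
    support = rho <= bound
    return support if support.any() else None


def generate_synthetic(config: SynthConfig) -> list[SegSample]:
    """Deterministically generate endoscopy-style blob images with masks."""
    rng = np.random.default_rng(config.seed)
    h, w = config.size
    samples = []
    for idx in range(config.n_images):
        # textured mucosa-like background
        base = np.array([170.0, 110.0, 100.0]) + rng.uniform(-20, 20, size=3)
        noise = rng.normal(0.0, 1.0, size=(h, w, 3))
        texture = ndimage.gaussian_filter(
            noise, sigma=(config.background_texture_scale,
                          config.background_texture_scale, 0))
        texture /= max(np.abs(texture).max(), 1e-9)
        img = base[None, None, :] + 25.0 * texture
        mask = np.zeros((h, w), dtype=np.uint8)
        n_polyps = int(rng.integers(config.polyps_per_image[0],
                                    config.polyps_per_image[1] + 1))
        placed = 0
        while placed < n_polyps:
            frac = rng.uniform(*config.blob_radius_frac)
            support = _polyp_support(rng, h, w, frac * min(h, w))
            if support is None:
                continue
            placed += 1
            mask |= support.astype(np.uint8)
            # brighter, slightly redder lesion with blurred boundary
            alpha = ndimage.gaussian_filter(
                support.astype(np.float64), sigma=config.boundary_blur_px)
            alpha = np.clip(alpha, 0.0, 1.0)[..., None]
            polyp_col = base + np.array([60.0, 35.0, 25.0]) \
                + rng.uniform(-10, 10, size=3)
            img = img * (1 - alpha) + alpha * polyp_col[None, None, :]
        img = np.clip(img, 0, 255).astype(np.uint8)
        samples.append(SegSample(image=img, mask=mask,
                                 id=f"synth-{config.seed}-{idx:03d}",
                                 source="synthetic"))
    return samples
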