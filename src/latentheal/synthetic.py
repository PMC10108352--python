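"""Synthetic head-like phantoms and sprite anomalies.

This module generates the controllable study data every downstream stage is
trained and tested on: 2D (or 3D) "head" phantoms — a bright skull ring
around a textured mid-gray interior with dark ventricle-like blobs — plus
binary sprite anomalies composited onto them at a chosen intensity, with
optional additive Gaussian noise.  Every generator is a pure function of its
seed.

The phantoms emulate the statistics that matter for latent-token density
modelling: a dark background, a closed high-intensity boundary, smooth
internal texture, and pose/shape variation across seeds, so that a
generative model has a nontrivial distribution to learn.  They do not
attempt radiological realism.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.measure import label

__all__ = [
    "Phantom",
    "ContaminatedSample",
    "generate_phantom",
    "generate_sprite",
    "contaminate",
    "generate_far_ood",
    "generate_dataset",
    "write_dataset",
]

MIN_SIZE = 16


@dataclass
class Phantom:
    """A head-like image in [0,1] plus the binary head-region mask."""

    image: np.ndarray
    tissue_mask: np.ndarray


@dataclass
class ContaminatedSample:
    """A phantom with a sprite composited in; `gt_mask` is the sprite support."""

    image: np.ndarray
    gt_mask: np.ndarray
    sprite_intensity: float
    noise_sd: float


def _check_size(size) -> tuple[int, ...]:
    size = tuple(int(s) for s in size)
    if any(s < MIN_SIZE for s in size):
        raise ValueError(f"each dimension must be >= {MIN_SIZE}, got {size}")
    return size


def _coord_grids(size):
    return np.meshgrid(*[np.arange(s, dtype=float) for s in size], indexing="ij")


def _ellipse_mask(size, center, axes, angle: float = 0.0) -> np.ndarray:
    """Filled (rotated in the first two axes, 2D only) ellipse/ellipsoid."""
    grids = _coord_grids(size)
    rel = [g - c for g, c in zip(grids, center)]
    if len(size) == 2 and angle != 0.0:
        c, s = np.cos(angle), np.sin(angle)
        rel = [c * rel[0] + s * rel[1], -s * rel[0] + c * rel[1]]
    r2 = sum((r / a) ** 2 for r, a in zip(rel, axes))
    return r2 <= 1.0


def generate_phantom(rng_seed: int, size=(64, 64)) -> Phantom:
    """Deterministically generate one head-like phantom.

    Appearance: concentric ellipses — a bright "skull" ring, a textured
    mid-gray interior, and 1–3 dark ventricle-like blobs; pose, axes and
    texture vary across seeds.  Background is exactly 0.
    """
    size = _check_size(size)
    rng = np.random.default_rng(rng_seed)
    nd = len(size)
    center = [s / 2.0 + rng.uniform(-0.05, 0.05) * s for s in size]
    axes = [rng.uniform(0.28, 0.38) * s for s in size]
    angle = rng.uniform(-0.35, 0.35) if nd == 2 else 0.0

    outer = _ellipse_mask(size, center, axes, angle)
    inner = _ellipse_mask(size, center, [0.85 * a for a in axes], angle)
    skull = outer & ~inner

    image = np.zeros(size, dtype=np.float64)
    image[skull] = rng.uniform(0.82, 0.95)

    base = rng.uniform(0.40, 0.50)
    texture = rng.normal(size=size)
    texture = gaussian_filter(texture, sigma=min(size) / 10.0, mode="reflect")
    tmax = np.abs(texture).max()
    if tmax > 0:
        texture = texture / tmax * 0.08
    image[inner] = base + texture[inner]

    for _ in range(rng.integers(1, 4)):
        voff = [rng.uniform(-0.18, 0.18) * a for a in axes]
        vcenter = [c + o for c, o in zip(center, voff)]
        vaxes = [rng.uniform(0.08, 0.18) * a for a in axes]
        vent = _ellipse_mask(size, vcenter, vaxes, angle) & inner
        image[vent] = rng.uniform(0.08, 0.16)

    return Phantom(image=np.clip(image, 0.0, 1.0), tissue_mask=outer)


def generate_sprite(
    rng_seed: int,
    size=(64, 64),
    shape_class: str = "ellipse",
    area_bounds: tuple[float, float] = (0.02, 0.15),
) -> np.ndarray:
    """One connected binary sprite with area in `area_bounds` × image area.

    `shape_class` is one of ``ellipse``, ``square`` (axis-aligned filled
    rectangle) or ``blob`` (thresholded smoothed noise, largest component).
    """
    size = _check_size(size)
    rng = np.random.default_rng(rng_seed)
    total = float(np.prod(size))
    lo, hi = area_bounds
    for _ in range(200):
        if shape_class == "ellipse":
            center = [rng.uniform(0.2, 0.8) * s for s in size]
            axes = [rng.uniform(0.06, 0.22) * s for s in size]
            mask = _ellipse_mask(size, center, axes, rng.uniform(0, np.pi) if len(size) == 2 else 0.0)
        elif shape_class == "square":
            mask = np.ones(size, dtype=bool)
            for ax, s in enumerate(size):
                w = int(rng.uniform(0.1, 0.4) * s)
                w = max(w, 2)
                start = rng.integers(0, max(s - w, 1))
                keep = np.zeros(s, dtype=bool)
                keep[start : start + w] = True
                mask &= np.expand_dims(keep, tuple(i for i in range(len(size)) if i != ax))
        elif shape_class == "blob":
            noise = gaussian_filter(rng.normal(size=size), sigma=min(size) / 12.0, mode="wrap")
            mask = noise > np.quantile(noise, rng.uniform(0.88, 0.95))
            lab = label(mask)
            if lab.max() == 0:
                continue
            counts = np.bincount(lab.ravel())[1:]
            mask = lab == (1 + int(np.argmax(counts)))
        else:
            raise ValueError(f"unknown shape_class {shape_class!r}")
        frac = mask.sum() / total
        if lo <= frac <= hi and label(mask).max() == 1:
            return mask
    raise RuntimeError(
        f"could not draw a {shape_class} sprite with area in {area_bounds} after 200 tries"
    )


def _shift_mask(mask: np.ndarray, shift) -> np.ndarray:
    """Translate a binary mask, dropping anything pushed off the grid."""
    out = np.zeros_like(mask)
    src = []
    dst = []
    for s, n in zip(shift, mask.shape):
        s = int(s)
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = mask[tuple(src)]
    return out


def contaminate(
    phantom: Phantom,
    sprite: np.ndarray,
    intensity: float,
    noise_sd: float = 0.0,
    rng_seed: int = 0,
    min_overlap: float = 0.5,
    max_retries: int = 20,
) -> ContaminatedSample:
    """Composite `sprite` into `phantom` at `intensity` (+ optional noise).

    Pixels under the sprite are set to `intensity`, then Gaussian noise of
    standard deviation `noise_sd` is added to those pixels and the image is
    clipped back to [0,1].  The sprite must overlap the head region by at
    least `min_overlap` of its own area; otherwise it is re-positioned (up
    to `max_retries` random translations toward/around the head) before
    giving up.
    """
    if not 0.0 <= intensity <= 1.0:
        raise ValueError(f"intensity must be in [0,1], got {intensity}")
    rng = np.random.default_rng(rng_seed)
    sprite = sprite.astype(bool)
    area = sprite.sum()
    if area == 0:
        return ContaminatedSample(
            image=phantom.image.copy(),
            gt_mask=np.zeros_like(sprite),
            sprite_intensity=float(intensity),
            noise_sd=float(noise_sd),
        )

    placed = sprite
    tissue = phantom.tissue_mask.astype(bool)
    for attempt in range(max_retries + 1):
        overlap = (placed & tissue).sum() / placed.sum() if placed.sum() else 0.0
        if overlap >= min_overlap and placed.sum() > 0:
            break
        if attempt == max_retries:
            raise RuntimeError(
                f"sprite/head overlap {overlap:.2f} < {min_overlap} after "
                f"{max_retries} placement retries"
            )
        # aim the sprite's centroid at a random point inside the head
        centroid = np.array([c.mean() for c in np.nonzero(sprite)])
        tissue_pts = np.argwhere(tissue)
        target = tissue_pts[rng.integers(len(tissue_pts))]
        jitter = rng.integers(-3, 4, size=sprite.ndim)
        placed = _shift_mask(sprite, np.round(target - centroid).astype(int) + jitter)

    image = phantom.image.copy()
    values = np.full(int(placed.sum()), float(intensity))
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    image[placed] = np.clip(values, 0.0, 1.0)
    return ContaminatedSample(
        image=image,
        gt_mask=placed.copy(),
        sprite_intensity=float(intensity),
        noise_sd=float(noise_sd),
    )


def generate_far_ood(rng_seed: int, size=(64, 64), kind: str = "uniform") -> np.ndarray:
    """Far out-of-distribution fixtures: uniform noise, or a structurally
    different multi-lobe ("hand-like") phantom class."""
    size = _check_size(size)
    rng = np.random.default_rng(rng_seed)
    if kind == "uniform":
        return rng.uniform(0.0, 1.0, size=size)
    if kind == "multilobe":
        image = np.zeros(size, dtype=np.float64)
        n_lobes = rng.integers(3, 7)
        for _ in range(n_lobes):
            center = [rng.uniform(0.15, 0.85) * s for s in size]
            axes = [rng.uniform(0.06, 0.16) * s for s in size]
            lobe = _ellipse_mask(size, center, axes, rng.uniform(0, np.pi) if len(size) == 2 else 0.0)
            image[lobe] = rng.uniform(0.5, 0.8)
        image += gaussian_filter(rng.normal(size=size), sigma=3.0) * 0.03
        return np.clip(image, 0.0, 1.0)
    raise ValueError(f"unknown far-OOD kind {kind!r}")


def generate_dataset(
    n: int,
    seed: int,
    size=(64, 64),
    contaminated: bool = False,
    intensities=(0.0, 1.0),
    noise_sd: float = 0.0,
    shape_classes=("ellipse", "square", "blob"),
):
    """Generate `n` phantoms (optionally sprite-contaminated).

    Seeds for individual samples are derived from `seed` via SeedSequence
    spawning, so datasets with different `seed` are independent and the
    whole dataset is reproducible.  For contaminated samples the sprite
    intensity cycles through `intensities` (binary-valued sprites use 0 and
    1) and the shape class cycles through `shape_classes`.

    Returns a list of Phantom or ContaminatedSample.
    """
    child_seeds = np.random.SeedSequence(seed).generate_state(3 * n)
    out = []
    for i in range(n):
        phantom = generate_phantom(int(child_seeds[3 * i]), size=size)
        if not contaminated:
            out.append(phantom)
            continue
        shape_class = shape_classes[i % len(shape_classes)]
        sprite = generate_sprite(int(child_seeds[3 * i + 1]), size=size, shape_class=shape_class)
        intensity = intensities[i % len(intensities)]
        out.append(
            contaminate(
                phantom,
                sprite,
                intensity=intensity,
                noise_sd=noise_sd,
                rng_seed=int(child_seeds[3 * i + 2]),
            )
        )
    return out


def write_dataset(samples, out_dir, split: str = "train", seed: int | None = None) -> Path:
    """Write samples as PNG (2D) or NIfTI (3D) plus a manifest CSV."""
    from . import data_io

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    new_file = not manifest.exists()
    with open(manifest, "a", newline="") as fh:
        writer = csv.writer(fh)
        if new_file:
            writer.writerow(["sample_id", "split", "seed", "intensity", "noise_sd", "image", "gt_mask"])
        for i, sample in enumerate(samples):
            sid = f"{split}_{i:05d}"
            if isinstance(sample, ContaminatedSample):
                image, gt = sample.image, sample.gt_mask
                intensity, noise_sd = sample.sprite_intensity, sample.noise_sd
            else:
                image, gt = sample.image, None
                intensity, noise_sd = "", ""
            ext = ".png" if image.ndim == 2 else ".nii.gz"
            img_path = out_dir / (sid + ext)
            data_io.save_image(image, img_path)
            gt_path = ""
            if gt is not None:
                gt_path = str(out_dir / (sid + "_gt" + ext))
                data_io.save_image(gt.astype(np.float64), gt_path)
            writer.writerow([sid, split, seed if seed is not None else "", intensity, noise_sd, str(img_path), gt_path])
    return manifest
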