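"""Likelihood-guided healing and residual-based anomaly segmentation.

The pipeline for one image and one ordering:

1. encode + quantize the image to a latent index grid, flatten it with the
   ordering into a token sequence s;
2. score every token with the autoregressive model in a single
   teacher-forced pass over the *original* sequence and build the
   resampling mask  m_i = 1  iff  p(s_i | s_<i) <= threshold;
3. heal: copy unmasked tokens, and resample each masked token
   left-to-right from p(. | healed prefix), so earlier corrections inform
   later ones (one pass, no iteration);
4. decode the healed sequence to the "healed" image x' and form residuals
   |x - x'| (or max(x - x', 0) for hyperintense-lesion post-processing);
5. filter the residuals by the upsampled, Gaussian-smoothed resampling
   mask, suppressing false positives where the reconstruction is merely
   blurry rather than anomalous.

An ensemble averages the per-ordering masked residuals; each member owns
its own resampling mask.  If no token falls below the threshold the healed
reconstruction is bit-identical to the plain VQ-VAE reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .density import LatentSequenceModel, LikelihoodProfile, sample_next
from .orderings import Ordering
from .vqvae import VQVAE

__all__ = [
    "resampling_mask",
    "heal_sequence",
    "residual_map",
    "latent_mask_to_image_mask",
    "masked_residual",
    "binarize",
    "SegmentationResult",
    "segment_single",
    "segment_ensemble",
]

DEFAULT_THRESHOLD_2D = 0.005
DEFAULT_THRESHOLD_3D = 0.001


def resampling_mask(profile: LikelihoodProfile | np.ndarray, threshold: float) -> np.ndarray:
    """Binary mask of tokens whose likelihood is at or below `threshold`.

    m_i = 1 iff p(s_i) <= threshold (ties count as anomalous).
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0,1), got {threshold}")
    p = profile.p if isinstance(profile, LikelihoodProfile) else np.asarray(profile)
    return (p <= threshold).astype(np.int8)


def heal_sequence(
    model: LatentSequenceModel,
    tokens: np.ndarray,
    mask: np.ndarray,
    rng: np.random.Generator,
    temperature: float = 1.0,
) -> np.ndarray:
    """Resample masked tokens ancestrally, conditioning on the healed prefix.

    Unmasked positions are copied verbatim; masked positions are visited
    left-to-right and drawn from p(. | healed s_<i), so a resampled value
    feeds the predictions of every later masked position.
    """
    tokens = np.asarray(tokens)
    mask = np.asarray(mask)
    if mask.shape != tokens.shape:
        raise ValueError(f"mask length {mask.shape} != sequence length {tokens.shape}")
    healed = tokens.copy()
    for i in np.nonzero(mask)[0]:
        inputs = np.concatenate([[model.bos_id], healed[:i]])
        logits = model.logits(inputs[None]).data[0, -1]
        z = logits - logits.max()
        probs = np.exp(z)
        probs /= probs.sum()
        healed[i] = sample_next(probs, rng, temperature=temperature)
    return healed


def residual_map(x: np.ndarray, x_healed: np.ndarray, signed: bool = False) -> np.ndarray:
    """Pixel-wise residual between an image and its healed reconstruction.

    `signed=False`: |x - x'| (default).  `signed=True`: max(x - x', 0),
    the positive-residual post-processing for lesions known to be
    hyperintense relative to the healed tissue.
    """
    x, x_healed = np.asarray(x), np.asarray(x_healed)
    if x.shape != x_healed.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {x_healed.shape}")
    diff = x - x_healed
    return np.maximum(diff, 0.0) if signed else np.abs(diff)


def latent_mask_to_image_mask(
    mask: np.ndarray,
    ordering: Ordering,
    image_shape: tuple[int, ...],
    sigma: float | None = None,
) -> np.ndarray:
    """Resampling mask -> smooth image-resolution mask in [0,1].

    The 1D mask is reshaped back onto the latent grid with the inverse
    ordering, upsampled by nearest-neighbour replication (each latent cell
    covers its f^nd image patch) and smoothed with a Gaussian filter of
    standard deviation `sigma` pixels (default f/2).
    """
    grid = ordering.invert(np.asarray(mask)).astype(np.float64)
    factors = []
    for s_img, s_lat in zip(image_shape, grid.shape):
        if s_img % s_lat:
            raise ValueError(f"image shape {image_shape} not a multiple of latent {grid.shape}")
        factors.append(s_img // s_lat)
    if len(set(factors)) != 1:
        raise ValueError(f"anisotropic upsampling factors {factors} not supported")
    f = factors[0]
    up = grid
    for ax in range(up.ndim):
        up = np.repeat(up, f, axis=ax)
    if sigma is None:
        sigma = f / 2.0
    return np.clip(gaussian_filter(up, sigma=sigma, mode="nearest"), 0.0, 1.0)


def masked_residual(residual: np.ndarray, image_mask: np.ndarray) -> np.ndarray:
    """Elementwise product; never exceeds the unmasked residual."""
    residual, image_mask = np.asarray(residual), np.asarray(image_mask)
    if residual.shape != image_mask.shape:
        raise ValueError(f"shape mismatch {residual.shape} vs {image_mask.shape}")
    return residual * image_mask


def binarize(residual: np.ndarray, threshold: float) -> np.ndarray:
    """Segment anomalies as the pixels with residual strictly above threshold."""
    return (np.asarray(residual) > threshold).astype(np.int8)


@dataclass
class SegmentationResult:
    """Everything one ordering produces for one image."""

    residual: np.ndarray  # mask-filtered residual map
    residual_unmasked: np.ndarray
    resampling_mask: np.ndarray  # per-token binary mask (sequence order)
    image_mask: np.ndarray  # upsampled smoothed mask in image space
    healed_image: np.ndarray
    healed_tokens: np.ndarray
    profile: LikelihoodProfile

    @property
    def n_resampled(self) -> int:
        return int(self.resampling_mask.sum())


def segment_single(
    image: np.ndarray,
    vqvae: VQVAE,
    model: LatentSequenceModel,
    ordering: Ordering,
    threshold: float = DEFAULT_THRESHOLD_2D,
    sigma: float | None = None,
    rng: np.random.Generator | None = None,
    signed: bool = False,
) -> SegmentationResult:
    """Full healing chain for one image under one ordering.

    The image must already be normalized to [0,1] and match the VQ-VAE's
    configured input shape.
    """
    model.check_ordering(ordering)
    rng = rng or np.random.default_rng(0)
    indices = vqvae.tokens(image)
    tokens = ordering.apply(indices)
    profile = model.sequence_likelihood(tokens)
    mask = resampling_mask(profile, threshold)
    healed_tokens = heal_sequence(model, tokens, mask, rng)
    healed_grid = ordering.invert(healed_tokens)
    healed_image = vqvae.decode(healed_grid)
    resid = residual_map(image, healed_image, signed=signed)
    image_mask = latent_mask_to_image_mask(mask, ordering, image.shape, sigma=sigma)
    return SegmentationResult(
        residual=masked_residual(resid, image_mask),
        residual_unmasked=resid,
        resampling_mask=mask,
        image_mask=image_mask,
        healed_image=healed_image,
        healed_tokens=healed_tokens,
        profile=profile,
    )


def segment_ensemble(
    image: np.ndarray,
    vqvae: VQVAE,
    members: list[tuple[LatentSequenceModel, Ordering]],
    threshold: float = DEFAULT_THRESHOLD_2D,
    sigma: float | None = None,
    rng: np.random.Generator | None = None,
    signed: bool = False,
):
    """Mean of the per-ordering masked residual maps.

    Each member computes its own resampling mask and healed reconstruction;
    the mask is applied per member before averaging.  Returns (mean
    residual, list of SegmentationResult).
    """
    if not members:
        raise ValueError("ensemble needs at least one (model, ordering) member")
    rng = rng or np.random.default_rng(0)
    results = [
        segment_single(image, vqvae, model, ordering, threshold=threshold, sigma=sigma, rng=rng, signed=signed)
        for model, ordering in members
    ]
    mean_residual = np.mean([r.residual for r in results], axis=0)
    return mean_residual, results
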