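"""Healing chain: resampling mask, sequential resampling, residual filtering."""

import numpy as np
import pytest

from latentheal.density import LatentSequenceModel, TransformerConfig
from latentheal.healing import (
    binarize,
    heal_sequence,
    latent_mask_to_image_mask,
    masked_residual,
    resampling_mask,
    residual_map,
    segment_ensemble,
    segment_single,
)
from latentheal.orderings import raster_ordering
from latentheal.vqvae import VQVAE, VQVAEConfig


# --- resampling mask --------------------------------------------------------


def test_resampling_mask_rule_and_tie_handling():
    p = np.array([0.5, 0.004, 0.9])
    assert resampling_mask(p, 0.005).tolist() == [0, 1, 0]
    # a probability exactly at the threshold counts as anomalous
    assert resampling_mask(np.array([0.005]), 0.005).tolist() == [1]


def test_resampling_mask_worked_example_threshold():
    # higher working threshold marks everything at or below 0.05
    p = np.array([0.2, 0.05, 0.01, 0.9])
    assert resampling_mask(p, 0.05).tolist() == [0, 1, 1, 0]


def test_resampling_mask_limits():
    p = np.full(6, 1.0 / 32)
    assert resampling_mask(p, 1e-9).sum() == 0
    assert resampling_mask(p, 1.0 - 1e-9).sum() == 6


def test_resampling_mask_rejects_bad_threshold():
    with pytest.raises(ValueError, match="threshold"):
        resampling_mask(np.array([0.5]), 0.0)


# --- healing ----------------------------------------------------------------


class ChainModel:
    """Deterministic stand-in model: next token is (previous + 1) mod K."""

    def __init__(self, K=8, seq_len=8):
        self.K = K
        self.bos_id = K
        self.seq_len = seq_len

    def logits(self, inputs):
        inputs = np.atleast_2d(inputs)
        b, t = inputs.shape
        out = np.full((b, t, self.K), -1e9)
        nxt = np.where(inputs == self.bos_id, 0, (inputs + 1) % self.K)
        for i in range(b):
            out[i, np.arange(t), nxt[i]] = 0.0

        class _T:  # minimal Tensor-like wrapper
            pass

        w = _T()
        w.data = out
        return w


def test_heal_identity_with_empty_mask():
    rng = np.random.default_rng(0)
    model = ChainModel()
    tokens = rng.integers(0, 8, size=8)
    healed = heal_sequence(model, tokens, np.zeros(8, dtype=int), rng)
    assert np.array_equal(healed, tokens)


def test_heal_all_masked_deterministic_model_unrolls_greedy_chain():
    model = ChainModel()
    tokens = np.array([5, 5, 5, 5, 5, 5, 5, 5])
    healed = heal_sequence(model, tokens, np.ones(8, dtype=int), np.random.default_rng(0))
    # BOS -> 0, then each healed value feeds the next prediction
    assert healed.tolist() == [0, 1, 2, 3, 4, 5, 6, 7]


def test_heal_conditions_on_healed_prefix_not_original():
    model = ChainModel()
    tokens = np.array([5, 9 % 8, 3, 3, 3, 3, 3, 3])
    mask = np.array([1, 1, 0, 0, 0, 0, 0, 0])
    healed = heal_sequence(model, tokens, mask, np.random.default_rng(0))
    # position 1 must follow healed[0]=0, not original tokens[0]=5
    assert healed[0] == 0 and healed[1] == 1
    assert np.array_equal(healed[2:], tokens[2:])


def test_heal_unmasked_positions_never_change_and_draws_are_seeded():
    cfg = TransformerConfig(vocab_size=8, seq_len=8, d_model=16, n_heads=2, n_layers=1, d_ff=32, seed=0)
    model = LatentSequenceModel(cfg, {})
    rng = np.random.default_rng(5)
    for p in model.parameters():
        p.data = p.data + rng.normal(0, 0.3, p.data.shape)
    tokens = np.arange(8) % 8
    mask = np.array([0, 1, 0, 1, 0, 0, 1, 0])
    h1 = heal_sequence(model, tokens, mask, np.random.default_rng(1))
    h2 = heal_sequence(model, tokens, mask, np.random.default_rng(1))
    h3 = heal_sequence(model, tokens, mask, np.random.default_rng(2))
    assert np.array_equal(h1, h2)
    unmasked = mask == 0
    assert np.array_equal(h1[unmasked], tokens[unmasked])
    assert np.array_equal(h3[unmasked], tokens[unmasked])


def test_heal_rejects_mask_length_mismatch():
    with pytest.raises(ValueError, match="mask"):
        heal_sequence(ChainModel(), np.zeros(8, dtype=int), np.zeros(7, dtype=int), np.random.default_rng(0))


# --- residuals --------------------------------------------------------------


def test_residual_map_abs_and_positive_modes():
    x = np.array([0.2, 0.9])
    xh = np.array([0.5, 0.4])
    np.testing.assert_allclose(residual_map(x, xh), [0.3, 0.5])
    np.testing.assert_allclose(residual_map(x, xh, signed=True), [0.0, 0.5])
    assert np.array_equal(residual_map(x, x), [0.0, 0.0])


def test_positive_residual_never_exceeds_absolute():
    rng = np.random.default_rng(1)
    x, xh = rng.random((16, 16)), rng.random((16, 16))
    assert np.all(residual_map(x, xh, signed=True) <= residual_map(x, xh))


def test_masked_residual_limits_and_bound():
    rng = np.random.default_rng(2)
    r = rng.random((8, 8))
    assert np.array_equal(masked_residual(r, np.ones_like(r)), r)
    assert np.all(masked_residual(r, np.zeros_like(r)) == 0)
    m = rng.random((8, 8))
    assert np.all(masked_residual(r, m) <= r)


def test_binarize_rules():
    r = np.array([0.1, 0.6])
    assert binarize(r, 0.5).tolist() == [0, 1]
    assert binarize(r, 0.0).tolist() == [1, 1]
    assert binarize(r, 0.7).tolist() == [0, 0]


# --- latent mask upsampling -------------------------------------------------


def test_latent_mask_constant_limits():
    o = raster_ordering((4, 4))
    ones = latent_mask_to_image_mask(np.ones(16, dtype=int), o, (32, 32), sigma=2.0)
    zeros = latent_mask_to_image_mask(np.zeros(16, dtype=int), o, (32, 32), sigma=2.0)
    np.testing.assert_allclose(ones, 1.0)
    np.testing.assert_allclose(zeros, 0.0)


def test_latent_mask_delta_gives_bump_centred_on_patch():
    o = raster_ordering((8, 8))
    mask = np.zeros(64, dtype=int)
    cell = (3, 4)
    mask[o.position_of(cell)] = 1
    f, sigma = 8, 2.0
    img_mask = latent_mask_to_image_mask(mask, o, (64, 64), sigma=sigma)
    peak = np.unravel_index(np.argmax(img_mask), img_mask.shape)
    cy = cell[0] * f + f // 2
    cx = cell[1] * f + f // 2
    assert abs(peak[0] - cy) <= 1 and abs(peak[1] - cx) <= 1
    assert img_mask.max() <= 1.0 and img_mask.min() >= 0.0
    # mass decays away from the patch
    assert img_mask[cy, cx] > 5 * img_mask[cy, min(cx + 3 * f, 63)]


# --- segmentation chains ----------------------------------------------------


@pytest.fixture(scope="module")
def tiny_pipeline():
    vq_cfg = VQVAEConfig(input_shape=(32, 32), f=4, K=8, n_z=16, channels=(4, 8), seed=0)
    vq = VQVAE(vq_cfg)
    t_cfg = TransformerConfig(vocab_size=8, seq_len=64, d_model=16, n_heads=2, n_layers=1, d_ff=32, seed=0)
    ordering = raster_ordering((8, 8))
    model = LatentSequenceModel(t_cfg, ordering.descriptor)
    return vq, model, ordering


def test_identity_chain_when_no_token_below_threshold(tiny_pipeline):
    """An untrained model is uniform (p = 1/8 per token), so nothing falls
    below a small threshold and the healed reconstruction is bit-identical
    to the plain VQ-VAE reconstruction."""
    vq, model, ordering = tiny_pipeline
    rng = np.random.default_rng(0)
    image = rng.random((32, 32))
    res = segment_single(image, vq, model, ordering, threshold=0.005, rng=rng)
    assert res.n_resampled == 0
    assert np.array_equal(res.healed_image, vq.reconstruct(image))
    assert np.all(res.residual == 0)  # empty mask -> all-zero image mask


def test_segment_single_is_seed_reproducible(tiny_pipeline):
    vq, model, ordering = tiny_pipeline
    image = np.random.default_rng(1).random((32, 32))
    # force resampling everywhere with a threshold above 1/K
    a = segment_single(image, vq, model, ordering, threshold=0.2, rng=np.random.default_rng(3))
    b = segment_single(image, vq, model, ordering, threshold=0.2, rng=np.random.default_rng(3))
    assert a.n_resampled > 0
    assert np.array_equal(a.healed_tokens, b.healed_tokens)
    assert np.array_equal(a.residual, b.residual)


def test_ensemble_of_one_equals_single_and_mean_is_bounded(tiny_pipeline):
    vq, model, ordering = tiny_pipeline
    image = np.random.default_rng(2).random((32, 32))
    single = segment_single(image, vq, model, ordering, threshold=0.2, rng=np.random.default_rng(7))
    mean_resid, results = segment_ensemble(
        image, vq, [(model, ordering)], threshold=0.2, rng=np.random.default_rng(7)
    )
    np.testing.assert_array_equal(mean_resid, single.residual)
    assert len(results) == 1
    # with several members the mean is bounded by the member-wise max
    from latentheal.orderings import ensemble_orderings
    from latentheal.density import LatentSequenceModel as LSM

    members = []
    for o in ensemble_orderings("raster", (8, 8), count=3):
        m = LSM(model.config, o.descriptor)
        members.append((m, o))
    mean_resid, results = segment_ensemble(
        image, vq, members, threshold=0.2, rng=np.random.default_rng(8)
    )
    stack = np.stack([r.residual for r in results])
    assert np.all(mean_resid <= stack.max(axis=0) + 1e-12)
    assert np.all(mean_resid >= stack.min(axis=0) - 1e-12)
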