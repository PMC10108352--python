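"""Autoregressive sequence model: likelihoods, causality, sampling, training."""

import numpy as np
import pytest

from latentheal.density import (
    LatentSequenceModel,
    TransformerConfig,
    evaluate_nll,
    load_density_model,
    sample_next,
    save_density_model,
    train_density_model,
)
from latentheal.orderings import raster_ordering

K, D = 8, 16


def make_model(seed=0, **kw):
    cfg = TransformerConfig(
        vocab_size=K, seq_len=D, d_model=32, n_heads=4, n_layers=2, d_ff=64, seed=seed, **kw
    )
    return LatentSequenceModel(cfg, {"class": "raster", "shape": [4, 4]})


def randomized(model, scale=0.1, seed=1):
    rng = np.random.default_rng(seed)
    for p in model.parameters():
        p.data = p.data + rng.normal(0, scale, p.data.shape)
    return model


def test_untrained_model_is_uniform_and_distributions_normalize():
    m = make_model()
    seq = np.concatenate([[m.bos_id], np.arange(D - 1) % K])
    probs = m.next_token_distributions(seq)
    assert probs.shape == (D, K)
    np.testing.assert_allclose(probs, 1.0 / K, atol=1e-12)
    m2 = randomized(make_model(), 0.3)
    probs2 = m2.next_token_distributions(seq)
    np.testing.assert_allclose(probs2.sum(axis=1), 1.0, atol=1e-5)


def test_uniform_model_sequence_logp_closed_form():
    m = make_model()
    prof = m.sequence_likelihood(np.zeros(D, dtype=int))
    assert prof.logp_total == pytest.approx(-D * np.log(K), abs=1e-9)
    assert np.all(prof.p > 0) and np.all(prof.p <= 1)
    assert prof.logp_total == pytest.approx(prof.logp.sum())


def test_sequence_likelihood_matches_prefixwise_chain_rule():
    """Teacher-forced profile equals the explicit chain-rule product where
    each conditional is computed from its own prefix forward pass."""
    m = randomized(make_model(), 0.3)
    rng = np.random.default_rng(2)
    tokens = rng.integers(0, K, size=D)
    prof = m.sequence_likelihood(tokens)
    for i in [0, 1, D // 2, D - 1]:
        prefix = np.concatenate([[m.bos_id], tokens[:i]])
        probs = m.next_token_distributions(prefix)
        assert prof.p[i] == pytest.approx(probs[-1, tokens[i]], abs=1e-6)


def test_causality_perturbation_probe():
    m = randomized(make_model(), 0.3)
    rng = np.random.default_rng(3)
    for _ in range(10):
        s1 = rng.integers(0, K, size=D)
        j = int(rng.integers(0, D))
        s2 = s1.copy()
        s2[j] = (s2[j] + 1 + rng.integers(0, K - 1)) % K
        i1 = np.concatenate([[m.bos_id], s1[:-1]])
        i2 = np.concatenate([[m.bos_id], s2[:-1]])
        p1 = m.next_token_distributions(i1)
        p2 = m.next_token_distributions(i2)
        diff = np.abs(p1 - p2).max(axis=1)
        assert np.all(diff[: j + 1] == 0.0)


def test_context_length_overflow_raises():
    m = make_model()
    with pytest.raises(ValueError, match="context"):
        m.logits(np.zeros((1, D + 1), dtype=int))


def test_ordering_descriptor_mismatch_refused():
    m = make_model()
    other = raster_ordering((4, 4), reflect=(True, False))
    with pytest.raises(ValueError, match="ordering"):
        m.check_ordering(other)


def test_sample_next_contracts():
    rng = np.random.default_rng(0)
    onehot = np.zeros(K)
    onehot[3] = 1.0
    assert all(sample_next(onehot, rng) == 3 for _ in range(5))
    uniform = np.full(4, 0.25)
    draws = [sample_next(uniform, rng) for _ in range(10_000)]
    freqs = np.bincount(draws, minlength=4) / 10_000
    np.testing.assert_allclose(freqs, 0.25, atol=0.02)
    a = sample_next(uniform, np.random.default_rng(7))
    b = sample_next(uniform, np.random.default_rng(7))
    assert a == b


@pytest.fixture(scope="module")
def degenerate_fit():
    seq = np.arange(D) % K
    seqs = np.tile(seq, (64, 1))
    cfg = TransformerConfig(
        vocab_size=K, seq_len=D, d_model=32, n_heads=4, n_layers=2, d_ff=64,
        epochs=150, batch_size=32, seed=0,
    )
    model, log = train_density_model(seqs, cfg, val_sequences=seqs[:4])
    return seq, model, log, cfg


def test_degenerate_fit_concentrates_likelihood(degenerate_fit):
    seq, model, log, _ = degenerate_fit
    fitted = model.sequence_likelihood(seq).logp_total
    other = model.sequence_likelihood((seq + 3) % K).logp_total
    assert fitted > -2.0  # near 0 for a single repeated sequence
    assert fitted > other + 10.0


def test_training_reduces_heldout_nll_below_uniform(degenerate_fit):
    _, _, log, _ = degenerate_fit
    assert log["val_nll"][-1] < D * np.log(K)
    assert log["train_nll"][-1] < log["train_nll"][0]


def test_training_is_deterministic():
    rng = np.random.default_rng(5)
    seqs = rng.integers(0, K, size=(32, D))
    cfg = TransformerConfig(
        vocab_size=K, seq_len=D, d_model=32, n_heads=2, n_layers=1, d_ff=32,
        epochs=3, batch_size=16, seed=4,
    )
    _, log1 = train_density_model(seqs, cfg)
    _, log2 = train_density_model(seqs, cfg)
    assert log1["train_nll"] == log2["train_nll"]


def test_in_distribution_scores_above_shuffled_sequences(degenerate_fit):
    """After training, held-out in-distribution sequences get higher mean
    log-likelihood than structurally unrelated ones."""
    seq, model, _, _ = degenerate_fit
    rng = np.random.default_rng(6)
    ood = rng.integers(0, K, size=(8, D))
    ind_logp = model.sequence_likelihood(seq).logp_total
    ood_logp = np.mean([model.sequence_likelihood(s).logp_total for s in ood])
    assert ind_logp > ood_logp


def test_checkpoint_round_trip(tmp_path, degenerate_fit):
    seq, model, _, _ = degenerate_fit
    path = tmp_path / "density.npz"
    save_density_model(model, path)
    loaded = load_density_model(path)
    assert loaded.ordering_descriptor == model.ordering_descriptor
    assert loaded.sequence_likelihood(seq).logp_total == pytest.approx(
        model.sequence_likelihood(seq).logp_total
    )


def test_favor_attention_approximates_exact_attention():
    """The random-feature linear-attention estimator converges to exact
    causal attention on moderate-magnitude queries/keys."""
    from latentheal.density import _favor_causal

    rng = np.random.default_rng(0)
    q = rng.normal(size=(1, 2, 8, 8)) * 0.5
    k = rng.normal(size=(1, 2, 8, 8)) * 0.5
    v = rng.normal(size=(1, 2, 8, 8))
    dh = q.shape[-1]
    scores = q @ np.swapaxes(k, -1, -2) / np.sqrt(dh)
    scores += np.triu(np.full(scores.shape[-2:], -np.inf), 1)
    e = np.exp(scores - scores.max(-1, keepdims=True))
    exact = (e / e.sum(-1, keepdims=True)) @ v
    approx = _favor_causal(q, k, v, np.random.default_rng(1), n_features=4096)
    assert np.abs(approx - exact).max() < 0.1


def test_favor_model_path_produces_valid_distributions():
    m = randomized(make_model(), 0.2)
    seq = np.concatenate([[m.bos_id], np.zeros(D - 1, dtype=int)])
    probs = m.next_token_distributions(
        seq, attention="favor", favor_rng=np.random.default_rng(0), n_features=512
    )
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-8)
    assert np.all(probs >= 0)


def test_evaluate_nll_matches_sequence_likelihood():
    m = randomized(make_model(), 0.2)
    rng = np.random.default_rng(9)
    seqs = rng.integers(0, K, size=(5, D))
    batch = evaluate_nll(m, seqs)
    manual = -np.mean([m.sequence_likelihood(s).logp_total for s in seqs])
    assert batch == pytest.approx(manual, abs=1e-9)
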