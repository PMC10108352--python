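"""Autoregressive density model over latent token sequences.

A small decoder-only transformer with learned absolute positions and exact
causal self-attention learns p(s) = prod_i p(s_i | s_<i) over the 1D token
sequences produced by one fixed ordering of the latent grid.  One model is
trained per ordering; a checkpoint stores the ordering descriptor and the
model refuses to score sequences produced under a different ordering.

The sequence is prepended with a begin-of-sequence (BOS) token whose id is
the codebook size K, outside the token range [0, K).  The output head is
zero-initialized, so an untrained model assigns the uniform distribution
1/K to every token.

An optional linear-attention estimator (positive-random-feature
approximation of the softmax kernel, computed causally with prefix sums) is
available at inference time behind the same interface; training always uses
exact attention.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn import Adam, Embedding, LayerNorm, Linear, Module, Tensor, cross_entropy, relu, softmax
from .orderings import Ordering

__all__ = [
    "TransformerConfig",
    "LikelihoodProfile",
    "LatentSequenceModel",
    "train_density_model",
    "sample_next",
]


@dataclass
class TransformerConfig:
    vocab_size: int  # K; BOS id is vocab_size
    seq_len: int  # d, number of latent tokens
    d_model: int = 64
    n_heads: int = 4
    n_layers: int = 2
    d_ff: int = 256
    lr: float = 3e-3
    epochs: int = 35
    batch_size: int = 64
    seed: int = 0


@dataclass
class LikelihoodProfile:
    """Per-token probabilities of the observed sequence under the model."""

    p: np.ndarray  # (d,) p(s_i | s_<i)
    logp: np.ndarray  # (d,) log p(s_i | s_<i)
    logp_total: float  # sum_i log p(s_i | s_<i) = log p(s)


class _Block(Module):
    def __init__(self, cfg: TransformerConfig, rng: np.random.Generator):
        d = cfg.d_model
        self.ln1 = LayerNorm(d)
        self.wq = Linear(d, d, rng)
        self.wk = Linear(d, d, rng)
        self.wv = Linear(d, d, rng)
        self.wo = Linear(d, d, rng)
        self.ln2 = LayerNorm(d)
        self.ff1 = Linear(d, cfg.d_ff, rng)
        self.ff2 = Linear(cfg.d_ff, d, rng)
        self.n_heads = cfg.n_heads

    def _heads(self, t: Tensor, b: int, n: int) -> Tensor:
        h = self.n_heads
        return t.reshape(b, n, h, -1).transpose(0, 2, 1, 3)  # (B,H,T,dh)

    def __call__(self, x: Tensor, mask: np.ndarray, attention: str = "exact", favor_rng=None, n_features: int = 256) -> Tensor:
        b, n, d = x.shape
        xn = self.ln1(x)
        q = self._heads(self.wq(xn), b, n)
        k = self._heads(self.wk(xn), b, n)
        v = self._heads(self.wv(xn), b, n)
        dh = d // self.n_heads
        if attention == "exact":
            scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
            scores = scores + Tensor(mask)
            att = softmax(scores, axis=-1)
            ctx = att @ v
        elif attention == "favor":
            ctx = Tensor(_favor_causal(q.data, k.data, v.data, favor_rng, n_features))
        else:
            raise ValueError(f"unknown attention mode {attention!r}")
        ctx = ctx.transpose(0, 2, 1, 3).reshape(b, n, d)
        x = x + self.wo(ctx)
        xn = self.ln2(x)
        return x + self.ff2(relu(self.ff1(xn)))


def _favor_causal(q: np.ndarray, k: np.ndarray, v: np.ndarray, rng, n_features: int) -> np.ndarray:
    """Causal linear attention with positive random features.

    exp(q.k/sqrt(dh)) is estimated by phi(q').phi(k') with
    phi(u) = exp(w.u - |u|^2/2)/sqrt(m), w ~ N(0,I), u = x/dh^(1/4);
    numerator and normalizer are prefix sums over the sequence.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    b, h, n, dh = q.shape
    scale = dh ** -0.25
    qp, kp = q * scale, k * scale
    # orthogonal random features (block-wise QR, Gaussian-matched row norms)
    # with antithetic +/-w pairing: both are standard variance reducers for
    # the positive softmax-kernel estimator
    half = max(n_features // 2, 1)
    blocks = []
    remaining = half
    while remaining > 0:
        g = rng.standard_normal((dh, dh))
        qmat, _ = np.linalg.qr(g)
        norms = np.linalg.norm(rng.standard_normal((dh, dh)), axis=1)
        blocks.append(qmat * norms[:, None])
        remaining -= dh
    w_half = np.concatenate(blocks, axis=0)[:half]
    w = np.concatenate([w_half, -w_half], axis=0)

    def phi(x, per_position: bool):
        proj = x @ w.T  # (B,H,T,m)
        norm = 0.5 * (x * x).sum(axis=-1, keepdims=True)
        z = proj - norm
        # stabilizers must cancel in the output ratio: any per-(b,h,t) factor
        # on phi(q) cancels; phi(k) may only be scaled per-(b,h)
        if per_position:
            stab = z.max(axis=-1, keepdims=True)
        else:
            stab = z.max(axis=(-2, -1), keepdims=True)
        return np.exp(z - stab)

    phi_q = phi(qp, per_position=True)
    phi_k = phi(kp, per_position=False)
    num = np.cumsum(phi_k[..., None] * v[..., None, :], axis=2)  # (B,H,T,m,dh)
    den = np.cumsum(phi_k, axis=2)  # (B,H,T,m)
    out_num = np.einsum("bhtm,bhtmd->bhtd", phi_q, num)
    out_den = np.einsum("bhtm,bhtm->bht", phi_q, den)
    return out_num / np.maximum(out_den[..., None], 1e-30)


class LatentSequenceModel(Module):
    """Decoder-only causal transformer over one ordering's token sequences."""

    def __init__(self, config: TransformerConfig, ordering_descriptor: dict):
        self.config = config
        self.ordering_descriptor = dict(ordering_descriptor)
        rng = np.random.default_rng(config.seed)
        self.tok_emb = Embedding(config.vocab_size + 1, config.d_model, rng)  # +1: BOS
        self.pos_emb = Embedding(config.seq_len, config.d_model, rng)
        self.blocks = [_Block(config, rng) for _ in range(config.n_layers)]
        self.ln_f = LayerNorm(config.d_model)
        self.head = Linear(config.d_model, config.vocab_size, rng, zero_init=True)
        self._mask_cache: dict[int, np.ndarray] = {}

    # -- forward ----------------------------------------------------------
    @property
    def bos_id(self) -> int:
        return self.config.vocab_size

    def _causal_mask(self, n: int) -> np.ndarray:
        m = self._mask_cache.get(n)
        if m is None:
            m = np.triu(np.full((n, n), -1e30), k=1)
            self._mask_cache[n] = m
        return m

    def logits(self, inputs: np.ndarray, attention: str = "exact", favor_rng=None, n_features: int = 256) -> Tensor:
        """(B, T) int tokens (BOS-led) -> (B, T, K) next-token logits."""
        inputs = np.atleast_2d(np.asarray(inputs))
        b, n = inputs.shape
        if n > self.config.seq_len:
            raise ValueError(
                f"sequence of length {n} exceeds trained context {self.config.seq_len}"
            )
        if inputs.min() < 0 or inputs.max() > self.bos_id:
            raise ValueError("token id outside [0, K] (K = BOS)")
        x = self.tok_emb(inputs) + self.pos_emb(np.arange(n))
        mask = self._causal_mask(n)
        for blk in self.blocks:
            x = blk(x, mask, attention=attention, favor_rng=favor_rng, n_features=n_features)
        return self.head(self.ln_f(x))

    def check_ordering(self, ordering: Ordering) -> None:
        if ordering.descriptor != self.ordering_descriptor:
            raise ValueError(
                f"sequence ordering {ordering.descriptor} does not match the ordering "
                f"this model was trained under: {self.ordering_descriptor}"
            )

    def next_token_distributions(self, seq_with_bos: np.ndarray, attention: str = "exact", favor_rng=None, n_features: int = 256) -> np.ndarray:
        """Per-position categorical distributions p(. | s_<i), shape (T, K).

        Position i's distribution depends only on tokens < i (causal);
        row i of the output is the distribution over token i given the
        BOS-led prefix.
        """
        seq_with_bos = np.asarray(seq_with_bos)
        if seq_with_bos.ndim != 1:
            raise ValueError("expects a single BOS-led sequence")
        logits = self.logits(seq_with_bos[None], attention=attention, favor_rng=favor_rng, n_features=n_features).data[0]
        z = logits - logits.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def sequence_likelihood(self, tokens: np.ndarray) -> LikelihoodProfile:
        """Teacher-forced likelihood profile of an observed token sequence."""
        tokens = np.asarray(tokens)
        if tokens.ndim != 1 or tokens.size != self.config.seq_len:
            raise ValueError(
                f"expected {self.config.seq_len} tokens, got shape {tokens.shape}"
            )
        inputs = np.concatenate([[self.bos_id], tokens[:-1]])
        logits = self.logits(inputs[None]).data[0]
        z = logits - logits.max(axis=-1, keepdims=True)
        logp_all = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
        logp = logp_all[np.arange(tokens.size), tokens]
        return LikelihoodProfile(p=np.exp(logp), logp=logp, logp_total=float(logp.sum()))


def sample_next(distribution: np.ndarray, rng: np.random.Generator, temperature: float = 1.0) -> int:
    """Draw one token from a categorical distribution (temperature 1 = plain)."""
    p = np.asarray(distribution, dtype=np.float64)
    if temperature <= 0:
        return int(np.argmax(p))
    if temperature != 1.0:
        logp = np.log(np.maximum(p, 1e-300)) / temperature
        logp -= logp.max()
        p = np.exp(logp)
    p = p / p.sum()
    return int(rng.choice(p.size, p=p))


def train_density_model(
    sequences: np.ndarray,
    config: TransformerConfig,
    val_sequences: np.ndarray | None = None,
    ordering: Ordering | dict | None = None,
    verbose: bool = False,
):
    """Fit a LatentSequenceModel on (N, d) token sequences from one ordering.

    Minimizes the mean negative sequence log-likelihood E[-log p(s)] by
    teacher forcing.  Returns (model, log) where log has per-epoch train
    and held-out mean -log p(s).  Raises on NaN loss.
    """
    sequences = np.asarray(sequences)
    n, d = sequences.shape
    if d != config.seq_len:
        raise ValueError(f"sequences have length {d}, config.seq_len={config.seq_len}")
    descriptor = ordering.descriptor if isinstance(ordering, Ordering) else dict(ordering or {})
    model = LatentSequenceModel(config, descriptor)
    opt = Adam(model.parameters(), lr=config.lr)
    rng = np.random.default_rng(config.seed + 1)
    bos = model.bos_id
    inputs_all = np.concatenate([np.full((n, 1), bos), sequences[:, :-1]], axis=1)
    log = {"train_nll": [], "val_nll": []}
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            logits = model.logits(inputs_all[idx])
            loss = cross_entropy(logits, sequences[idx])
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"training diverged (NaN/inf loss) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(loss.item() * d)  # per-sequence NLL
        log["train_nll"].append(float(np.mean(losses)))
        if val_sequences is not None:
            log["val_nll"].append(evaluate_nll(model, val_sequences))
        if verbose:
            msg = f"epoch {epoch}: train -logp(s) {log['train_nll'][-1]:.2f}"
            if log["val_nll"]:
                msg += f", val {log['val_nll'][-1]:.2f}"
            print(msg)
    return model, log


def evaluate_nll(model: LatentSequenceModel, sequences: np.ndarray, batch_size: int = 128) -> float:
    """Mean -log p(s) over sequences (teacher forced, no gradient)."""
    sequences = np.asarray(sequences)
    n, d = sequences.shape
    bos = model.bos_id
    total = 0.0
    for start in range(0, n, batch_size):
        batch = sequences[start : start + batch_size]
        inputs = np.concatenate([np.full((batch.shape[0], 1), bos), batch[:, :-1]], axis=1)
        logits = model.logits(inputs).data
        z = logits - logits.max(axis=-1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
        rows = np.arange(batch.shape[0])[:, None]
        cols = np.arange(d)[None, :]
        total += -logp[rows, cols, batch].sum()
    return float(total / n)


# -- checkpointing ----------------------------------------------------------


def save_density_model(model: LatentSequenceModel, path) -> None:
    meta = json.dumps(
        {"config": asdict(model.config), "ordering": model.ordering_descriptor}
    )
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8), **model.state_dict())


def load_density_model(path) -> LatentSequenceModel:
    data = np.load(path)
    meta = json.loads(bytes(data["__meta__"]).decode())
    model = LatentSequenceModel(TransformerConfig(**meta["config"]), meta["ordering"])
    model.load_state_dict({k: data[k] for k in data.files if k != "__meta__"})
    return model
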