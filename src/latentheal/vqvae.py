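"""Vector-quantized autoencoder: discrete latent codes for images.

A strided convolutional encoder maps an image (2D or 3D, values in [0,1])
to a grid of continuous encodings z_e; each spatial encoding is snapped to
its nearest codebook vector e_k (squared Euclidean distance, ties broken
toward the lowest index); a convolutional decoder reconstructs the image
from the quantized grid through a sigmoid.  Training minimizes

    L = |x - x_hat|^2  +  L_codebook  +  beta * |sg[e_k] - z_e|^2

with all terms reduced as per-element means.  By default the codebook term
is replaced by exponential-moving-average codebook updates: per code k,

    N_k  <- decay * N_k + (1 - decay) * count_k
    m_k  <- decay * m_k + (1 - decay) * sum_{i: k_i = k} z_e_i
    e_k  =  m_k / laplace(N_k),

where laplace smooths cluster sizes as (N_k + eps) / (sum_j N_j + K eps) *
sum_j N_j.  With EMA enabled no gradient-based update touches the codebook.
The quantizer uses the straight-through estimator, so reconstruction
gradients reach the encoder as if quantization were the identity.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .nn import Adam, ConvNd, Module, Tensor, depth_to_space, relu, sigmoid, straight_through
from .nn.tensor import embedding

__all__ = [
    "VQVAEConfig",
    "Codebook",
    "VqvaeLoss",
    "VQVAE",
    "train_vqvae",
    "vqvae_loss_terms",
]


@dataclass
class VQVAEConfig:
    input_shape: tuple[int, ...] = (64, 64)
    f: int = 8  # spatial downsampling factor per axis (power of 2)
    K: int = 32  # codebook size
    n_z: int = 64  # latent embedding dimension
    channels: tuple[int, ...] = (16, 32, 64)  # one entry per stride-2 stage
    beta: float = 0.25
    use_ema: bool = True
    ema_decay: float = 0.99
    ema_epsilon: float = 1e-5
    lr: float = 3e-3
    epochs: int = 30
    warmup_epochs: int = 8  # plain-autoencoder epochs before quantization
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        self.input_shape = tuple(int(s) for s in self.input_shape)
        self.channels = tuple(int(c) for c in self.channels)
        stages = int(np.log2(self.f))
        if 2**stages != self.f:
            raise ValueError(f"downsampling factor f={self.f} must be a power of 2")
        if len(self.channels) != stages:
            raise ValueError(f"need {stages} channel entries for f={self.f}, got {self.channels}")
        if any(s % self.f for s in self.input_shape):
            raise ValueError(f"input shape {self.input_shape} not divisible by f={self.f}")

    @property
    def latent_shape(self) -> tuple[int, ...]:
        return tuple(s // self.f for s in self.input_shape)


class Codebook:
    """K embedding vectors with EMA accumulators."""

    def __init__(self, K: int, n_z: int, decay: float = 0.99, epsilon: float = 1e-5, rng=None, trainable: bool = False):
        if K < 2:
            raise ValueError("codebook needs K >= 2")
        rng = rng or np.random.default_rng(0)
        vectors = rng.normal(0.0, 0.1, size=(K, n_z))
        self.trainable = trainable
        if trainable:
            self.vectors_t = Tensor(vectors, requires_grad=True)
        else:
            self.vectors_t = Tensor(vectors)
        self.ema_cluster_size = np.ones(K)
        self.ema_embedding_sum = vectors.copy()
        self.decay = float(decay)
        self.epsilon = float(epsilon)

    @property
    def vectors(self) -> np.ndarray:
        return self.vectors_t.data

    @vectors.setter
    def vectors(self, value: np.ndarray) -> None:
        self.vectors_t.data = np.asarray(value, dtype=np.float64)

    @property
    def K(self) -> int:
        return self.vectors.shape[0]

    def quantize(self, encodings: np.ndarray) -> np.ndarray:
        """Nearest-codebook indices of (M, n_z) encodings; ties -> lowest index."""
        encodings = np.asarray(encodings, dtype=np.float64)
        if not np.all(np.isfinite(encodings)):
            raise ValueError("non-finite encodings cannot be quantized")
        # |z - e|^2 = |z|^2 - 2 z.e + |e|^2; argmin returns the first minimum
        d = (
            (encodings**2).sum(axis=1, keepdims=True)
            - 2.0 * encodings @ self.vectors.T
            + (self.vectors**2).sum(axis=1)
        )
        return np.argmin(d, axis=1)

    def lookup(self, indices: np.ndarray) -> np.ndarray:
        indices = np.asarray(indices)
        if indices.min() < 0 or indices.max() >= self.K:
            raise ValueError(f"codebook index outside [0,{self.K})")
        return self.vectors[indices]

    def ema_update(self, encodings: np.ndarray, indices: np.ndarray) -> None:
        """One EMA step given current nearest assignments."""
        k, n_z = self.vectors.shape
        counts = np.bincount(indices, minlength=k).astype(np.float64)
        sums = np.zeros((k, n_z))
        np.add.at(sums, indices, encodings)
        self.ema_cluster_size = self.decay * self.ema_cluster_size + (1 - self.decay) * counts
        self.ema_embedding_sum = self.decay * self.ema_embedding_sum + (1 - self.decay) * sums
        total = self.ema_cluster_size.sum()
        smoothed = (self.ema_cluster_size + self.epsilon) / (total + k * self.epsilon) * total
        self.vectors = self.ema_embedding_sum / smoothed[:, None]


@dataclass
class VqvaeLoss:
    recons: float
    codebook_term: float
    commit: float
    beta: float
    total: float = field(init=False)

    def __post_init__(self):
        self.total = self.recons + self.codebook_term + self.beta * self.commit


def vqvae_loss_terms(x: np.ndarray, x_hat: np.ndarray, encodings: np.ndarray, quantized: np.ndarray, beta: float, use_ema: bool = True) -> VqvaeLoss:
    """Loss terms (per-element mean reduction) for inspection/logging."""
    x, x_hat = np.asarray(x), np.asarray(x_hat)
    if x.shape != x_hat.shape or encodings.shape != quantized.shape:
        raise ValueError("shape mismatch between inputs and reconstructions/encodings")
    recons = float(np.mean((x - x_hat) ** 2))
    commit = float(np.mean((quantized - encodings) ** 2))
    codebook_term = 0.0 if use_ema else commit  # same value, different gradient target
    return VqvaeLoss(recons=recons, codebook_term=codebook_term, commit=commit, beta=beta)


class VQVAE(Module):
    def __init__(self, config: VQVAEConfig):
        self.config = config
        nd = len(config.input_shape)
        rng = np.random.default_rng(config.seed)
        ch = config.channels
        c_last = ch[-1]
        self.enc_convs = []
        c_in = 1
        for c in ch:
            self.enc_convs.append(ConvNd(c_in, c, 4, rng, stride=2, padding=1, ndim=nd))
            c_in = c
        self.enc_res1 = ConvNd(c_last, c_last, 3, rng, stride=1, padding=1, ndim=nd)
        self.enc_res2 = ConvNd(c_last, c_last, 3, rng, stride=1, padding=1, ndim=nd)
        self.enc_out = ConvNd(c_last, config.n_z, 1, rng, ndim=nd)
        self.dec_in = ConvNd(config.n_z, c_last, 1, rng, ndim=nd)
        self.dec_res1 = ConvNd(c_last, c_last, 3, rng, stride=1, padding=1, ndim=nd)
        self.dec_res2 = ConvNd(c_last, c_last, 3, rng, stride=1, padding=1, ndim=nd)
        # decoder upsampling: conv at the coarse grid to c*2^nd channels then
        # depth-to-space, so expensive convolutions never run at fine
        # resolution; a thin 3x3 conv at full resolution finishes the image
        up_channels = list(reversed(ch[:-1])) + [4]
        self.dec_convs = []
        c_in = c_last
        for c in up_channels:
            self.dec_convs.append(ConvNd(c_in, c * 2**nd, 3, rng, stride=1, padding=1, ndim=nd))
            c_in = c
        self.dec_out = ConvNd(4, 1, 3, rng, stride=1, padding=1, ndim=nd)
        self.nd = nd
        self.codebook = Codebook(
            config.K,
            config.n_z,
            decay=config.ema_decay,
            epsilon=config.ema_epsilon,
            rng=np.random.default_rng(config.seed + 1),
            trainable=not config.use_ema,
        )

    # -- model pieces -----------------------------------------------------
    def _check_images(self, images: np.ndarray) -> np.ndarray:
        images = np.asarray(images, dtype=np.float64)
        if images.ndim == len(self.config.input_shape):
            images = images[None]
        if images.shape[1:] != self.config.input_shape:
            raise ValueError(
                f"image shape {images.shape[1:]} does not match the model's "
                f"configured input shape {self.config.input_shape}"
            )
        return images

    def _encode_t(self, images: np.ndarray) -> Tensor:
        x = Tensor(self._check_images(images)[:, None])  # (N,1,*S)
        for conv in self.enc_convs:
            x = relu(conv(x))
        x = x + self.enc_res2(relu(self.enc_res1(relu(x))))
        return self.enc_out(x)  # (N, n_z, *L)

    def _decode_t(self, z_q: Tensor) -> Tensor:
        x = relu(self.dec_in(z_q))
        x = x + self.dec_res2(relu(self.dec_res1(x)))
        for conv in self.dec_convs:
            x = relu(depth_to_space(conv(x), 2))
        out = sigmoid(self.dec_out(x))
        return out.reshape(*(out.shape[0],) + out.shape[2:])

    def encode(self, images: np.ndarray) -> np.ndarray:
        """Images (N,*S) or (*S) -> continuous encodings z_e (N, n_z, *S/f)."""
        return self._encode_t(images).data

    def quantize(self, encodings: np.ndarray):
        """Encodings (N, n_z, *L) -> (indices (N,*L), quantized (N, n_z, *L))."""
        encodings = np.asarray(encodings)
        single = encodings.ndim == len(self.config.latent_shape) + 1
        if single:
            encodings = encodings[None]
        n = encodings.shape[0]
        flat = np.moveaxis(encodings, 1, -1).reshape(-1, self.config.n_z)
        idx = self.codebook.quantize(flat)
        zq = np.moveaxis(
            self.codebook.lookup(idx).reshape((n,) + self.config.latent_shape + (self.config.n_z,)),
            -1,
            1,
        )
        idx = idx.reshape((n,) + self.config.latent_shape)
        if single:
            return idx[0], zq[0]
        return idx, zq

    def decode(self, indices_or_quantized: np.ndarray) -> np.ndarray:
        """Latent indices (N,*L) or quantized grids (N,n_z,*L) -> images in [0,1]."""
        arr = np.asarray(indices_or_quantized)
        l_nd = len(self.config.latent_shape)
        if np.issubdtype(arr.dtype, np.integer):
            single = arr.ndim == l_nd
            if single:
                arr = arr[None]
            zq = np.moveaxis(self.codebook.lookup(arr), -1, 1)
        else:
            single = arr.ndim == l_nd + 1
            if single:
                arr = arr[None]
            zq = arr
        out = self._decode_t(Tensor(zq)).data
        return out[0] if single else out

    def reconstruct(self, images: np.ndarray) -> np.ndarray:
        """Plain VQ-VAE reconstruction: decode(quantize(encode(x)))."""
        single = np.asarray(images).ndim == len(self.config.input_shape)
        idx, _ = self.quantize(self.encode(images))
        out = self.decode(idx)
        return out[0] if single else out

    def tokens(self, images: np.ndarray) -> np.ndarray:
        """Latent index grid (N,*L) of images — the discrete representation."""
        single = np.asarray(images).ndim == len(self.config.input_shape)
        idx, _ = self.quantize(self.encode(images))
        return idx[0] if single else idx

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        meta = json.dumps(asdict(self.config))
        np.savez(
            path,
            __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
            __codebook__=self.codebook.vectors,
            __ema_size__=self.codebook.ema_cluster_size,
            __ema_sum__=self.codebook.ema_embedding_sum,
            **self.state_dict(),
        )

    @classmethod
    def load(cls, path) -> "VQVAE":
        data = np.load(path)
        meta = json.loads(bytes(data["__meta__"]).decode())
        meta["input_shape"] = tuple(meta["input_shape"])
        meta["channels"] = tuple(meta["channels"])
        model = cls(VQVAEConfig(**meta))
        model.load_state_dict(
            {k: data[k] for k in data.files if not k.startswith("__")}
        )
        model.codebook.vectors = data["__codebook__"]
        model.codebook.ema_cluster_size = data["__ema_size__"]
        model.codebook.ema_embedding_sum = data["__ema_sum__"]
        return model


def _kmeans_init_codebook(model: VQVAE, sample_images: np.ndarray, config: VQVAEConfig) -> None:
    """Initialize the codebook by k-means over current encoder outputs."""
    from sklearn.cluster import KMeans

    z = model.encode(sample_images)
    flat = np.moveaxis(z, 1, -1).reshape(-1, config.n_z)
    km = KMeans(n_clusters=config.K, n_init=1, max_iter=20, random_state=config.seed).fit(flat)
    model.codebook.vectors = km.cluster_centers_.astype(np.float64)
    model.codebook.ema_embedding_sum = model.codebook.vectors.copy()
    model.codebook.ema_cluster_size = np.ones(config.K)


def train_vqvae(
    images: np.ndarray,
    config: VQVAEConfig,
    val_images: np.ndarray | None = None,
    verbose: bool = False,
):
    """Train a VQ-VAE on (N, *S) images in [0,1].

    Returns (model, log); log holds per-epoch mean loss terms and, if a
    validation split is given, held-out reconstruction error.  Training
    starts with `warmup_epochs` of plain (unquantized) autoencoding so the
    encoder develops diverse features; the codebook is then initialized by
    k-means over encoder outputs and quantized training proceeds with EMA
    codebook updates (or the codebook loss term when EMA is disabled).
    There is no dead-code resuscitation — codebook usage is only logged.
    Raises on NaN loss.
    """
    images = np.asarray(images, dtype=np.float64)
    model = VQVAE(config)
    params = model.parameters()
    if not config.use_ema:
        params = params + [model.codebook.vectors_t]
    opt = Adam(params, lr=config.lr)
    rng = np.random.default_rng(config.seed + 2)
    n = images.shape[0]
    log = {"recons": [], "commit": [], "total": [], "val_recons": []}
    quantizing = config.warmup_epochs <= 0
    for epoch in range(config.epochs):
        if not quantizing and epoch >= config.warmup_epochs:
            _kmeans_init_codebook(model, images[: min(n, 64)], config)
            quantizing = True
        order = rng.permutation(n)
        ep = {"recons": [], "commit": [], "total": []}
        for start in range(0, n, config.batch_size):
            batch = images[order[start : start + config.batch_size]]
            z_e = model._encode_t(batch)
            if quantizing:
                flat = np.moveaxis(z_e.data, 1, -1).reshape(-1, config.n_z)
                idx = model.codebook.quantize(flat)
                zq_flat = model.codebook.lookup(idx)
                zq = np.moveaxis(
                    zq_flat.reshape(z_e.data.shape[0:1] + config.latent_shape + (config.n_z,)),
                    -1,
                    1,
                )
                zq_t = straight_through(z_e, zq)
                commit = ((z_e - Tensor(zq)) ** 2.0).mean()
            else:
                zq_t = z_e
                commit = None
            x_hat = model._decode_t(zq_t)
            recons = ((Tensor(batch) - x_hat) ** 2.0).mean()
            loss = recons if commit is None else recons + commit * config.beta
            if quantizing and not config.use_ema:
                zq_grad = embedding(model.codebook.vectors_t, idx)
                codebook_term = ((zq_grad - Tensor(flat)) ** 2.0).mean()
                loss = loss + codebook_term
            if not np.isfinite(loss.item()):
                raise RuntimeError(f"VQ-VAE training diverged (NaN/inf loss) at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            if quantizing and config.use_ema:
                model.codebook.ema_update(flat, idx)
            ep["recons"].append(recons.item())
            ep["commit"].append(commit.item() if commit is not None else 0.0)
            ep["total"].append(loss.item())
        for k in ("recons", "commit", "total"):
            log[k].append(float(np.mean(ep[k])))
        if val_images is not None:
            recon = model.reconstruct(val_images)
            log["val_recons"].append(float(np.mean((val_images - recon) ** 2)))
        if verbose:
            msg = f"epoch {epoch}: recons {log['recons'][-1]:.5f} commit {log['commit'][-1]:.5f}"
            if log["val_recons"]:
                msg += f" val {log['val_recons'][-1]:.5f}"
            print(msg)
    return model, log
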