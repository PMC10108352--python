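"""End-to-end orchestration of the synthetic anomaly-segmentation study.

`run_synthetic_study` reproduces, at desk scale, the controllable
experiment the method is validated on: train a VQ-VAE and a small ensemble
of per-ordering sequence models on clean head phantoms, contaminate held-out
phantoms with binary sprites, and measure

* the segmentation ablation — best-achievable DICE of (1) the raw VQ-VAE
  residual, (2) a single ordering's healed residual, (3) the same with
  latent-mask filtering, (4) the ensemble mean of masked residuals;
* image-wise detection — AUROC of the ensemble-mean log-likelihood for
  clean vs far-OOD (uniform noise) and clean vs sprite-contaminated
  images, plus the two-feature (log-likelihood, lesion volume) one-class
  score.

All stages are deterministic functions of the study seed.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field

import numpy as np

from . import synthetic
from .density import TransformerConfig, train_density_model
from .detection import fit_one_class_scorer, image_log_likelihood, lesion_volume
from .evaluation import auroc, best_dice, evaluate_segmentation
from .healing import DEFAULT_THRESHOLD_2D, binarize, segment_ensemble
from .orderings import ensemble_orderings
from .vqvae import VQVAEConfig, train_vqvae

__all__ = ["StudyConfig", "StudyResult", "run_synthetic_study"]


@dataclass
class StudyConfig:
    """Study conditions for the desk-scale synthetic experiment."""

    image_size: tuple[int, int] = (64, 64)
    n_train: int = 500
    n_val: int = 100
    n_test: int = 50  # contaminated test images
    n_clean_test: int = 50  # in-distribution test images (detection)
    n_far_ood: int = 50  # uniform-noise images (detection)
    n_val_seg: int = 40  # validation images segmented for the lesion-size feature
    sprite_intensities: tuple[float, ...] = (0.0, 1.0)  # binary-valued sprites
    noise_sd: float = 0.0
    ordering_class: str = "raster"
    ensemble_size: int = 4
    threshold: float = DEFAULT_THRESHOLD_2D
    sigma: float | None = None  # None -> f/2
    lesion_quantile: float = 0.99  # validation residual quantile -> binarization threshold
    vqvae: dict = field(default_factory=dict)
    density: dict = field(default_factory=dict)


@dataclass
class StudyResult:
    dice_vqvae_only: float
    dice_healed: float
    dice_masked: float
    dice_ensemble: float
    auprc_ensemble: float
    auroc_far_ood: float
    auroc_near_ood: float
    auroc_logp_only: float
    auroc_two_feature: float
    codebook_usage: int
    timings: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _train_models(images_train, images_val, cfg: StudyConfig, seed: int):
    vq_kwargs = dict(input_shape=cfg.image_size, seed=seed)
    vq_kwargs.update(cfg.vqvae)
    vq_config = VQVAEConfig(**vq_kwargs)
    vq, vq_log = train_vqvae(images_train, vq_config, val_images=images_val[:16])

    orderings = ensemble_orderings(cfg.ordering_class, vq_config.latent_shape, count=cfg.ensemble_size)
    tokens_train = vq.tokens(images_train)
    tokens_val = vq.tokens(images_val)
    seq_len = int(np.prod(vq_config.latent_shape))
    members = []
    for i, ordering in enumerate(orderings):
        d_kwargs = dict(vocab_size=vq_config.K, seq_len=seq_len, seed=seed + 10 + i)
        d_kwargs.update(cfg.density)
        d_config = TransformerConfig(**d_kwargs)
        seqs = np.stack([ordering.apply(t) for t in tokens_train])
        val_seqs = np.stack([ordering.apply(t) for t in tokens_val])
        model, _ = train_density_model(seqs, d_config, val_sequences=val_seqs[:32], ordering=ordering)
        members.append((model, ordering))
    usage = len(np.unique(tokens_train))
    return vq, members, usage, vq_log


@dataclass
class StudyArtifacts:
    """Trained models and held-out data of one study run."""

    vqvae: object
    members: list
    clean_test: list
    contaminated_test: list
    lesion_threshold: float


def run_synthetic_study(
    seed: int,
    cfg: StudyConfig | None = None,
    verbose: bool = False,
    return_artifacts: bool = False,
):
    """Run the full synthetic study and return its headline metrics.

    With ``return_artifacts=True`` returns (StudyResult, StudyArtifacts)."""
    cfg = cfg or StudyConfig()
    t = {}
    tic = time.time()
    ss = np.random.SeedSequence(seed)
    data_seeds = [int(s) for s in ss.generate_state(6) % (2**31)]

    train = synthetic.generate_dataset(cfg.n_train, seed=data_seeds[0], size=cfg.image_size)
    val = synthetic.generate_dataset(cfg.n_val, seed=data_seeds[1], size=cfg.image_size)
    test = synthetic.generate_dataset(
        cfg.n_test,
        seed=data_seeds[2],
        size=cfg.image_size,
        contaminated=True,
        intensities=cfg.sprite_intensities,
        noise_sd=cfg.noise_sd,
    )
    clean_test = synthetic.generate_dataset(cfg.n_clean_test, seed=data_seeds[3], size=cfg.image_size)
    far_ood = [
        synthetic.generate_far_ood(data_seeds[4] + i, size=cfg.image_size, kind="uniform")
        for i in range(cfg.n_far_ood)
    ]
    images_train = np.stack([p.image for p in train])
    images_val = np.stack([p.image for p in val])
    t["data"] = time.time() - tic

    tic = time.time()
    vq, members, usage, _ = _train_models(images_train, images_val, cfg, seed)
    t["training"] = time.time() - tic

    # --- segmentation ablation on the contaminated test set ---------------
    tic = time.time()
    heal_rng = np.random.default_rng(data_seeds[5])
    res_vq, res_healed, res_masked, res_ens, gts = [], [], [], [], []
    test_lesions = []
    for sample in test:
        x = sample.image
        recon = vq.reconstruct(x)
        res_vq.append(np.abs(x - recon))
        mean_resid, results = segment_ensemble(
            x, vq, members, threshold=cfg.threshold, sigma=cfg.sigma, rng=heal_rng
        )
        res_healed.append(results[0].residual_unmasked)
        res_masked.append(results[0].residual)
        res_ens.append(mean_resid)
        gts.append(sample.gt_mask)
        test_lesions.append(mean_resid)
    d_vq, _ = best_dice(res_vq, gts)
    d_healed, _ = best_dice(res_healed, gts)
    d_masked, _ = best_dice(res_masked, gts)
    report = evaluate_segmentation(res_ens, gts)
    t["segmentation"] = time.time() - tic

    # --- image-wise detection --------------------------------------------
    tic = time.time()

    def mean_logp(image):
        return image_log_likelihood(members, vq, image).mean_logp

    logp_clean = np.array([mean_logp(s.image) for s in clean_test])
    logp_cont = np.array([mean_logp(s.image) for s in test])
    logp_far = np.array([mean_logp(x) for x in far_ood])
    labels_far = np.concatenate([np.ones_like(logp_clean), np.zeros_like(logp_far)])
    auroc_far = auroc(np.concatenate([logp_clean, logp_far]), labels_far)
    labels_near = np.concatenate([np.ones_like(logp_clean), np.zeros_like(logp_cont)])
    auroc_near = auroc(np.concatenate([logp_clean, logp_cont]), labels_near)

    # lesion-size feature: binarization threshold = validation residual quantile
    val_seg = val[: cfg.n_val_seg]
    val_resids = []
    val_logps = []
    for sample in val_seg:
        mean_resid, _ = segment_ensemble(
            sample.image, vq, members, threshold=cfg.threshold, sigma=cfg.sigma, rng=heal_rng
        )
        val_resids.append(mean_resid)
        val_logps.append(mean_logp(sample.image))
    lesion_threshold = float(np.quantile(np.stack(val_resids), cfg.lesion_quantile))

    def features(logps, resids):
        vols = [lesion_volume(binarize(r, lesion_threshold)) for r in resids]
        return np.column_stack([logps, vols])

    ref_feats = features(val_logps, val_resids)
    scorer = fit_one_class_scorer(ref_feats, seed=seed)
    clean_resids = []
    for sample in clean_test:
        mean_resid, _ = segment_ensemble(
            sample.image, vq, members, threshold=cfg.threshold, sigma=cfg.sigma, rng=heal_rng
        )
        clean_resids.append(mean_resid)
    feats_clean = features(logp_clean, clean_resids)
    feats_cont = features(logp_cont, test_lesions)
    scores = np.concatenate([scorer.score(feats_clean), scorer.score(feats_cont)])
    auroc_two = auroc(scores, labels_near)
    t["detection"] = time.time() - tic

    result = StudyResult(
        dice_vqvae_only=d_vq,
        dice_healed=d_healed,
        dice_masked=d_masked,
        dice_ensemble=report.best_dice,
        auprc_ensemble=report.auprc,
        auroc_far_ood=auroc_far,
        auroc_near_ood=auroc_near,
        auroc_logp_only=auroc_near,
        auroc_two_feature=auroc_two,
        codebook_usage=usage,
        timings={k: round(v, 1) for k, v in t.items()},
    )
    if verbose:
        print(json.dumps(result.to_dict(), indent=2))
    if return_artifacts:
        return result, StudyArtifacts(
            vqvae=vq,
            members=members,
            clean_test=clean_test,
            contaminated_test=test,
            lesion_threshold=lesion_threshold,
        )
    return result
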