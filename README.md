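# latentheal

Unsupervised anomaly detection and segmentation for brain-like images,
built on discrete latent representations and autoregressive token models.

## The problem

Segmenting lesions (tumours, white-matter hyperintensities, demyelinating
lesions) normally requires expert pixel labels, which are expensive and
never cover every pathology. The alternative is to model *healthy* images
only and flag whatever a test image does that healthy images never do.
Plain autoencoder approaches score anomalies by reconstruction error and
inherit all the blur and bias of the reconstruction. `latentheal`
implements the sharper, likelihood-first variant of this idea for
researchers working on out-of-distribution detection and unsupervised
lesion segmentation:

1. A **VQ-VAE** compresses an image `x` to a grid of discrete codebook
   indices `z_q` (encoder → nearest-codebook quantization
   `k = argmin_j ‖z_e − e_j‖²` with straight-through gradients and EMA
   codebook updates).
2. A fixed **ordering** (raster, S-curve, Hilbert, or random — each with
   reflected/transposed variants) flattens the grid to a token sequence
   `s`, and a causal **transformer** learns `p(s) = Π_i p(s_i | s_<i)` on
   healthy data.
3. At test time, tokens with `p(s_i | s_<i) ≤ t` form a **resampling
   mask**; masked tokens are **healed** by ancestral resampling
   conditioned on the healed prefix, and the decoded healed image `x′`
   gives residuals `|x − x′|`.
4. The residuals are **filtered** by the upsampled, Gaussian-smoothed
   resampling mask and **averaged over an ensemble** of per-ordering
   models. Image-wise scores use the ensemble mean `log p(x) = Σ_i log
   p(s_i)`, optionally combined with predicted lesion volume in a
   one-class SVM.

Everything — including the convolutional autoencoder and the causal
transformer — runs on a small numpy autodiff engine shipped in
`latentheal.nn`, so the whole package is pure scientific Python with
deterministic, seedable training.

## Worked example

The package ships a fully synthetic study: head-like phantoms (bright
skull ring, textured interior, dark ventricles) contaminated with binary
sprites whose support is the known ground truth.

```python
from latentheal.pipeline import StudyConfig, run_synthetic_study

result = run_synthetic_study(seed=1, cfg=StudyConfig(), verbose=True)
```

trains the VQ-VAE (500 phantoms, 8×8 latent grid, K=32 codes) and four
raster-ordering transformers, then segments 50 sprite-contaminated
phantoms and scores clean/contaminated/noise images. It prints (the
per-stage wall-clock `timings` entry is omitted here):

```json
{
  "dice_vqvae_only": 0.6282002706359946,
  "dice_healed": 0.7402030553183414,
  "dice_masked": 0.7587174154858055,
  "dice_ensemble": 0.823813899501862,
  "auprc_ensemble": 0.8422661488094438,
  "auroc_far_ood": 1.0,
  "auroc_near_ood": 0.9904,
  "auroc_logp_only": 0.9904,
  "auroc_two_feature": 0.9912,
  "codebook_usage": 30
}
```

Read the four `dice_*` values as the ablation, in best-achievable DICE
(⌈DICE⌉, the maximum DICE over one global residual threshold): raw VQ-VAE
residuals (0.63) < transformer healing (0.74) < mask-filtered residuals
(0.76) ≤ 4-ordering ensemble (0.82). Each stage of the method earns its
keep. `auroc_far_ood = 1.0` says the ensemble log-likelihood separates
phantoms from uniform noise perfectly; `auroc_near_ood = 0.99` that it
also separates clean from sprite-contaminated phantoms; and the
two-feature one-class score (log-likelihood + lesion volume) does at
least as well as the likelihood alone.

## Command-line pipeline

The same stages are available as a config-driven CLI operating on a run
directory (PNG/NIfTI in, PNG/NIfTI + CSV/JSON out, with provenance
records per stage):

```bash
latentheal make-data      config.yaml --run runs/demo
latentheal train-vqvae    config.yaml --run runs/demo
latentheal train-density  config.yaml --run runs/demo
latentheal segment        config.yaml --run runs/demo --seed 0
latentheal detect         config.yaml --run runs/demo
latentheal evaluate       config.yaml --run runs/demo
```

`segment` accepts external images via `--input`, a custom likelihood
`--threshold`, Gaussian `--sigma`, and `--positive-residuals` for
hyperintense-lesion post-processing. See `latentheal.config.RunConfig`
for the YAML schema; `tests/test_cli.py` contains a complete miniature
configuration.

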