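# Methods

## The model

`latentheal` detects and segments anomalies in brain-like images without
any anomaly labels, by modelling what *normal* images look like and asking
where a test image departs from that model. It combines two learned
components and one combinatorial one:

1. **Vector-quantized autoencoder (VQ-VAE).** An encoder E maps an image
   x ∈ [0,1]^D to a grid of continuous latent vectors z_e ∈ R^(d×n_z),
   downsampled by a factor f per axis. Each spatial vector is snapped to
   its nearest codebook entry e_k (k = argmin_j ‖z_e − e_j‖²; ties go to
   the lowest index, for determinism), and a decoder G reconstructs the
   image from the quantized grid. Training minimizes

       L = ‖x − x̂‖² + L_codebook + β‖sg[e_k] − z_e‖²,

   all terms per-element means, with the straight-through estimator
   carrying reconstruction gradients through the quantizer. By default the
   codebook term is replaced by exponential-moving-average (EMA) updates
   of the codebook: per code, decayed counts and coordinate sums whose
   ratio (with Laplace-smoothed counts) gives the code vector. With EMA
   enabled, gradients never touch the codebook.

2. **Autoregressive token model.** A fixed ordering flattens the latent
   index grid into a sequence s; a small decoder-only transformer with
   exact causal self-attention and learned positions is trained by
   teacher forcing to minimize E[−log p(s)], p(s) = Π_i p(s_i | s_<i),
   with a begin-of-sequence token (id K) prepended. Several orderings are
   used — raster, S-curve (boustrophedon), generalized Hilbert, random —
   each augmented by reflections and transposition: 8 variants in 2D,
   7 in 3D (identity + the six single/double axis reflections). One
   independent model is trained per ordering; different orderings give
   each model a different causal context for the same voxel, which is what
   makes the ensemble informative rather than just averaging noise.

3. **Healing and segmentation.** At test time each model scores every
   token in one teacher-forced pass over the *original* sequence; tokens
   with p(s_i | s_<i) ≤ t (t = 0.005 in 2D, 0.001 in 3D) form the binary
   *resampling mask*. Masked tokens are then resampled left-to-right,
   each conditioned on the already-healed prefix (one pass, no iteration),
   and the healed sequence is decoded to a lesion-free reconstruction x′.
   The residual |x − x′| is multiplied by the resampling mask upsampled to
   image resolution (nearest-neighbour replication of each latent cell
   over its f×f patch) and smoothed with a Gaussian of σ = f/2 pixels;
   this suppresses residual energy in places the token models considered
   normal, where the autoencoder is merely blurry. The ensemble
   segmentation is the mean of the per-ordering *masked* residuals (each
   member owns its own mask). Image-wise anomaly scores are the ensemble
   mean of log p(x) = Σ_i log p(s_i), optionally combined with the
   predicted lesion volume in a two-feature one-class SVM fitted on normal
   validation images (features standardized; higher score = more normal).

## Numerical and design choices

* **numpy neural-network engine.** Both models are built on
  `latentheal.nn`, a compact float64 reverse-mode autodiff library
  (im2col/matmul N-d convolutions with a batched-bincount scatter in the
  backward pass, depth-to-space upsampling, layer norm, Adam). Everything
  is plain numpy, so a fixed seed gives bit-reproducible training on a
  given platform. Desk-scale defaults — 64×64 images, f = 8, K = 32,
  n_z = 64, encoder channels (16, 32, 64), transformer with 2 layers,
  4 heads, width 64 — keep a full study within minutes on one CPU core.

* **Quantization warm-up.** With a randomly initialized encoder, all
  spatial cells initially map to a handful of codes and EMA then merges
  the codebook irreversibly (there is deliberately no dead-code
  resuscitation; usage is only logged). Training therefore starts with a
  few plain-autoencoder epochs (default 8 of 30), after which the
  codebook is initialized by k-means over actual encoder outputs and
  quantized training proceeds. This reliably yields near-full codebook
  usage.

* **Decoder layout.** Upsampling uses convolution at the coarse grid into
  c·2^nd channels followed by depth-to-space, plus one thin 3×3
  convolution at full resolution; convolutions never run wide at fine
  resolution, which dominates CPU cost otherwise.

* **Generalized Hilbert curves.** Latent grids need not be powers of two,
  so the Hilbert class uses a recursive generalized construction on
  arbitrary rectangles. Its primary axis is fixed (not chosen by side
  length) so that transposed variants are genuinely different orderings on
  rectangles. On some odd-by-even rectangles a corner-to-corner fully
  grid-adjacent path is parity-impossible; there the curve contains a
  single diagonal step. In 3D the curve is Hilbert within each
  trailing-axes slab and boustrophedon across slabs, which preserves
  grid-adjacency of consecutive tokens everywhere.

* **Linear attention.** An optional inference-time attention estimator
  (positive orthogonal random features with antithetic pairing, causal
  prefix sums) stands behind the same interface as exact attention. It is
  a Monte-Carlo approximation whose variance grows with attention
  sharpness; training always uses exact attention, which at sequence
  length ≤ 4,096 is the cheaper and exact choice.

* **Likelihood-mask details.** Mask thresholds compare p(s_i) with `<=`,
  so a probability exactly at the threshold counts as anomalous.
  Likelihoods for the mask come from the original sequence only; the
  healed prefix affects sampling but masks are not recomputed. Ancestral
  sampling uses temperature 1.

* **Metrics.** Best-achievable DICE searches one global threshold over
  the pooled test set: all unique residual values when ≤ 10⁴, else 1,024
  quantile-spaced candidates (exact at desk scale, bounded at volume
  scale). DICE of two empty masks is defined as 1. AUROC/AUPRC/ROC curves
  come from scikit-learn; for FPR-at-TPR the in-distribution class is the
  positive class. Degenerate single-class label sets raise rather than
  return NaN.

* **Normalization.** Per-image min–max scaling for 2D inputs; 1st/99th
  percentile scaling clipped to [0,1] for 3D volumes, where extreme
  voxels would otherwise compress the intensity range.

* **Lesion-volume feature.** The residual binarization threshold is the
  0.99 quantile of pooled validation-set ensemble residuals when no
  ground truth is available (validation images are normal); with ground
  truth one would instead maximize validation DICE.

## The synthetic data and what it does (not) show

The generator emulates the controllable 2D study conditions: head-like
phantoms — a bright elliptical skull ring, mid-gray interior with
low-frequency Gaussian texture, 1–3 dark ventricle-like blobs, randomized
pose/axes per seed, exact-zero background — contaminated with connected
binary sprites (procedural ellipses, axis-aligned rectangles, and
thresholded-noise blobs, 2–15% of the image area, required to overlap the
head by ≥ 50%, at most 20 placement retries). Sprite pixels are set to an
intensity in [0,1] (the study default alternates 0 and 1), optionally with
additive Gaussian noise of σ = 0.2 on the sprite, clipped to [0,1].
Far-out-of-distribution fixtures are uniform-noise images and multi-lobe
("hand-like") shapes. Every generator is a pure function of its seed.

These phantoms share with real head images the features the method
exploits — closed bright boundary, smooth interior statistics, dark
background, population variation — but none of the acquisition physics,
partial-volume effects, registration error or anatomy of MRI/CT. Passing
the study here shows the machinery (discretization, token density
modelling, healing, mask filtering, ensembling) behaves as designed on
data whose anomalies are exactly known; it does not certify performance
on clinical data, which additionally requires the registration and
lesion-inpainting preprocessing that is out of scope for this package.

## The desk-scale study

`latentheal.pipeline.run_synthetic_study` trains on 500 phantoms
(100 validation), segments 50 sprite-contaminated phantoms, and scores 50
clean, 50 contaminated and 50 uniform-noise images. Problem sizes, epoch
counts (30 VQ-VAE epochs with 8 warm-up; 35 transformer epochs per
ordering, where held-out likelihood plateaus) and the 4-member raster
ensemble were chosen so a full study runs in roughly ten minutes on one
CPU core while still exhibiting the qualitative results: the segmentation
ablation improves monotonically from raw VQ-VAE residuals through
healing, mask filtering and ensembling, far-OOD detection is essentially
perfect, near-OOD detection is clearly above chance, and adding the
lesion-volume feature does not hurt. Absolute values at this scale are
not comparable to a study trained on thousands of real images with
full-size architectures.

## Known limitations

* Dead codebook codes are possible on unlucky seeds (usage is logged);
  by design nothing revives them.
* Healing does one left-to-right pass; it never re-scores the healed
  sequence, so a masked token early in the sequence is corrected using
  possibly-anomalous later context from other orderings only.
* The 2D/3D mask thresholds (0.005 / 0.001) are operating points chosen
  for K ≈ 32-sized vocabularies; very different K warrants re-tuning on a
  holdout split.
* The FAVOR-style attention path is an estimator, not a drop-in equal:
  with sharp attention its output error can be large at practical feature
  counts.
* 3D support is implemented (N-d convolutions, 7-ordering ensembles,
  percentile normalization, NIfTI I/O) but the shipped study conditions
  are 2D; 3D runs at realistic volume sizes need substantially more
  compute than a desktop CPU.
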