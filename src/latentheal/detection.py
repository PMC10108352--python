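"""Image-wise anomaly (out-of-distribution) detection.

Two scores are available per image: the ensemble-mean sequence
log-likelihood log p(x) = sum_i log p(s_i) averaged over the per-ordering
models, and a two-feature one-class score that combines the mean
log-likelihood with the predicted lesion volume (pixel count of the
binarized ensemble residual).  The one-class scorer is a one-class SVM
fitted on features of *normal* reference images only, with features
standardized; higher decision scores mean "more normal".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import OneClassSVM

from .density import LatentSequenceModel
from .orderings import Ordering
from .vqvae import VQVAE

__all__ = [
    "DetectionScore",
    "image_log_likelihood",
    "lesion_volume",
    "OneClassScorer",
    "fit_one_class_scorer",
]

MIN_REFERENCE_POINTS = 10


@dataclass
class DetectionScore:
    per_model_logp: list[float]
    mean_logp: float = field(init=False)
    lesion_volume: int | None = None
    decision_score: float | None = None

    def __post_init__(self):
        self.mean_logp = float(np.mean(self.per_model_logp))


def image_log_likelihood(
    members: list[tuple[LatentSequenceModel, Ordering]],
    vqvae: VQVAE,
    image: np.ndarray,
) -> DetectionScore:
    """Ensemble log-likelihood of one image.

    Each model scores the same latent grid under its own ordering; the
    image-wise score is the arithmetic mean of the per-model totals.
    """
    if not members:
        raise ValueError("need at least one (model, ordering) member")
    indices = vqvae.tokens(image)
    per_model = []
    for model, ordering in members:
        model.check_ordering(ordering)
        tokens = ordering.apply(indices)
        per_model.append(model.sequence_likelihood(tokens).logp_total)
    return DetectionScore(per_model_logp=per_model)


def lesion_volume(binary_mask: np.ndarray) -> int:
    """Number of set pixels/voxels in a binary segmentation mask."""
    return int(np.asarray(binary_mask).astype(bool).sum())


class OneClassScorer:
    """One-class SVM over (mean_logp, lesion_volume) features.

    Fitted on normal validation images only; `score` returns the SVM
    decision function after the training standardization — higher =
    more normal, negative values fall outside the learned frontier.
    """

    def __init__(self, nu: float = 0.1, gamma: str | float = "scale", seed: int = 0):
        self.nu = nu
        self.gamma = gamma
        self.seed = seed
        self._pipe = None

    def fit(self, features: np.ndarray) -> "OneClassScorer":
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        if features.shape[0] < MIN_REFERENCE_POINTS:
            raise ValueError(
                f"one-class scorer needs >= {MIN_REFERENCE_POINTS} reference points, "
                f"got {features.shape[0]}"
            )
        # OneClassSVM is deterministic given data; seed kept for provenance
        self._pipe = make_pipeline(
            StandardScaler(), OneClassSVM(kernel="rbf", nu=self.nu, gamma=self.gamma)
        ).fit(features)
        return self

    def score(self, features: np.ndarray) -> np.ndarray:
        if self._pipe is None:
            raise RuntimeError("scorer is not fitted")
        features = np.atleast_2d(np.asarray(features, dtype=np.float64))
        return self._pipe.decision_function(features)


def fit_one_class_scorer(reference_features, nu: float = 0.1, seed: int = 0) -> OneClassScorer:
    """Fit the two-feature one-class scorer on normal reference features."""
    return OneClassScorer(nu=nu, seed=seed).fit(np.asarray(reference_features))
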